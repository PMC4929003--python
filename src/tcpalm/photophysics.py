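"""Dendra2 photophysics simulation and synthetic acquisition generators.

Photo-convertible fluorophores such as Dendra2 are the workhorse of
live-cell PALM.  A molecule starts *unconverted* (invisible in the red
channel), is stochastically photo-converted to the emitting *on* state
(rate ``k_on``), and from there either blinks into a reversible *dark*
state (``k_dark``, returning with ``k_rev``) or photobleaches
irreversibly (``k_bleach``).  The camera integrates the emitted light in
fixed frames (60 ms by default); a molecule is registered as a single
"detection" in a frame when it spends at least half a frame emitting in
it, and simultaneous molecules within a region still produce a single
count because detection counting ignores spot intensity.

This module provides

* an exact Gillespie simulator for single-molecule state trajectories,
* the camera binning/collapsing rules that turn trajectories into
  per-frame detection counts,
* cluster scenarios (N molecules recruited and released at set times)
  rendered as cumulative-detection traces,
* spatial localization fields (clusters + random background with
  Gaussian localization error), and
* diffraction-limited image stacks of mRNA loci with known per-molecule
  unit brightness,

which together supply the inputs of every downstream analysis stage.

Units: time in seconds, positions in nanometres, frames 0-based; frame
``f`` covers the half-open interval ``[f*frame_time, (f+1)*frame_time)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import special

__all__ = [
    "PhotophysicsParams",
    "MoleculeTrajectory",
    "ClusterScenario",
    "CumulantTrace",
    "DENDRA2",
    "simulate_molecule",
    "simulate_molecules",
    "bin_detections",
    "simulate_cluster_trace",
    "sample_spatial_field",
    "render_locus_stack",
]

# Trajectory state labels
UNCONVERTED = "unconverted"
ON = "on"
DARK = "dark"
BLEACHED = "bleached"

_HALF_FRAME_TOL = 1e-12


@dataclass(frozen=True)
class PhotophysicsParams:
    """Rate constants of the Dendra2 photophysical model plus camera framing.

    Parameters
    ----------
    k_on : float
        Photo-conversion (activation) rate, s^-1.
    k_dark : float
        on -> reversible dark (blinking) rate, s^-1.
    k_bleach : float
        on -> irreversible bleached rate, s^-1.
    k_rev : float
        dark -> on recovery rate, s^-1.
    frame_time : float
        Camera exposure per frame, s.
    """

    k_on: float = 0.0067
    k_dark: float = 9.6
    k_bleach: float = 3.0
    k_rev: float = 2.33
    frame_time: float = 0.06

    def __post_init__(self) -> None:
        for name in ("k_on", "k_dark", "k_bleach", "k_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.frame_time <= 0:
            raise ValueError(f"frame_time must be > 0, got {self.frame_time}")

    @property
    def k_off(self) -> float:
        """Total rate of leaving the on state, s^-1."""
        return self.k_dark + self.k_bleach

    def replace(self, **kwargs) -> "PhotophysicsParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


#: Measured Dendra2 rates with 60 ms camera frames.
DENDRA2 = PhotophysicsParams()


@dataclass
class MoleculeTrajectory:
    """One molecule's state history as (state, entry time) pairs.

    The trajectory starts unconverted at the window start and is
    truncated at the window end (molecules are removed instantly when
    the observation/cluster window closes).
    """

    states: list
    times: np.ndarray
    window: tuple

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.states) != len(self.times):
            raise ValueError("states and times must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("entry times must be strictly increasing")

    def on_intervals(self) -> np.ndarray:
        """Emitting intervals as an (n, 2) array of [start, stop) times."""
        out = []
        t_end = self.window[1]
        for i, state in enumerate(self.states):
            if state != ON:
                continue
            start = self.times[i]
            stop = self.times[i + 1] if i + 1 < len(self.times) else t_end
            if stop > start:
                out.append((start, min(stop, t_end)))
        return np.asarray(out, dtype=float).reshape(-1, 2)

    @property
    def final_state(self) -> str:
        return self.states[-1]

    def total_on_time(self) -> float:
        iv = self.on_intervals()
        return float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0

    def n_dark_excursions(self) -> int:
        return sum(1 for s in self.states if s == DARK)


@dataclass(frozen=True)
class ClusterScenario:
    """A cluster of ``n_molecules`` recruited at ``t_assemble`` and
    (optionally) released at ``t_disassemble``, observed for ``total_time``."""

    n_molecules: int
    t_assemble: float = 0.0
    t_disassemble: float | None = None
    total_time: float = 300.0

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        t_dis = self.t_disassemble
        if t_dis is not None and not (self.t_assemble < t_dis <= self.total_time):
            raise ValueError(
                "need 0 <= t_assemble < t_disassemble <= total_time, got "
                f"{self.t_assemble}, {t_dis}, {self.total_time}"
            )
        if not (0 <= self.t_assemble <= self.total_time):
            raise ValueError("t_assemble must lie within [0, total_time]")

    @property
    def t_end(self) -> float:
        return self.total_time if self.t_disassemble is None else self.t_disassemble


@dataclass
class CumulantTrace:
    """Per-frame (collapsed) detection counts and their running sum.

    The cumulant — the sum of all detections counted from the start of
    acquisition — is the central tcPALM observable: its slope tracks the
    local concentration of labelled molecules, a burst of clustering
    shows up as a steep rise, and cluster dissolution as a plateau.
    """

    counts: np.ndarray
    frame_time: float
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Frame start times, s."""
        return np.arange(self.n_frames) * self.frame_time

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_molecule(
    params: PhotophysicsParams,
    window: tuple,
    seed=None,
) -> MoleculeTrajectory:
    """Simulate one molecule's state trajectory over ``window`` (Gillespie).

    The molecule appears unconverted at ``window[0]`` and is removed at
    ``window[1]``; all waiting times are exponential with the rates in
    ``params``.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not np.isfinite(t0) or not np.isfinite(t1) or t1 < t0:
        raise ValueError(f"invalid window {window}")
    rng = _as_rng(seed)

    states = [UNCONVERTED]
    times = [t0]
    t = t0
    state = UNCONVERTED
    while True:
        if state == UNCONVERTED:
            if params.k_on == 0:
                break
            t = t + rng.exponential(1.0 / params.k_on)
            nxt = ON
        elif state == ON:
            if params.k_off == 0:
                break
            t = t + rng.exponential(1.0 / params.k_off)
            p_dark = params.k_dark / params.k_off
            nxt = DARK if rng.random() < p_dark else BLEACHED
        elif state == DARK:
            if params.k_rev == 0:
                break
            t = t + rng.exponential(1.0 / params.k_rev)
            nxt = ON
        else:  # bleached is absorbing
            break
        if t >= t1:
            break
        states.append(nxt)
        times.append(t)
        state = nxt
    return MoleculeTrajectory(states=states, times=np.array(times), window=(t0, t1))


def simulate_molecules(
    n: int,
    params: PhotophysicsParams,
    window: tuple,
    rng: np.random.Generator,
) -> tuple:
    """Vectorized batch of ``n`` independent molecules over ``window``.

    Returns ``(mol_id, start, stop)`` arrays describing every emitting
    interval, clipped to the window; ``mol_id`` indexes the original
    ``0..n-1`` molecules (molecules never activated simply contribute no
    intervals).  Statistically identical to calling
    :func:`simulate_molecule` ``n`` times, but orders of magnitude
    faster for the large batches used in cluster simulation and
    simulation-matching molecular counting.
    """
    t0, t1 = float(window[0]), float(window[1])
    span = t1 - t0
    if span <= 0 or n == 0 or params.k_on == 0:
        e = np.empty(0)
        return e.astype(int), e, e

    # Activation times (memoryless; molecules never activated are dropped).
    t_act_all = t0 + rng.exponential(1.0 / params.k_on, size=n)
    ids = np.flatnonzero(t_act_all < t1)
    t_act = t_act_all[ids]
    m = len(ids)
    if m == 0:
        e = np.empty(0)
        return e.astype(int), e, e

    if params.k_off == 0:
        # Once on, molecules emit until the window closes.
        return ids, t_act, np.full(m, t1)

    p_bleach = params.k_bleach / params.k_off
    # Number of bright periods before bleaching ~ Geometric(p_bleach);
    # when bleaching is impossible, cap by the number of on/dark cycles
    # that can fit in the window and extend if a molecule outruns the cap.
    if p_bleach > 0:
        n_bright = rng.geometric(p_bleach, size=m)
    else:
        mean_cycle = 1.0 / params.k_off + (1.0 / params.k_rev if params.k_rev > 0 else np.inf)
        if not np.isfinite(mean_cycle):  # stuck in dark forever after first period
            n_bright = np.ones(m, dtype=int)
        else:
            n_bright = np.full(m, max(8, int(4 * span / mean_cycle) + 8))

    pos = np.repeat(np.arange(m), n_bright)
    mol_id = ids[pos]
    total = len(pos)
    bright = rng.exponential(1.0 / params.k_off, size=total)
    if params.k_rev > 0:
        dark = rng.exponential(1.0 / params.k_rev, size=total)
    else:
        dark = np.full(total, np.inf)

    # Within each molecule, bright period j starts after the cumulative
    # previous bright+dark durations; flattened segmented cumsum.
    cycle = bright + dark
    cum = np.cumsum(cycle)
    first = np.concatenate(([0], np.cumsum(n_bright)[:-1]))
    offset = np.repeat(cum[first] - cycle[first], n_bright)
    prev = np.concatenate(([0.0], cum[:-1]))
    start_rel = prev - offset  # start of each bright period relative to activation
    starts = t_act[pos] + start_rel
    stops = starts + bright

    keep = starts < t1
    mol_id, starts, stops = mol_id[keep], starts[keep], np.minimum(stops[keep], t1)
    keep = stops > starts
    return mol_id[keep], starts[keep], stops[keep]


# ---------------------------------------------------------------------------
# Camera binning
# ---------------------------------------------------------------------------

def _detected_frame_ranges(
    starts: np.ndarray, stops: np.ndarray, frame_time: float
) -> tuple:
    """First/last frame in which each on-interval is detected.

    A frame registers the interval only when their overlap is at least
    half a frame; returns ``(f0, f1)`` with empty intervals flagged by
    ``f0 > f1``.
    """
    dt = frame_time
    half = dt / 2.0 - _HALF_FRAME_TOL
    fa = np.floor(starts / dt).astype(np.int64)
    # last frame index with any overlap (handles stops on a boundary)
    fb = np.ceil(stops / dt).astype(np.int64) - 1
    fb = np.maximum(fb, fa)
    ov_first = np.minimum(stops, (fa + 1) * dt) - starts
    ov_last = stops - np.maximum(starts, fb * dt)
    f0 = np.where(ov_first >= half, fa, fa + 1)
    f1 = np.where(ov_last >= half, fb, fb - 1)
    return f0, f1


def _collapse_intervals_to_frames(
    starts: np.ndarray, stops: np.ndarray, frame_time: float, n_frames: int
) -> np.ndarray:
    """Per-frame detection counts in {0, 1} from a set of on-intervals."""
    counts = np.zeros(n_frames, dtype=np.int64)
    if len(starts) == 0:
        return counts
    f0, f1 = _detected_frame_ranges(starts, stops, frame_time)
    f0 = np.clip(f0, 0, n_frames)
    f1 = np.clip(f1, -1, n_frames - 1)
    good = f0 <= f1
    f0, f1 = f0[good], f1[good]
    if len(f0) == 0:
        return counts
    diff = np.zeros(n_frames + 1, dtype=np.int64)
    np.add.at(diff, f0, 1)
    np.add.at(diff, f1 + 1, -1)
    covered = np.cumsum(diff[:-1])
    return (covered > 0).astype(np.int64)


def bin_detections(
    trajectories: Iterable[MoleculeTrajectory],
    params: PhotophysicsParams,
    n_frames: int | None = None,
) -> np.ndarray:
    """Per-frame detection counts from molecule trajectories.

    Applies the camera model: an on-interval is registered in a frame
    only when it overlaps it by at least ``frame_time / 2``, and
    simultaneous detections of several molecules in a frame collapse to
    a single count, so counts are in {0, 1}.
    """
    trajectories = list(trajectories)
    if n_frames is None:
        t_max = max((tr.window[1] for tr in trajectories), default=0.0)
        n_frames = int(np.ceil(t_max / params.frame_time)) if t_max > 0 else 0
    iv = [tr.on_intervals() for tr in trajectories]
    iv = [a for a in iv if len(a)]
    if not iv:
        return np.zeros(n_frames, dtype=np.int64)
    allint = np.vstack(iv)
    return _collapse_intervals_to_frames(
        allint[:, 0], allint[:, 1], params.frame_time, n_frames
    )


def simulate_cluster_trace(
    scenario: ClusterScenario,
    params: PhotophysicsParams,
    seed=None,
) -> CumulantTrace:
    """Simulate a cluster scenario and return its detection-count trace.

    ``scenario.n_molecules`` molecules appear at ``t_assemble``; at
    ``t_disassemble`` (if set) they are removed instantly in whatever
    state they are in, so no detections occur outside the cluster's
    life.  Counts are camera-binned and collapsed as in
    :func:`bin_detections`.
    """
    rng = _as_rng(seed)
    n_frames = int(np.ceil(scenario.total_time / params.frame_time))
    _, starts, stops = simulate_molecules(
        scenario.n_molecules, params, (scenario.t_assemble, scenario.t_end), rng
    )
    counts = _collapse_intervals_to_frames(starts, stops, params.frame_time, n_frames)
    return CumulantTrace(counts=counts, frame_time=params.frame_time)


# ---------------------------------------------------------------------------
# Spatial localization fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialCluster:
    """A spatial cluster emitting detections around ``center`` during frames
    ``[frame_start, frame_stop)`` with Poisson-mean ``n_detections``."""

    center: tuple
    n_detections: float
    frame_start: int = 0
    frame_stop: int | None = None
    spread_nm: float = 0.0  # physical cluster extent (std), on top of loc. error


def sample_spatial_field(
    clusters: Sequence[SpatialCluster],
    background_density: float,
    sigma_loc: float,
    n_frames: int,
    extent: tuple,
    frame_time: float = 0.06,
    seed=None,
):
    """Generate a localization table for clusters plus random background.

    Parameters
    ----------
    clusters : sequence of SpatialCluster
        Cluster specifications; each produces Poisson(``n_detections``)
        detections at its centre (plus physical spread), each displaced
        by isotropic Gaussian localization error ``sigma_loc``.
    background_density : float
        Mean background detections per nm^2 over the whole acquisition
        (complete spatial randomness, uniform in time).
    sigma_loc : float
        Localization error (std per axis), nm.
    n_frames : int
        Acquisition length in frames.
    extent : (width, height)
        Field size in nm; the field is [0, W] x [0, H].
    frame_time : float
        Frame exposure, s.
    seed : int, Generator, optional

    Returns
    -------
    pandas.DataFrame
        Columns ``frame, t_s, x_nm, y_nm, photons, sigma_nm``.
    """
    import pandas as pd

    w, h = float(extent[0]), float(extent[1])
    if w <= 0 or h <= 0:
        raise ValueError(f"field extent must be positive, got {extent}")
    if background_density < 0 or sigma_loc < 0:
        raise ValueError("densities and sigma must be >= 0")
    rng = _as_rng(seed)

    frames, xs, ys = [], [], []
    for c in clusters:
        k = rng.poisson(c.n_detections)
        if k == 0:
            continue
        stop = n_frames if c.frame_stop is None else c.frame_stop
        fr = rng.integers(c.frame_start, max(stop, c.frame_start + 1), size=k)
        spread = np.hypot(c.spread_nm, sigma_loc)
        xs.append(c.center[0] + rng.normal(0, spread, size=k))
        ys.append(c.center[1] + rng.normal(0, spread, size=k))
        frames.append(fr)
    n_bg = rng.poisson(background_density * w * h)
    if n_bg:
        xs.append(rng.uniform(0, w, size=n_bg))
        ys.append(rng.uniform(0, h, size=n_bg))
        frames.append(rng.integers(0, n_frames, size=n_bg))

    if frames:
        frame = np.concatenate(frames)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        frame = np.empty(0, dtype=int)
        x = y = np.empty(0)
    order = np.argsort(frame, kind="stable")
    frame, x, y = frame[order], x[order], y[order]
    n = len(frame)
    return pd.DataFrame(
        {
            "frame": frame.astype(int),
            "t_s": frame * frame_time,
            "x_nm": x,
            "y_nm": y,
            "photons": np.full(n, 1000.0),
            "sigma_nm": np.full(n, max(sigma_loc, 1e-9)),
        }
    )


# ---------------------------------------------------------------------------
# mRNA locus image stacks
# ---------------------------------------------------------------------------

def _gaussian_spot(shape: tuple, center: tuple, sigma: float, flux: float) -> np.ndarray:
    """Pixel-integrated 2-D Gaussian with total integral ``flux``."""
    ny, nx = shape
    cx, cy = center
    xe = np.arange(nx + 1) - 0.5  # pixel i covers [i-0.5, i+0.5)
    ye = np.arange(ny + 1) - 0.5
    fx = 0.5 * (special.erf((xe[1:] - cx) / (np.sqrt(2) * sigma))
                - special.erf((xe[:-1] - cx) / (np.sqrt(2) * sigma)))
    fy = 0.5 * (special.erf((ye[1:] - cy) / (np.sqrt(2) * sigma))
                - special.erf((ye[:-1] - cy) / (np.sqrt(2) * sigma)))
    return flux * np.outer(fy, fx)


def render_locus_stack(
    loci: Sequence[tuple],
    unit_brightness: float,
    psf_sigma_px: float,
    background_level: float,
    shape: tuple = (64, 64),
    n_frames: int = 100,
    noise: str = "poisson-gaussian",
    read_noise_sd: float = 2.0,
    seed=None,
) -> np.ndarray:
    """Render an image stack of mRNA loci as diffraction-limited spots.

    Each locus is ``(x_px, y_px, mrna_count)``; each mRNA contributes
    one PSF (pixel-integrated Gaussian of std ``psf_sigma_px``) whose
    total flux equals ``unit_brightness``.  Noise defaults to Poisson
    shot noise plus Gaussian read noise (a generic EM-CCD proxy); use
    ``noise="none"`` for deterministic fixtures.

    Returns a float ``(n_frames, ny, nx)`` array.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    if any(l[2] < 0 for l in loci):
        raise ValueError("mRNA counts must be >= 0")
    rng = _as_rng(seed)
    ny, nx = shape
    clean = np.full((ny, nx), float(background_level))
    for x, y, count in loci:
        if count > 0:
            clean += _gaussian_spot((ny, nx), (x, y), psf_sigma_px, unit_brightness * count)
    stack = np.broadcast_to(clean, (n_frames, ny, nx)).copy()
    if noise == "none":
        return stack
    if noise == "poisson-gaussian":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        stack += rng.normal(0.0, read_noise_sd, size=stack.shape)
        return stack
    raise ValueError(f"unknown noise model: {noise!r}")
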