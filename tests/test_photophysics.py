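"""Gillespie simulator, camera binning and synthetic generators."""

import numpy as np
import pytest
from scipy import special

from tcpalm import (
    ClusterScenario,
    MoleculeTrajectory,
    PhotophysicsParams,
    SpatialCluster,
    bin_detections,
    render_locus_stack,
    sample_spatial_field,
    simulate_cluster_trace,
    simulate_molecule,
    simulate_molecules,
)

LEGAL = {
    "unconverted": {"on"},
    "on": {"dark", "bleached"},
    "dark": {"on"},
    "bleached": set(),
}


class TestParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PhotophysicsParams(k_on=-1.0)

    def test_zero_frame_time_rejected(self):
        with pytest.raises(ValueError):
            PhotophysicsParams(frame_time=0.0)

    def test_inverted_window_rejected(self, dendra2):
        with pytest.raises(ValueError):
            simulate_molecule(dendra2, (10.0, 5.0), seed=0)


class TestTrajectories:
    def test_no_activation_without_k_on(self, dendra2):
        p = dendra2.replace(k_on=0.0)
        tr = simulate_molecule(p, (0.0, 100.0), seed=0)
        assert tr.states == ["unconverted"]
        assert tr.total_on_time() == 0.0

    def test_transitions_legal_and_times_increasing(self, dendra2):
        for seed in range(50):
            tr = simulate_molecule(dendra2, (0.0, 500.0), seed=seed)
            assert tr.states[0] == "unconverted"
            assert np.all(np.diff(tr.times) > 0)
            assert tr.times[0] >= 0.0 and tr.times[-1] <= 500.0
            for a, b in zip(tr.states[:-1], tr.states[1:]):
                assert b in LEGAL[a], f"illegal transition {a} -> {b}"

    def test_absorbing_end_state_on_long_horizon(self, dendra2):
        # with activation and bleaching possible, every molecule ends
        # unconverted (never activated) or bleached
        for seed in range(30):
            tr = simulate_molecule(dendra2, (0.0, 5000.0), seed=seed)
            assert tr.final_state in ("unconverted", "bleached")

    def test_activated_fraction_matches_closed_form(self, dendra2, rng):
        # fraction activated in 10 s is 1 - exp(-k_on * 10) ~ 6.5%
        n = 20000
        ids, a, b = simulate_molecules(n, dendra2, (0.0, 10.0), rng)
        frac = len(np.unique(ids)) / n
        expect = 1.0 - np.exp(-dendra2.k_on * 10.0)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 4 * se

    def test_mean_blinks_matches_geometric_branching(self, dendra2):
        # dark excursions before bleaching: mean k_dark / k_bleach = 3.2
        rng = np.random.default_rng(99)
        blinks = []
        for _ in range(3000):
            tr = simulate_molecule(dendra2, (0.0, 3000.0), seed=rng)
            if tr.final_state == "bleached":
                blinks.append(tr.n_dark_excursions())
        mean = np.mean(blinks)
        expect = dendra2.k_dark / dendra2.k_bleach
        se = np.std(blinks, ddof=1) / np.sqrt(len(blinks))
        assert abs(mean - expect) < 3 * se

    def test_dwell_time_means(self, dendra2, rng):
        # bright dwell 1/(k_dark+k_bleach), dark dwell 1/k_rev
        _, a, b = simulate_molecules(20000, dendra2, (0.0, 3000.0), rng)
        bright = b - a
        # drop window-truncated intervals (b == t1)
        keep = b < 3000.0
        bright = bright[keep]
        mb = bright.mean()
        expect = 1.0 / dendra2.k_off
        assert abs(mb - expect) < 3 * bright.std(ddof=1) / np.sqrt(len(bright))

    def test_batch_agrees_with_scalar_simulator(self, dendra2):
        # same physics, different implementations: compare mean total
        # emitting time per molecule
        rng = np.random.default_rng(3)
        _, a, b = simulate_molecules(5000, dendra2, (0.0, 600.0), rng)
        batch_mean = (b - a).sum() / 5000
        scal = [
            simulate_molecule(dendra2, (0.0, 600.0), seed=rng).total_on_time()
            for _ in range(3000)
        ]
        se = np.std(scal, ddof=1) / np.sqrt(len(scal))
        assert abs(batch_mean - np.mean(scal)) < 4 * se

    def test_seed_determinism(self, dendra2):
        a = simulate_molecule(dendra2, (0.0, 100.0), seed=42)
        b = simulate_molecule(dendra2, (0.0, 100.0), seed=42)
        assert a.states == b.states
        assert np.array_equal(a.times, b.times)


def _traj(intervals, window):
    """Hand-built trajectory emitting exactly in the given intervals."""
    states, times = ["unconverted"], [window[0]]
    t_prev = window[0]
    for a, b in intervals:
        states += ["on", "dark"]
        times += [a, b]
    return MoleculeTrajectory(states=states, times=np.array(times), window=window)


class TestBinning:
    def test_empty_input_gives_zeros(self, dendra2):
        counts = bin_detections([], dendra2, n_frames=100)
        assert counts.shape == (100,)
        assert counts.sum() == 0

    def test_simultaneous_molecules_collapse_to_one(self, dendra2):
        t1 = _traj([(0.60, 0.72)], (0.0, 6.0))
        t2 = _traj([(0.60, 0.72)], (0.0, 6.0))
        counts = bin_detections([t1, t2], dendra2, n_frames=100)
        assert counts.max() == 1
        assert counts[10] == 1 and counts[11] == 1

    def test_short_blink_undetected(self, dendra2):
        # a 20 ms on-interval never overlaps any 60 ms frame by >= 30 ms
        tr = _traj([(0.10, 0.12)], (0.0, 6.0))
        assert bin_detections([tr], dendra2, n_frames=100).sum() == 0

    def test_half_frame_boundary_included(self, dendra2):
        # exactly 30 ms inside frame 1 counts (>= rule)
        tr = _traj([(0.06, 0.09)], (0.0, 6.0))
        counts = bin_detections([tr], dendra2, n_frames=100)
        assert counts[1] == 1 and counts.sum() == 1

    def test_long_interval_covers_contiguous_frames(self, dendra2):
        tr = _traj([(0.06, 0.66)], (0.0, 6.0))
        counts = bin_detections([tr], dendra2, n_frames=100)
        assert counts[1:11].sum() == 10
        assert counts.sum() == 10


class TestClusterTrace:
    def test_zero_molecules_zero_cumulant(self, dendra2):
        tr = simulate_cluster_trace(ClusterScenario(0, 0, None, 60.0), dendra2, seed=0)
        assert tr.cumulative[-1] == 0

    def test_cumulant_shape_properties(self, dendra2):
        scen = ClusterScenario(100, 200.0, 210.0, 600.0)
        tr = simulate_cluster_trace(scen, dendra2, seed=1)
        cum = tr.cumulative
        assert np.all(np.diff(cum) >= 0)
        assert np.all(np.diff(cum) <= 1)  # collapsed counts
        first_frame = int(200.0 / dendra2.frame_time)
        assert cum[first_frame - 1] == 0  # silent before assembly
        last = int(210.0 / dendra2.frame_time) + 1
        assert cum[-1] == cum[last]  # flat after disassembly

    def test_static_activation_fraction_800s(self, dendra2):
        # ~99.5% of molecules yield at least one detection over 800 s
        got = 0
        n_tot = 2000
        rng = np.random.default_rng(5)
        ids, a, b = simulate_molecules(n_tot, dendra2, (0.0, 800.0), rng)
        frac = len(np.unique(ids)) / n_tot
        expect = 1.0 - np.exp(-dendra2.k_on * 800.0)
        assert abs(frac - expect) < 0.01

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            ClusterScenario(10, 50.0, 40.0, 100.0)
        with pytest.raises(ValueError):
            ClusterScenario(-1, 0.0, None, 100.0)

    def test_seeded_reproducibility(self, dendra2):
        scen = ClusterScenario(50, 10.0, 20.0, 100.0)
        a = simulate_cluster_trace(scen, dendra2, seed=7)
        b = simulate_cluster_trace(scen, dendra2, seed=7)
        assert np.array_equal(a.counts, b.counts)


class TestSpatialField:
    def test_empty_field(self, dendra2):
        df = sample_spatial_field([], 0.0, 20.0, 100, (1000.0, 1000.0), seed=0)
        assert len(df) == 0

    def test_bad_extent_rejected(self):
        with pytest.raises(ValueError):
            sample_spatial_field([], 0.0, 20.0, 100, (0.0, 1000.0), seed=0)

    def test_cluster_counts_poisson(self):
        cl = SpatialCluster(center=(500.0, 500.0), n_detections=50.0)
        ns = [
            len(sample_spatial_field([cl], 0.0, 20.0, 100, (1000.0, 1000.0), seed=s))
            for s in range(200)
        ]
        mean, var = np.mean(ns), np.var(ns, ddof=1)
        assert abs(mean - 50.0) < 3 * np.sqrt(50.0 / 200)
        assert 0.6 < var / mean < 1.5  # Poisson dispersion

    def test_positions_scatter_around_center(self):
        cl = SpatialCluster(center=(800.0, 300.0), n_detections=500.0)
        df = sample_spatial_field([cl], 0.0, 25.0, 100, (2000.0, 2000.0), seed=1)
        assert abs(df["x_nm"].mean() - 800.0) < 5
        assert abs(df["x_nm"].std() - 25.0) < 4


class TestLocusStack:
    def test_zero_counts_pure_background(self):
        stack = render_locus_stack(
            [(32.0, 32.0, 0)], 1000.0, 1.2, 50.0, noise="none", seed=0
        )
        assert np.allclose(stack, 50.0)

    def test_single_emitter_window_mass_matches_erf_oracle(self):
        unit, sigma = 2000.0, 1.2
        stack = render_locus_stack(
            [(32.0, 32.0, 1)], unit, sigma, 0.0, noise="none", seed=0
        )
        win = stack[0, 31:34, 31:34].sum()
        # Gaussian mass inside +/-1.5 px of center, per axis
        mass1d = special.erf(1.5 / (np.sqrt(2) * sigma))
        assert win == pytest.approx(unit * mass1d**2, rel=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            render_locus_stack([(10.0, 10.0, -1)], 1.0, 1.0, 0.0)

    def test_noise_seeded(self):
        a = render_locus_stack([(32.0, 32.0, 3)], 500.0, 1.2, 20.0, seed=3)
        b = render_locus_stack([(32.0, 32.0, 3)], 500.0, 1.2, 20.0, seed=3)
        assert np.array_equal(a, b)
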