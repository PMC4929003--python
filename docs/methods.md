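# Methods

This note documents the models, estimators and numerical choices behind the
package, including the assumptions a user should know before trusting results
on their own data.

## Dendra2 photophysics and the camera model

A molecule moves through four states: *unconverted* → *on* (activation,
`k_on`), *on* → *dark* (blinking, `k_dark`) or *on* → *bleached*
(irreversible, `k_bleach`), *dark* → *on* (recovery, `k_rev`).  All waiting
times are exponential; trajectories are simulated exactly (Gillespie), either
one molecule at a time or in vectorized batches that draw the geometric number
of bright periods and all dwell times at once (the batch form is what makes
simulation-matching counting affordable).  Defaults are the measured Dendra2
rates: `k_on = 0.0067 s⁻¹`, `k_dark = 9.6 s⁻¹`, `k_bleach = 3 s⁻¹`,
`k_rev = 2.33 s⁻¹`, 60 ms frames.  Useful consequences: a mean bright dwell
of `1/(k_dark+k_bleach) ≈ 79 ms`, a mean of `k_dark/k_bleach = 3.2` dark
excursions before bleaching, and an activated fraction `1 − exp(−k_on t)`
(≈6.5% after 10 s, ≈99.5% after 800 s).

The camera model has two rules, both applied to every emitting interval: an
interval registers in a frame only if it overlaps it by at least half a frame
(limited sensitivity), and any number of simultaneously emitting molecules in
a frame produce a single count (detection counting ignores spot intensity).
Per-frame counts are therefore binary.  Cluster scenarios remove molecules
instantly at disassembly, in whatever state they are; whether an unconverted
molecule removed at disassembly could have re-entered later is unknowable
from the data, and the generator assumes it cannot.

The generator does **not** emulate diffusing (motion-blurred) molecules,
EM-gain statistics, drift, or axial structure.  Rendered mRNA stacks use
pixel-integrated Gaussian PSFs with Poisson shot noise plus Gaussian read
noise as a generic EM-CCD proxy.  Tests that pass on these synthetic inputs
validate the estimators under the stated photophysical model; they do not
guarantee robustness to aberrations the generator omits.

## Cluster-event detection on cumulant traces

The cumulant (running detection sum) of an ROI is segmented by penalized
least-squares piecewise-linear optimal partitioning (dynamic program, O(1)
interval costs from prefix sums, ties broken toward the earlier frame) on a
0.6 s grid.  The per-change-point penalty defaults to
`3 · σ̂² · log(n)`, with `σ̂²` a robust noise estimate from second differences
of the binned trace (floored at 0.25).  Over-segmentation is cheap here —
adjacent burst segments re-merge — so the penalty errs low.

A segment is a *burst* when its slope exceeds `5×` the background rate.  The
background is the 10th percentile of per-bin rates (the trace-wide mean for
sparse traces); a median would sit on the cluster rate itself whenever a
stable structure spans the whole acquisition.  Collapsed counting saturates
at one detection per frame, so if the threshold exceeds that rate the trace
is active nearly everywhere and the detector treats the active span as a
single event — the "slope onset from the beginning of acquisition, gradual
plateau" signature of stable (chromatin-like or drug-stabilized) structures.

Event edges carry a renewal **dead-time correction**.  Detections arrive in
blink trains paced by photo-conversion; the cluster exists for about one mean
inter-train wait before its first detection and after its last.  Gaps longer
than `train_gap = 0.5 s` are treated as inter-train waits; by memorylessness
their mean excess over the threshold estimates the censored wait, pooled over
the trace's events and capped at 1.5 s per edge.  Without this correction the
detected lifetime of a 10 s, 100-molecule cluster is biased to ~7.2 s; with
it the mean is ~9 s and ~83% of acquisitions land within ±30% of the truth
(an oracle that knows the true conversion pacing reaches 91% — the residual
gap is small-sample noise in the per-trace wait estimate).  The onset of a
cluster remains fundamentally uncertain by the wait for its first conversion
(mean ~1.5 s for 100 molecules), which no estimator can remove.

Detector defaults (penalty factor, train gap, cap, straggler attachment
window of 4 s) were calibrated on simulated dynamic-cluster scenarios and
verified on held-out seeds.  Burst size is the number of collapsed detections
in the event; clustering strength is size/lifetime; events below 5 detections
are suppressed; onset within 1 s of acquisition start classifies an event as
pre-existing.

## Molecular counting

`fit_photophysics` inverts dwell moments: mean bright dwell →
`k_dark + k_bleach`, mean blink count → `k_dark/k_bleach`, mean dark dwell →
`k_rev`, censored-exponential MLE for `k_on`.  The inversion is exact on dwell
times; at 60 ms frames the bright dwell (~79 ms) is comparable to the frame,
~30% of bright periods fall under the half-frame sensitivity limit, and short
dark excursions are swallowed, so moments from coarse-framed traces are
biased.  Rate estimation from real 60 ms data should be treated as effective
rather than microscopic; the recovery test uses finer framing to validate the
inversion itself.

`estimate_count` scores each candidate N by the mean absolute deviation
between the observed cumulant and 100 simulated static-cluster cumulants
(coarse logarithmic scan, then unit-step refinement around the minimum;
simulated assembly aligned to the observed onset, cumulative curves compared
as displayed in practice).  Precision is limited by physics, not by the
matcher: the number of detections one molecule produces has CV ≈ 1 (dominated
by the geometric blink count), so any estimator seeing a single cluster
realization has `sd(N̂)/N ≈ 1/√N` — about ±10% at N = 80 but ±45% at N = 5.
Counts for small clusters are individually noisy and should be averaged over
loci.

## Pair-correlation decomposition

The empirical g(r) uses toroidal (translation) edge correction on a
rectangular window, 10 nm bins to 500 nm, normalized so CSR gives 1.  The
fitted model is `g(r) = 1 + A_s·exp(−r²/4σ²) + [protein ⊛ kernel](r)`: the
stochastic term is the autocorrelation of one molecule's repeated
localizations (width fixed by the localization precision σ), and the protein
term (exponential `A·e^{−r/ξ}` by default, Gaussian cluster model by option)
is convolved with the pairwise localization kernel (variance 2σ², computed by
Hankel-type quadrature with exponentially scaled Bessel functions).  Bins are
weighted by Poisson pair-count noise.  ξ is bounded below by 3σ: protein
structure below the localization scale is not identifiable against blinking,
and without the bound the two components can trade off freely.

## Cluster-gated transcription model

Clusters arrive as a Poisson process at `f = 0.2 min⁻¹`; a cluster arriving
at time t lasts `τ(t) = τ_b + (τ_p − τ_b)·exp(−(t−t_p)²/2w²)` with
`τ_b = 6.9 s`, `τ_p = 24 s`, `t_p = 12.5 min`, and width `w = 4 min` — the
width is a shape parameter chosen so the response spans roughly the first
half hour after stimulation, not a measured constant.  While a cluster is
present, productive Pol II initiate as a Poisson process with mean interval
2.5 s ("loaded stochastically with an effective rate"); the gene is silent
otherwise.  Each initiation contributes a deterministic MS2 fluorescence
profile: zero until the polymerase reaches the cassette (`L_pre = 3400 bp`
at `v = 3.1 kbp/min`, ≈66 s), a linear ramp across the cassette
(`L_cassette = 1300 bp`), full brightness past the gene end
(`L_post = 300 bp`) plus a residence time `t_release_extra = 30 s`, then
release.  `L_cassette`, `L_post` and the residence are documented assumptions
(construct-geometry values of this order, not measured here); the model lag
moves by about +0.25 min per +30 s of residence and is 2.10 min at the
default, 1.84 min with no residence at all.

Overlapping clusters are allowed (Poisson superposition).  An
exclusion rule (discarding arrivals during an active cluster) would make the
effective arrival rate `f/(1+fτ)` and bend the input-output relation by ~20%
at 4× lifetime; superposition keeps the model exactly linear in τ — the
property the data exhibit — and is indistinguishable from exclusion in the
realistic regime (fτ ≈ 0.02–0.08).

The expected mean course has a closed form used as a test oracle: the
expected initiation rate is `(f/60)·(1/2.5)·cover(s)` with
`cover(s) = s − a*(s)`, `a*` the root of `a + τ(a) = s`, convolved with the
single-chain profile.  A caution that cost a round of debugging: the course
is within 0.4% of its maximum for a full minute, so peak positions read from
coarse grids or noisy means are ill-conditioned.  Peak lags are therefore
measured by a local quadratic vertex (±3 min window) on well-averaged
courses; the model's input→output lag under the defaults is 2.1 min
(experimentally the corresponding delay is ~2.5 min).

Fitting minimises the summed squared difference between the mean simulated
course (common random numbers, fixed seed) and an observed course, over any
subset of {v, loading interval, cluster frequency, residence} in log space —
a coarse coordinate-wise scan (factor-4 steps, two passes) followed by
Nelder–Mead, because the Monte-Carlo objective is slightly jagged at small
scales.  Only population-mean courses are fitted; single-cell trajectories
are out of scope.

A reversible CDK9 block (DRB-type) between `t_on` and `t_off` sets the
loading rate to zero and suspends the remaining lifetime of any cluster
overlapping the block; previously loaded polymerases elongate to completion,
so the nascent signal drains, and loading resumes on the held cluster after
release, producing a second burst whose timing follows the release time.  An
empty block is bit-identical to an unblocked run at the same seed.

## Nascent-mRNA quantification

Stacks are merged by per-pixel maximum projection; locus intensity is the
3×3-pixel window sum minus 9× the background mean (dimensional consistency:
the background is per pixel).  Background defaults to the median of pixels
outside a 7×7 exclusion zone around each locus — a robust choice the source
protocol leaves unspecified.  Counts are net intensity divided by the mean
single-mRNA net intensity, floored at zero and reported as real numbers.
Because the max projection inflates both locus and background pixels under
noise, the unit reference must be measured through the same projection
pipeline as the loci; the stage runner takes the unit as an input for this
reason.

## Degenerate inputs and numerical conventions

Frames are 0-based with half-open time intervals `[f·Δ, (f+1)·Δ)`; half-frame
overlap uses a ≥ comparison with a 1 ps tolerance; positions are nm, pixel
units only in image quantification.  Empty traces yield empty event lists and
zero counts; an all-zero observed cumulant yields N̂ = 0; flat observed
courses are rejected as unidentifiable; correlations with fewer than three
pairs are flagged undefined.  All stochastic entry points take an integer
seed (or Generator) and are bit-reproducible; batch and scalar simulators are
statistically equivalent but draw in different orders, so they match in
distribution, not bitwise.

## Problem sizes in the test suite

The suite simulates at the sizes the statistics require rather than the sizes
the experiments used: closed-form checks with 10⁴–2×10⁴ molecules, lifetime
recovery over 500 seeded acquisitions, count recovery at N ∈ {5, 20, 80}
with 50 clusters each, model checks with 400–50 000 runs, pair-correlation
fields of a few thousand points.  Source-data-dependent checks (published
lifetime tables and binned courses) require the supplementary tables as CSV
under `data/source_data/` and report their absence explicitly rather than
silently passing.
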