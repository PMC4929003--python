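"""Cluster-gated transcription model: inputs, simulation, fitting."""

import numpy as np
import pytest

from tcpalm import (
    GeneGeometry,
    KineticParams,
    LifetimeProfile,
    NascentCourse,
    fit_kinetics,
    lifetime_input,
    lifetime_output_correlation,
    ms2_signal,
    packing_density,
    peak_lag,
    simulate_intervention,
    simulate_nascent_course,
)


def exact_mean_course(profile, geometry, kinetics, horizon_min=40.0, ds=0.1):
    """Deterministic expected course: coverage integral convolved with
    the single-chain MS2 response (independent oracle for the
    stochastic simulation).  The fine grid matters: the coverage curve
    is very flat near its peak, so coarse binning biases the argmax."""
    s = np.arange(0.0, horizon_min * 60.0, ds)
    a = np.arange(-600.0, horizon_min * 60.0, ds)
    tau = lifetime_input(a / 60.0, profile)
    cover = np.zeros_like(s)
    i0 = np.searchsorted(s, a)
    i1 = np.searchsorted(s, a + tau)
    for j0, j1 in zip(i0, i1):
        cover[j0:j1] += ds
    rate = (kinetics.cluster_frequency / 60.0) / kinetics.loading_interval * cover
    ages = np.arange(0.0, 600.0, ds)
    h = ms2_signal(ages, geometry, kinetics.v, kinetics.t_release_extra)
    mean = np.convolve(rate, h)[: len(s)] * ds
    return s / 60.0, mean


class TestLifetimeInput:
    def test_peak_value(self):
        prof = LifetimeProfile()
        assert lifetime_input(prof.t_peak, prof) == pytest.approx(24.0)

    def test_far_from_peak_is_basal(self):
        prof = LifetimeProfile()
        assert lifetime_input(200.0, prof) == pytest.approx(6.9, abs=1e-6)

    def test_flat_profile(self):
        prof = LifetimeProfile(tau_basal=10.0, tau_peak=10.0)
        t = np.linspace(0, 60, 7)
        assert np.allclose(lifetime_input(t, prof), 10.0)

    def test_invalid_profile(self):
        with pytest.raises(ValueError):
            LifetimeProfile(tau_basal=10.0, tau_peak=5.0)


class TestMs2Signal:
    def test_zero_at_birth_and_at_ramp_start(self):
        geom, v = GeneGeometry(), 3100.0 / 60.0
        assert ms2_signal(0.0, geom, v) == 0.0
        assert ms2_signal(geom.L_pre / v, geom, v) == 0.0

    def test_ramp_start_time_arithmetic(self):
        # 3400 bp at 3.1 kbp/min -> ~65.8 s
        v = 3100.0 / 60.0
        t1 = GeneGeometry().L_pre / v
        assert t1 == pytest.approx(65.8, abs=0.1)
        assert ms2_signal(t1 + 1.0, GeneGeometry(), v) > 0.0

    def test_full_brightness_then_release(self):
        geom, v = GeneGeometry(), 50.0
        t2 = (geom.L_pre + geom.L_cassette) / v
        t3 = (geom.L_pre + geom.L_cassette + geom.L_post) / v + 10.0
        assert ms2_signal(t2, geom, v, 10.0) == 1.0
        assert ms2_signal(t3 - 1e-6, geom, v, 10.0) == 1.0
        assert ms2_signal(t3, geom, v, 10.0) == 0.0


class TestPackingDensity:
    def test_printed_parameters_give_130bp(self):
        assert packing_density(3100.0 / 60.0, 2.5) == pytest.approx(129.2, abs=0.1)

    def test_arithmetic_and_degenerate(self):
        assert packing_density(3000.0 / 60.0, 2.5) == pytest.approx(125.0)
        assert packing_density(0.0, 2.5) == 0.0

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            packing_density(50.0, 0.0)


class TestSimulation:
    def test_no_clusters_no_output(self):
        kin = KineticParams(cluster_frequency=0.0)
        out = simulate_nascent_course(
            LifetimeProfile(), GeneGeometry(), kin, horizon_min=20, n_runs=20, seed=0
        )
        assert np.all(out.mean == 0.0)

    def test_stationary_mean_matches_littles_law(self):
        prof = LifetimeProfile(tau_basal=10.0, tau_peak=10.0)
        geom, kin = GeneGeometry(), KineticParams()
        out = simulate_nascent_course(prof, geom, kin, horizon_min=150, n_runs=400, seed=2)
        sim = out.mean[out.t_min > 10.0].mean()
        ages = np.linspace(0, 500, 20001)
        integral = np.trapezoid(ms2_signal(ages, geom, kin.v, kin.t_release_extra), ages)
        expect = (kin.cluster_frequency / 60.0) * 10.0 / kin.loading_interval * integral
        assert sim == pytest.approx(expect, rel=0.1)

    def test_simulated_course_matches_exact_expectation(self):
        prof, geom, kin = LifetimeProfile(), GeneGeometry(), KineticParams()
        out = simulate_nascent_course(prof, geom, kin, horizon_min=40, n_runs=3000, seed=3)
        t, exact = exact_mean_course(prof, geom, kin)
        on_grid = np.interp(out.t_min, t, exact)
        resid = out.mean - on_grid
        assert np.max(np.abs(resid)) < 0.15
        assert np.mean(np.abs(resid)) < 0.04

    def test_linearity_in_lifetime(self):
        geom, kin = GeneGeometry(), KineticParams()
        means = []
        for c in (1.0, 4.0):
            prof = LifetimeProfile(tau_basal=6.9 * c, tau_peak=6.9 * c)
            out = simulate_nascent_course(prof, geom, kin, horizon_min=120, n_runs=400, seed=4)
            means.append(out.mean[out.t_min > 8.0].mean())
        assert means[1] / means[0] == pytest.approx(4.0, rel=0.1)

    def test_lag_lower_bound_is_elongation_delay(self):
        # the output cannot peak before the cassette is transcribed
        for trel in (0.0, 60.0):
            kin = KineticParams(t_release_extra=trel)
            prof, geom = LifetimeProfile(), GeneGeometry()
            t, exact = exact_mean_course(prof, geom, kin)
            lag = t[np.argmax(exact)] - prof.t_peak
            assert lag >= geom.L_pre / kin.v / 60.0 - 1e-9

    def test_seeded_determinism(self):
        args = (LifetimeProfile(), GeneGeometry(), KineticParams())
        a = simulate_nascent_course(*args, horizon_min=20, n_runs=30, seed=5)
        b = simulate_nascent_course(*args, horizon_min=20, n_runs=30, seed=5)
        assert np.array_equal(a.mean, b.mean)


class TestIntervention:
    def test_empty_block_identical_to_plain_run(self):
        args = (LifetimeProfile(), GeneGeometry(), KineticParams())
        a = simulate_nascent_course(*args, horizon_min=30, n_runs=40, seed=6)
        b = simulate_intervention(*args, block_min=(10.0, 10.0), horizon_min=30, n_runs=40, seed=6)
        assert np.array_equal(a.mean, b.mean)

    def test_block_drains_nascent_pool(self):
        out = simulate_intervention(
            LifetimeProfile(),
            GeneGeometry(),
            KineticParams(),
            block_min=(10.0, 60.0),
            horizon_min=60,
            n_runs=300,
            seed=7,
        )
        before = out.mean[(out.t_min > 8) & (out.t_min < 10)].mean()
        after = out.mean[out.t_min > 20].mean()
        assert after < 0.05 * max(before, 1e-9) + 1e-3

    def test_second_burst_follows_release_time(self):
        peaks = []
        for rel in (15.0, 30.0):
            out = simulate_intervention(
                LifetimeProfile(),
                GeneGeometry(),
                KineticParams(),
                block_min=(10.0, rel),
                horizon_min=60,
                n_runs=400,
                seed=8,
            )
            m = np.where(out.t_min >= rel, out.mean, 0.0)
            peaks.append(float(out.t_min[np.argmax(m)]))
        assert peaks[1] > peaks[0]

    def test_inverted_block_rejected(self):
        with pytest.raises(ValueError):
            simulate_intervention(
                LifetimeProfile(), GeneGeometry(), KineticParams(),
                block_min=(20.0, 10.0), n_runs=5,
            )


class TestFitAndCorrelation:
    def test_elongation_rate_recovered(self):
        prof, geom = LifetimeProfile(), GeneGeometry()
        truth = KineticParams()
        obs = simulate_nascent_course(prof, geom, truth, horizon_min=40, n_runs=2000, seed=9)
        start = KineticParams(v=4500.0 / 60.0)
        best, fitted, report = fit_kinetics(
            obs, prof, geom, start, free=("v",), n_runs=400, seed=10
        )
        assert best.v == pytest.approx(truth.v, rel=0.15)

    def test_flat_course_unidentifiable(self):
        obs = NascentCourse(t_min=np.arange(8.0), mean=np.full(8, 2.0))
        with pytest.raises(ValueError):
            fit_kinetics(obs, LifetimeProfile(), GeneGeometry())

    def test_peak_lag_identical_curves_zero(self):
        t = np.arange(0.0, 30.0, 0.5)
        m = np.exp(-((t - 12.5) ** 2) / 8.0)
        c = NascentCourse(t_min=t, mean=m)
        assert peak_lag(c, c) == 0.0

    def test_peak_lag_binned_experimental_peaks(self):
        t = np.arange(0.0, 40.0, 2.5)
        inp = NascentCourse(t_min=t, mean=np.exp(-((t - 12.5) ** 2) / 30.0))
        out = NascentCourse(t_min=t, mean=np.exp(-((t - 15.0) ** 2) / 30.0))
        assert peak_lag(inp, out) == pytest.approx(2.5)

    def test_correlation_linear_pairs(self):
        t = np.arange(0.0, 30.0, 2.5)
        tau = 6.9 + 17.0 * np.exp(-((t - 12.5) ** 2) / 30.0)
        mrna = 0.7 * tau + 0.5
        a = NascentCourse(t_min=t, mean=tau)
        b = NascentCourse(t_min=t, mean=mrna)
        pairs, res = lifetime_output_correlation(a, b, lag_min=0.0)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.7)

    def test_correlation_permuted_near_zero(self, rng):
        t = np.arange(0.0, 100.0, 1.0)
        x = rng.normal(10, 2, len(t))
        y = rng.normal(5, 1, len(t))
        a = NascentCourse(t_min=t, mean=x)
        b = NascentCourse(t_min=t, mean=y)
        _, res = lifetime_output_correlation(a, b, lag_min=0.0, window_min=(0, 100))
        assert abs(res["r"]) < 0.25

    def test_correlation_needs_three_pairs(self):
        t = np.array([0.0, 1.0])
        a = NascentCourse(t_min=t, mean=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            lifetime_output_correlation(a, a, lag_min=0.0, window_min=(0, 1))
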