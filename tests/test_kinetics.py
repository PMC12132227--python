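import numpy as np
import pytest

import npqkin as nk
from npqkin.kinetics import (
    InsufficientDataError,
    QCThresholds,
    fit_cycles,
    r_squared,
)
from npqkin.protocol import DARK, LIGHT
from npqkin.simulate import npq_truth_series

from _oracles import (
    exponential_light_oracle,
    hyperbolic_dark_oracle,
    hyperbolic_light_oracle,
)

CROP_LIGHT_T = np.cumsum([15, 30, 30] + [60] * 10).astype(float)
CROP_DARK_T = np.cumsum([9, 15, 30, 60, 180, 300]).astype(float)


class TestInductionHyperbolic:
    def test_noiseless_recovery_and_gof(self):
        y = 2.5 * CROP_LIGHT_T / (90.0 + CROP_LIGHT_T)
        fit = nk.fit_induction_hyperbolic(CROP_LIGHT_T, y)
        assert fit["A_L"] == pytest.approx(2.5, rel=1e-6)
        assert fit["K_L"] == pytest.approx(90.0, rel=1e-6)
        assert fit.gof == pytest.approx(1.0, abs=1e-12)
        assert fit.converged
        # independent grid oracle lands on the same optimum
        _, oracle_rss = hyperbolic_light_oracle(CROP_LIGHT_T, y)
        assert fit.rss <= oracle_rss + 1e-8

    def test_decreasing_line_is_model_mismatch(self):
        y = np.linspace(2.0, 0.5, len(CROP_LIGHT_T))
        fit = nk.fit_induction_hyperbolic(CROP_LIGHT_T, y)
        assert (fit.gof is not None and fit.gof < 0.5) or not fit.converged

    def test_deterministic(self):
        y = 2.0 * CROP_LIGHT_T / (120.0 + CROP_LIGHT_T) + 0.01 * np.sin(CROP_LIGHT_T)
        a = nk.fit_induction_hyperbolic(CROP_LIGHT_T, y)
        b = nk.fit_induction_hyperbolic(CROP_LIGHT_T, y)
        assert a.params == b.params and a.rss == b.rss

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            nk.fit_induction_hyperbolic([15.0, 45.0], [0.3, 0.6])

    def test_all_zero_flagged(self):
        fit = nk.fit_induction_hyperbolic(CROP_LIGHT_T, np.zeros_like(CROP_LIGHT_T))
        assert not fit.converged
        assert "no_signal" in fit.flags


class TestRelaxationHyperbolic:
    def test_noiseless_recovery(self):
        y = 2.5 - 1.8 * CROP_DARK_T / (120.0 + CROP_DARK_T)
        assert y[-1] == pytest.approx(2.5 - 1.8 * 594 / 714)
        fit = nk.fit_relaxation_hyperbolic(CROP_DARK_T, y, n_at_light_off=2.5)
        assert fit["N0"] == pytest.approx(2.5, rel=1e-6)
        assert fit["A_D"] == pytest.approx(1.8, rel=1e-6)
        assert fit["K_D"] == pytest.approx(120.0, rel=1e-6)
        assert fit.gof == pytest.approx(1.0, abs=1e-12)
        _, oracle_rss = hyperbolic_dark_oracle(CROP_DARK_T, y)
        assert fit.rss <= oracle_rss + 1e-8

    def test_amplitude_constrained_by_n0(self):
        y = 2.5 - 1.8 * CROP_DARK_T / (120.0 + CROP_DARK_T)
        fit = nk.fit_relaxation_hyperbolic(CROP_DARK_T, y)
        assert 0.0 <= fit["A_D"] <= fit["N0"] + 1e-9

    def test_flat_series_amplitude_at_zero(self):
        fit = nk.fit_relaxation_hyperbolic(CROP_DARK_T, np.full(6, 1.7))
        assert fit["A_D"] == pytest.approx(0.0, abs=1e-6)
        assert "amplitude_at_lower_bound" in fit.flags

    def test_increasing_series_not_converged(self):
        y = np.linspace(1.0, 2.0, 6)
        fit = nk.fit_relaxation_hyperbolic(CROP_DARK_T, y)
        assert fit["A_D"] == pytest.approx(0.0, abs=1e-6)
        assert not fit.converged


class TestInductionExponential:
    def test_noiseless_recovery(self):
        y = 2.0 * (1.0 - np.exp(-CROP_LIGHT_T / 60.0))
        fit = nk.fit_induction_exponential(CROP_LIGHT_T, y)
        assert fit["A_E"] == pytest.approx(2.0, rel=1e-6)
        assert fit["tau"] == pytest.approx(60.0, rel=1e-6)
        _, oracle_rss = exponential_light_oracle(CROP_LIGHT_T, y)
        assert fit.rss <= oracle_rss + 1e-8

    def test_value_at_tau(self):
        y = 2.0 * (1.0 - np.exp(-CROP_LIGHT_T / 60.0))
        fit = nk.fit_induction_exponential(CROP_LIGHT_T, y)
        a, tau = fit["A_E"], fit["tau"]
        assert a * (1 - np.exp(-1)) == pytest.approx(
            a * (1 - np.exp(-tau / tau))
        )

    def test_slower_induction_gives_larger_tau(self):
        fast = 2.0 * (1.0 - np.exp(-CROP_LIGHT_T / 40.0))
        slow = 2.0 * (1.0 - np.exp(-CROP_LIGHT_T / 160.0))
        tau_fast = nk.fit_induction_exponential(CROP_LIGHT_T, fast)["tau"]
        tau_slow = nk.fit_induction_exponential(CROP_LIGHT_T, slow)["tau"]
        assert tau_slow > tau_fast


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        assert r_squared([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) < 0

    def test_zero_variance_flagged_none(self):
        assert r_squared([1.0, 1.0, 1.0], [1.0, 1.1, 0.9]) is None


class TestExtractTraits:
    def test_slope_is_initial_derivative(self, noiseless_series):
        traits = nk.traits_for_sample(noiseless_series)
        # A_L/K_L for A_L=2.5, K_L=90
        assert traits.NPQslope_lightH == pytest.approx(2.5 / 90.0, rel=1e-5)
        dark = traits.fits["dark"]
        assert traits.NPQslope_darkH == pytest.approx(
            dark["A_D"] / dark["K_D"], rel=1e-12
        )

    def test_observed_traits_are_observed(self, noiseless_series, truth, crop_schedule):
        traits = nk.traits_for_sample(noiseless_series)
        npq = npq_truth_series(truth, crop_schedule)
        assert traits.NPQ_max == pytest.approx(npq[12], abs=1e-12)
        assert traits.NPQ_end == pytest.approx(npq[-1], abs=1e-12)

    def test_npq_max_regardless_of_fit(self, crop_schedule):
        """NPQ_max is the last observed light value even for a bad fit."""
        rng = np.random.default_rng(0)
        fm_prime = 3.0 / (1.0 + np.abs(rng.normal(1.0, 0.5, 19)))
        tr = nk.FluorescenceTrace("x", 0.5, 3.0, fm_prime, crop_schedule)
        s = nk.npq_series(tr)
        traits = nk.traits_for_sample(s)
        assert traits.NPQ_max == pytest.approx(s.npq[12])

    def test_scale_equivariance(self, noiseless_series):
        """Scaling NPQ by c scales amplitudes/slopes by c, times and gof not."""
        base = nk.traits_for_sample(noiseless_series)
        c = 3.0
        scaled = nk.NPQSeries(
            sample_id="scaled",
            t_abs_s=noiseless_series.t_abs_s,
            t_local_s=noiseless_series.t_local_s,
            cycle=noiseless_series.cycle,
            phase=noiseless_series.phase,
            npq=c * noiseless_series.npq,
            fvfm=noiseless_series.fvfm,
        )
        tr = nk.traits_for_sample(scaled)
        for name in ("NPQasymptote_lightH", "NPQamplitude_darkH", "NPQslope_lightH",
                     "NPQslope_darkH", "NPQ_max", "NPQ_end"):
            assert getattr(tr, name) == pytest.approx(c * getattr(base, name), rel=1e-4)
        assert tr.NPQtime_constant_light == pytest.approx(
            base.NPQtime_constant_light, rel=1e-4
        )
        assert tr.NPQgof_light == pytest.approx(base.NPQgof_light, abs=1e-9)


class TestFitCycles:
    def test_three_cycle_records(self, arabidopsis_schedule):
        gt = nk.GroundTruth(residual_gain=1.2)
        s = nk.npq_series(nk.trace_from_truth(gt, arabidopsis_schedule, 0.0, seed=0))
        per_cycle = fit_cycles(s)
        assert len(per_cycle) == 3
        for tr in per_cycle:
            assert tr.NPQ_max is not None and tr.NPQ_end is not None

    def test_residual_gain_increases_npq_end(self, arabidopsis_schedule):
        gt = nk.GroundTruth(residual_gain=1.3)
        s = nk.npq_series(nk.trace_from_truth(gt, arabidopsis_schedule, 0.0, seed=0))
        ends = [tr.NPQ_end for tr in fit_cycles(s)]
        assert ends[0] < ends[1] < ends[2]

    def test_no_carryover_identical_cycles(self, arabidopsis_schedule):
        s = nk.npq_series(
            nk.trace_from_truth(nk.GroundTruth(), arabidopsis_schedule, 0.0, seed=0)
        )
        per_cycle = fit_cycles(s)
        maxes = [tr.NPQ_max for tr in per_cycle]
        asym = [tr.NPQasymptote_lightH for tr in per_cycle]
        assert maxes[0] == pytest.approx(maxes[1], rel=1e-9)
        assert asym[0] == pytest.approx(asym[2], rel=1e-6)

    def test_single_cycle_rejected(self, noiseless_series):
        with pytest.raises(ValueError):
            fit_cycles(noiseless_series)


class TestQC:
    def test_noiseless_sample_passes(self, noiseless_series):
        traits = nk.traits_for_sample(noiseless_series)
        rep = nk.qc_assess([traits], {noiseless_series.sample_id: noiseless_series})
        assert len(rep.records) == 0
        assert rep.passed(noiseless_series.sample_id)

    def test_fvfm_rule(self, noiseless_series):
        traits = nk.traits_for_sample(noiseless_series)
        traits.FvFm = 0.95
        rep = nk.qc_assess([traits])
        assert "fvfm_out_of_range" in set(rep.records["rule"])

    def test_negative_npq_rule(self, crop_schedule):
        fm_prime = np.full(19, 1.5)
        fm_prime[0] = 3.4  # Fm' above Fm -> NPQ < -0.05
        tr = nk.FluorescenceTrace("neg", 0.5, 3.0, fm_prime, crop_schedule)
        s = nk.npq_series(tr)
        traits = nk.traits_for_sample(s)
        rep = nk.qc_assess([traits], {"neg": s})
        assert "negative_npq" in set(rep.records["rule"])

    def test_mad_outlier_rule(self, crop_schedule):
        traces = [
            nk.trace_from_truth(nk.GroundTruth(), crop_schedule, 0.01, seed=i, sample_id=f"s{i}")
            for i in range(6)
        ]
        all_traits = [nk.traits_for_sample(nk.npq_series(t)) for t in traces]
        all_traits[0].NPQasymptote_lightH = 12.0  # grossly out of cohort
        groups = {t.sample_id: ("WT", "control") for t in all_traits}
        rep = nk.qc_assess(all_traits, groups=groups)
        assert any("cohort_outlier" in r for r in rep.records["rule"])
        assert "s0" in rep.flagged_samples

    def test_noise_only_series_flagged_on_gof(self, crop_schedule, rng):
        flagged = 0
        for i in range(50):
            npq_noise = rng.normal(0.3, 0.08, size=19)
            fm_prime = 3.0 / (1.0 + np.clip(npq_noise, -0.5, None))
            s = nk.npq_series(nk.FluorescenceTrace(f"n{i}", 0.5, 3.0, fm_prime, crop_schedule))
            rep = nk.qc_assess([nk.traits_for_sample(s)], {s.sample_id: s})
            flagged += any("gof" in r for r in rep.records["rule"])
        assert flagged >= 48
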