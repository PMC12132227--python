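import numpy as np
import pytest

import npqkin as nk
from npqkin.protocol import DARK, LIGHT
from npqkin.simulate import npq_truth_at, npq_truth_series


class TestGroundTruthCurve:
    def test_half_saturation(self, truth, crop_schedule):
        _, segs = nk.flash_times(crop_schedule)
        assert npq_truth_at(truth, segs[0], truth.K_L) == pytest.approx(truth.A_L / 2)

    def test_zero_time_zero_npq(self, truth, crop_schedule):
        _, segs = nk.flash_times(crop_schedule)
        assert npq_truth_at(truth, segs[0], 0.0) == 0.0

    def test_analytic_value_at_light_end(self, crop_schedule):
        # A_L * t / (K_L + t) = 2.5 * 675 / 765
        gt = nk.GroundTruth(A_L=2.5, K_L=90.0)
        _, segs = nk.flash_times(crop_schedule)
        assert npq_truth_at(gt, segs[0], 675.0) == pytest.approx(2.5 * 675 / 765)

    def test_dark_curve_with_explicit_n0(self, crop_schedule):
        gt = nk.GroundTruth(N0=2.5, A_D=1.8, K_D=120.0)
        _, segs = nk.flash_times(crop_schedule)
        v = npq_truth_at(gt, segs[1], 594.0, light_duration_s=675.0)
        assert v == pytest.approx(2.5 - 1.8 * 594 / 714)

    def test_negative_local_time_rejected(self, truth, crop_schedule):
        _, segs = nk.flash_times(crop_schedule)
        with pytest.raises(ValueError):
            npq_truth_at(truth, segs[0], -1.0)

    def test_monotone_within_segments(self, truth, crop_schedule):
        npq = npq_truth_series(truth, crop_schedule)
        assert (np.diff(npq[:13]) > 0).all()  # light: non-decreasing
        assert (np.diff(npq[13:]) < 0).all()  # dark: non-increasing
        assert (npq >= 0).all()

    def test_residual_gain_grows_dark_end(self, arabidopsis_schedule):
        gt = nk.GroundTruth(residual_gain=1.3)
        npq = npq_truth_series(gt, arabidopsis_schedule)
        ends = [npq[(np.asarray(arabidopsis_schedule.cycle_index) == c)][-1] for c in range(3)]
        assert ends[0] < ends[1] < ends[2]

    def test_residual_gain_one_identical_cycles(self, arabidopsis_schedule):
        npq = npq_truth_series(nk.GroundTruth(), arabidopsis_schedule)
        per_cycle = npq.reshape(3, 10)
        np.testing.assert_allclose(per_cycle[0], per_cycle[1])
        np.testing.assert_allclose(per_cycle[0], per_cycle[2])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            nk.GroundTruth(A_L=-1.0)
        with pytest.raises(ValueError):
            nk.GroundTruth(N0=1.0, A_D=1.5)
        with pytest.raises(ValueError):
            nk.GroundTruth(Fo_true=3.0, Fm_true=2.0)


class TestTraceFromTruth:
    def test_inverse_of_stern_volmer(self, crop_schedule):
        gt = nk.GroundTruth(Fm_true=3.0)
        tr = nk.trace_from_truth(gt, crop_schedule, 0.0, seed=0)
        npq = npq_truth_series(gt, crop_schedule)
        np.testing.assert_allclose(tr.fm_prime, 3.0 / (1.0 + npq), rtol=1e-15)

    def test_seeded_determinism(self, truth, crop_schedule):
        a = nk.trace_from_truth(truth, crop_schedule, 0.05, seed=42)
        b = nk.trace_from_truth(truth, crop_schedule, 0.05, seed=42)
        assert np.array_equal(a.fm_prime, b.fm_prime)
        assert a.fo == b.fo and a.fm == b.fm

    def test_roundtrip_identity_at_zero_noise(self, truth, crop_schedule):
        s = nk.npq_series(nk.trace_from_truth(truth, crop_schedule, 0.0, seed=0))
        np.testing.assert_allclose(
            s.npq, npq_truth_series(truth, crop_schedule), atol=1e-12
        )

    def test_negative_noise_rejected(self, truth, crop_schedule):
        with pytest.raises(ValueError):
            nk.trace_from_truth(truth, crop_schedule, -0.1)


class TestSimulateStudy:
    def test_counts(self, crop_schedule):
        design = nk.StudyDesign(
            genotype_effects={"WT": {}, "mut": {"A_L": 0.5}},
            treatment_effects={"control": {}, "stress": {"A_L": 1.5}},
            n_replicates=4,
        )
        traces, table = nk.simulate_study(design, crop_schedule)
        assert len(traces) == 16
        assert len(table) == 16
        assert set(table["genotype"]) == {"WT", "mut"}

    def test_degenerate_design_identical_parameters(self, crop_schedule):
        design = nk.StudyDesign(
            genotype_effects={"WT": {}},
            treatment_effects={"control": {}, "stress": {}},
            n_replicates=3,
            replicate_sd=0.0,
        )
        _, table = nk.simulate_study(design, crop_schedule)
        assert table["A_L"].nunique() == 1
        assert table["K_D"].nunique() == 1

    def test_treatment_multiplier_recovered_in_mean(self, crop_schedule):
        """Monte-Carlo: stress/control mean A_L ratio ~ 1.5 at n=50/cell."""
        design = nk.StudyDesign(
            treatment_effects={"control": {}, "stress": {"A_L": 1.5}},
            n_replicates=50,
            replicate_sd=0.1,
            seed=5,
        )
        _, table = nk.simulate_study(design, crop_schedule)
        means = table.groupby("treatment")["A_L"].mean()
        assert means["stress"] / means["control"] == pytest.approx(1.5, rel=0.05)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            nk.StudyDesign(genotype_effects={"WT": {"bogus": 2.0}})


class TestPairedApproaches:
    def test_identity_at_zero_noise_unit_bias(self, truth, crop_schedule):
        discs, plants = nk.simulate_paired_approaches(
            truth, crop_schedule, 0.0, 0.0, 1.0, seed=0
        )
        np.testing.assert_allclose(
            nk.npq_series(discs[0]).npq, nk.npq_series(plants[0]).npq, rtol=1e-12
        )

    def test_bias_scales_disc_npq(self, truth, crop_schedule):
        discs, plants = nk.simulate_paired_approaches(
            truth, crop_schedule, 0.0, 0.0, 0.9, seed=0
        )
        np.testing.assert_allclose(
            nk.npq_series(discs[0]).npq,
            0.9 * nk.npq_series(plants[0]).npq,
            rtol=1e-10,
        )

    def test_bias_below_one_gives_slope_below_one(self, truth, crop_schedule):
        slopes = []
        for seed in range(30):
            d, p = nk.simulate_paired_approaches(
                truth, crop_schedule, 0.03, 0.03, 0.9, seed=seed, n_replicates=8
            )
            y = np.mean([nk.npq_series(t).npq for t in d], axis=0)
            x = np.mean([nk.npq_series(t).npq for t in p], axis=0)
            slopes.append(nk.concordance(x, y).slope)
        assert all(s < 1.0 for s in slopes)
        assert np.mean(slopes) == pytest.approx(0.9, abs=0.03)


class TestRenderPlateStack:
    def test_constant_disc_exact(self, crop_schedule):
        layout = nk.PlateLayout()
        gt = nk.GroundTruth()
        tr = nk.trace_from_truth(gt, crop_schedule, 0.0, seed=0)
        stack = nk.render_plate_stack(layout, [tr])
        assert stack.shape[0] == crop_schedule.n_flashes + 2
        mask = layout.disc_mask(0)
        assert stack[0][mask].mean() == pytest.approx(tr.fo, abs=1e-12)
        assert stack[1][mask].mean() == pytest.approx(tr.fm, abs=1e-12)

    def test_two_wells_independent_values(self, crop_schedule):
        layout = nk.PlateLayout()
        a = nk.trace_from_truth(nk.GroundTruth(Fm_true=3.0), crop_schedule, 0.0, seed=0, sample_id="a")
        b = nk.trace_from_truth(nk.GroundTruth(Fm_true=6.0, Fo_true=1.0), crop_schedule, 0.0, seed=0, sample_id="b")
        stack = nk.render_plate_stack(layout, [a, b])
        assert stack[1][layout.disc_mask(0)].mean() == pytest.approx(3.0, abs=1e-12)
        assert stack[1][layout.disc_mask(1)].mean() == pytest.approx(6.0, abs=1e-12)

    def test_too_many_traces_rejected(self, crop_schedule):
        layout = nk.PlateLayout()
        tr = nk.trace_from_truth(nk.GroundTruth(), crop_schedule, 0.0, seed=0)
        with pytest.raises(nk.imaging.LayoutError):
            nk.render_plate_stack(layout, [tr] * 97)
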