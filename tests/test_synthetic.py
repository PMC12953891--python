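"""Phantom generator: bolus model, voxel synthesis, cohort structure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ftburden as fb
from ftburden.synthetic import (
    gamma_variate_integral,
    largest_remainder_counts,
    reference_bolus_curve,
    sample_fraction_table,
)
from ftburden.stats import mann_whitney


class TestGammaVariateBolus:
    def test_zero_at_and_before_onset(self):
        t = np.array([0.0, 5.0, 10.0])
        out = fb.gamma_variate_bolus(t, t0=10.0, alpha=3, beta=4, amplitude=6)
        assert np.all(out == 0)

    def test_peak_value_and_location(self):
        alpha, beta, amp = 2.5, 3.0, 7.0
        t_peak = 10.0 + alpha * beta
        peak = fb.gamma_variate_bolus(np.array([t_peak]), 10.0, alpha, beta, amp)[0]
        assert peak == pytest.approx(amp, rel=1e-12)
        t = np.linspace(10, 80, 5000)
        curve = fb.gamma_variate_bolus(t, 10.0, alpha, beta, amp)
        assert curve.max() <= peak + 1e-9

    def test_quadrature_matches_closed_form(self):
        alpha, beta, amp = 3.0, 4.0, 6.0
        t = np.linspace(0, 400, 400_001)
        curve = fb.gamma_variate_bolus(t, 0.0, alpha, beta, amp)
        numeric = np.trapezoid(curve, t)
        assert numeric == pytest.approx(
            gamma_variate_integral(alpha, beta, amp), rel=1e-6
        )

    @pytest.mark.parametrize("alpha,beta", [(0, 1), (-1, 2), (1, 0), (2, -0.5)])
    def test_rejects_nonpositive_shape(self, alpha, beta):
        with pytest.raises(ValueError):
            fb.gamma_variate_bolus(np.array([1.0]), 0.0, alpha, beta, 1.0)


class TestVoxelSynthesis:
    def test_no_perfusion_gives_flat_baseline(self, acq):
        ref = reference_bolus_curve(acq)
        s = fb.synthesize_voxel_timeseries(0.0, 0.0, ref, acq, baseline_signal=120.0)
        assert np.allclose(s, 120.0)

    def test_leakage_drives_late_dr2star_negative(self, acq):
        ref = reference_bolus_curve(acq)
        s = fb.synthesize_voxel_timeseries(1.0, 0.05, ref, acq, baseline_signal=100.0)
        last = -np.log(s[-1] / 100.0) / acq.te_s
        assert last < 0  # T1-extravasation signature

    def test_recovered_dr2star_scales_linearly_with_rcbv(self, acq):
        ref = reference_bolus_curve(acq)
        integrals = []
        for rcbv in (1.0, 2.0):
            s = fb.synthesize_voxel_timeseries(rcbv, 0.0, ref, acq)
            dr2 = -np.log(s / 100.0) / acq.te_s
            integrals.append(np.trapezoid(dr2, dx=acq.tr_s))
        assert integrals[1] == pytest.approx(2 * integrals[0], rel=1e-12)

    def test_noiseless_invertibility(self, acq):
        # signal -> ΔR2* round trip recovers the constructed curve exactly
        from scipy.integrate import cumulative_trapezoid

        ref = reference_bolus_curve(acq)
        rcbv, k2 = np.array([0.7, 1.4, 2.2]), np.array([0.0, 0.02, 0.05])
        s = fb.synthesize_voxel_timeseries(rcbv, k2, ref, acq)
        expected = rcbv[:, None] * ref - k2[:, None] * cumulative_trapezoid(
            ref, dx=acq.tr_s, initial=0.0
        )
        recovered = -np.log(s / 100.0) / acq.te_s
        assert np.allclose(recovered, expected, rtol=1e-9, atol=1e-9)


class TestLargestRemainder:
    def test_exact_fraction_example(self):
        counts = largest_remainder_counts(np.array([0.44, 0.19, 0.37]), 1000)
        assert counts.tolist() == [440, 190, 370]

    @given(
        st.lists(st.floats(0.01, 10), min_size=2, max_size=6),
        st.integers(1, 5000),
    )
    def test_matches_independent_apportionment(self, weights, total):
        fracs = np.array(weights) / np.sum(weights)
        counts = largest_remainder_counts(fracs, total)
        # independent oracle: python-sorted remainders
        quotas = [f * total for f in fracs]
        floors = [int(np.floor(q)) for q in quotas]
        order = sorted(
            range(len(fracs)), key=lambda i: (-(quotas[i] - floors[i]), i)
        )
        expected = list(floors)
        for i in order[: total - sum(floors)]:
            expected[i] += 1
        assert counts.tolist() == expected
        assert counts.sum() == total


class TestBuildPatient:
    def test_pure_low_lesion(self, acq):
        spec = fb.LesionSpec((15.5, 15.5, 7.0), (5, 5, 3), 1.0, 0.0, 0.0)
        p = fb.build_patient(spec, "TRA", acq, rng=np.random.default_rng(0))
        lesion_vals = p.truth.rcbv_true[p.truth.voi_true]
        assert np.all(lesion_vals <= 1.0)
        assert p.truth.fracs_true.tolist() == [1.0, 0.0, 0.0]

    def test_zero_k2_range(self, acq):
        spec = fb.LesionSpec(
            (15.5, 15.5, 7.0), (5, 5, 3), 0.5, 0.3, 0.2, k2_range=(0.0, 0.0)
        )
        p = fb.build_patient(spec, "TP", acq, rng=np.random.default_rng(0))
        assert np.all(p.truth.k2_true == 0)

    def test_k2_zero_outside_lesion(self, noiseless_patient):
        t = noiseless_patient.truth
        assert np.all(t.k2_true[~t.voi_true] == 0)

    def test_realized_fractions_match_counts_exactly(self, noiseless_patient):
        t = noiseless_patient.truth
        lesion_vals = t.rcbv_true[t.voi_true]
        counts = np.array(
            [
                np.sum(lesion_vals <= 1.0),
                np.sum((lesion_vals > 1.0) & (lesion_vals < 1.6)),
                np.sum(lesion_vals >= 1.6),
            ]
        )
        assert np.array_equal(t.fracs_true, counts / counts.sum())
        assert t.fracs_true.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lesion_smaller_than_class_count_errors(self, acq):
        spec = fb.LesionSpec((16.0, 16.0, 7.0), (0.6, 0.6, 0.6), 0.4, 0.3, 0.3)
        with pytest.raises(ValueError, match="voxels"):
            fb.build_patient(spec, "TP", acq, rng=np.random.default_rng(0))

    def test_lesion_outside_brain_errors(self, acq):
        spec = fb.LesionSpec((2.0, 2.0, 2.0), (6, 6, 4), 1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="margin"):
            fb.build_patient(spec, "TP", acq, rng=np.random.default_rng(0))

    def test_post_contrast_enhancement(self, noiseless_patient, lesion_spec):
        p = noiseless_patient
        voi = p.truth.voi_true
        ratio = p.t1_post[voi] / p.t1_pre[voi]
        assert np.allclose(ratio, lesion_spec.enhancement_gain)
        assert np.allclose(p.t1_post[~voi], p.t1_pre[~voi])


class TestCohort:
    def test_truth_table_deterministic(self):
        spec = fb.CohortSpec(n_tp=2, n_tra=2, seed=5)
        acq = fb.AcquisitionParams(grid=(20, 20, 10))
        _, t1 = fb.generate_cohort(spec, acq)
        _, t2 = fb.generate_cohort(spec, acq)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_default_cohort_size_is_59(self):
        table = sample_fraction_table(fb.CohortSpec(seed=0))
        assert len(table) == 59
        assert (table.label == "TP").sum() == 35
        assert (table.label == "TRA").sum() == 24

    def test_planted_fraction_means(self):
        spec = fb.CohortSpec(n_tp=200, n_tra=200, seed=17)
        table = sample_fraction_table(spec)
        tp = table[table.label == "TP"][["frac_low", "frac_mid", "frac_high"]].mean()
        assert np.allclose(tp, [0.44, 0.19, 0.37], atol=0.03)
        tra = table[table.label == "TRA"][["frac_low", "frac_mid", "frac_high"]].mean()
        assert np.allclose(tra, [0.60, 0.19, 0.21], atol=0.03)

    def test_group_separation_in_planted_high_fraction(self):
        spec = fb.CohortSpec(n_tp=200, n_tra=200, seed=23)
        table = sample_fraction_table(spec)
        tp = table[table.label == "TP"].frac_high.to_numpy()
        tra = table[table.label == "TRA"].frac_high.to_numpy()
        _, p = mann_whitney(tp, tra)
        assert p < 1e-6
        assert tp.mean() > tra.mean()

    def test_volumes_deterministic_given_seed(self):
        spec = fb.CohortSpec(n_tp=1, n_tra=1, seed=9)
        acq = fb.AcquisitionParams(grid=(20, 20, 10))
        p1, _ = fb.generate_cohort(spec, acq)
        p2, _ = fb.generate_cohort(spec, acq)
        assert np.array_equal(p1[0].dsc, p2[0].dsc)
        assert np.array_equal(p1[1].t1_post, p2[1].t1_post)
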