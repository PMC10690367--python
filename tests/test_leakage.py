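"""Exchange-model leakage correction: fits, corrections, nrCBV."""

import numpy as np
import pytest

from dscradiomics import leakage

DT = 1.87


def normal_equations_unidir(conc, ref, dt):
    """Independent closed-form oracle for the two-parameter linear fit."""
    a = np.column_stack([ref, -leakage.cumulative_trapezoid_curve(ref, dt)])
    return np.linalg.solve(a.T @ a, a.T @ conc)


class TestDiscreteOperators:
    def test_exp_kernel_reduces_to_cumtrapz_at_zero_rate(self, reference_curve):
        k0 = leakage.exp_kernel_convolution(reference_curve, 0.0, DT)
        ct = leakage.cumulative_trapezoid_curve(reference_curve, DT)
        assert np.allclose(k0, ct, atol=1e-14)

    def test_exp_kernel_matches_direct_quadrature(self, reference_curve):
        # recurrence vs explicit trapezoid-weighted sum
        kep = 0.13
        t = np.arange(len(reference_curve)) * DT
        direct = np.zeros_like(reference_curve)
        for n in range(1, len(t)):
            w = np.ones(n + 1)
            w[0] = w[-1] = 0.5
            direct[n] = DT * np.sum(
                w * reference_curve[: n + 1] * np.exp(-kep * (t[n] - t[: n + 1]))
            )
        rec = leakage.exp_kernel_convolution(reference_curve, kep, DT)
        assert np.allclose(rec, direct, atol=1e-12)

    def test_nrcbv_trapezoid_hand_example(self):
        assert leakage.integrate_nrcbv(np.array([0.0, 1, 1, 0]), 0, 3, 1.0) == 2.0
        assert leakage.integrate_nrcbv(np.zeros(10), 0, 9, 1.0) == 0.0
        assert leakage.integrate_nrcbv(np.array([0.0, 1, 1, 0]), 0, 3, 2.0) == 4.0

    def test_nrcbv_invalid_window(self):
        with pytest.raises(ValueError):
            leakage.integrate_nrcbv(np.zeros(5), 3, 3, 1.0)


class TestReferenceCurve:
    def test_mean_of_two_voxels(self):
        conc = np.zeros((2, 1, 1, 2))
        conc[0, 0, 0] = [0, 2]
        conc[1, 0, 0] = [0, 4]
        brain = np.ones((2, 1, 1), bool)
        tumor = np.zeros((2, 1, 1), bool)
        ref, n = leakage.compute_reference_curve(conc, brain, tumor)
        assert np.allclose(ref, [0, 3]) and n == 2

    def test_tumor_exclusion_changes_mean(self):
        conc = np.zeros((5, 5, 1, 2))
        conc[..., 1] = 1.0
        conc[2, 2, 0, 1] = 100.0
        brain = np.ones((5, 5, 1), bool)
        tumor = np.zeros((5, 5, 1), bool)
        tumor[2, 2, 0] = True
        ref_all, _ = leakage.compute_reference_curve(
            conc, brain, tumor & False, dilation_voxels=0
        )
        ref_excl, n = leakage.compute_reference_curve(
            conc, brain, tumor, dilation_voxels=0
        )
        assert ref_all[1] > ref_excl[1]
        assert ref_excl[1] == pytest.approx(1.0) and n == 24

    def test_empty_reference_raises(self):
        conc = np.zeros((2, 2, 1, 3))
        brain = np.ones((2, 2, 1), bool)
        with pytest.raises(ValueError):
            leakage.compute_reference_curve(conc, brain, brain)


class TestUnidirectional:
    def test_exact_linear_recovery(self, reference_curve):
        ct = leakage.contaminate_with_leakage(reference_curve, 1.5, 0.02, 0.0, DT)
        p = leakage.fit_unidirectional(ct, reference_curve, DT)
        assert p.k1 == pytest.approx(1.5, abs=1e-10)
        assert p.k2 == pytest.approx(0.02, abs=1e-10)

    def test_pure_scaling_gives_zero_k2(self, reference_curve):
        p = leakage.fit_unidirectional(2.0 * reference_curve, reference_curve, DT)
        assert p.k1 == pytest.approx(2.0, abs=1e-10)
        assert p.k2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, reference_curve, rng):
        for _ in range(20):
            k1, k2 = rng.normal(1, 0.5), rng.normal(0, 0.05)
            noise = rng.normal(0, 0.01, reference_curve.shape)
            ct = (
                leakage.contaminate_with_leakage(reference_curve, k1, k2, 0.0, DT)
                + noise
            )
            p = leakage.fit_unidirectional(ct, reference_curve, DT)
            k1_o, k2_o = normal_equations_unidir(ct, reference_curve, DT)
            assert p.k1 == pytest.approx(k1_o, abs=1e-8)
            assert p.k2 == pytest.approx(k2_o, abs=1e-8)

    def test_orthogonal_residual_leaves_fit_unchanged(self, reference_curve):
        ct = leakage.contaminate_with_leakage(reference_curve, 1.3, 0.03, 0.0, DT)
        design = np.column_stack(
            [reference_curve, -leakage.cumulative_trapezoid_curve(reference_curve, DT)]
        )
        q, _ = np.linalg.qr(design, mode="complete")
        ortho = q[:, -1]  # orthogonal to the design column space
        p0 = leakage.fit_unidirectional(ct, reference_curve, DT)
        p1 = leakage.fit_unidirectional(ct + 0.5 * ortho, reference_curve, DT)
        assert p1.k1 == pytest.approx(p0.k1, abs=1e-9)
        assert p1.k2 == pytest.approx(p0.k2, abs=1e-9)
        assert p1.residual_norm > 0.4

    def test_rank_deficient_reference_rejected(self):
        with pytest.raises(ValueError):
            leakage.fit_unidirectional(np.zeros(10), np.zeros(10), DT)

    def test_correction_definition_and_roundtrip(self, reference_curve):
        clean = 1.5 * reference_curve
        ct = leakage.contaminate_with_leakage(reference_curve, 1.5, 0.02, 0.0, DT)
        p = leakage.fit_unidirectional(ct, reference_curve, DT)
        corr = leakage.correct_unidirectional(ct, reference_curve, p.k2, DT)
        # corrected - input = K2 * int(ref), and round trip restores clean curve
        assert np.allclose(
            corr - ct,
            p.k2 * leakage.cumulative_trapezoid_curve(reference_curve, DT),
        )
        t0, t1 = 4, leakage.replenish_index(reference_curve)
        got = leakage.integrate_nrcbv(corr, t0, t1, DT)
        want = leakage.integrate_nrcbv(clean, t0, t1, DT)
        assert got == pytest.approx(want, rel=0.01)
        # K2 = 0 leaves the curve untouched
        assert np.array_equal(
            leakage.correct_unidirectional(ct, reference_curve, 0.0, DT), ct
        )


class TestBidirectional:
    def test_noiseless_recovery(self, reference_curve):
        ct = leakage.contaminate_with_leakage(reference_curve, 1.2, 0.05, 0.1, DT)
        p = leakage.fit_bidirectional(ct, reference_curve, DT)
        assert p.converged
        assert p.k1 == pytest.approx(1.2, rel=0.05)
        assert p.k2 == pytest.approx(0.05, rel=0.05)
        assert p.kep == pytest.approx(0.1, rel=0.05)

    def test_zero_k2_flags_kep_unidentifiable(self, reference_curve):
        p = leakage.fit_bidirectional(1.1 * reference_curve, reference_curve, DT)
        assert abs(p.k2) < 1e-6
        assert not p.kep_identifiable

    def test_kep_zero_limit_matches_unidirectional(self, reference_curve):
        ct = leakage.contaminate_with_leakage(reference_curve, 1.5, 0.02, 0.0, DT)
        uni = leakage.fit_unidirectional(ct, reference_curve, DT)
        bid = leakage.fit_bidirectional(ct, reference_curve, DT)
        assert bid.k1 == pytest.approx(uni.k1, rel=0.01)
        assert bid.k2 == pytest.approx(uni.k2, rel=0.01)

    def test_correction_kep_zero_equals_unidirectional(self, reference_curve):
        ct = leakage.contaminate_with_leakage(reference_curve, 1.2, 0.04, 0.08, DT)
        c_bi = leakage.correct_bidirectional(ct, reference_curve, 0.04, 0.0, DT)
        c_un = leakage.correct_unidirectional(ct, reference_curve, 0.04, DT)
        assert np.allclose(c_bi, c_un, atol=1e-10)
        assert np.array_equal(
            leakage.correct_bidirectional(ct, reference_curve, 0.0, 0.1, DT), ct
        )

    def test_contaminate_fit_correct_roundtrip(self, reference_curve):
        k1, k2, kep = 1.2, 0.05, 0.1
        clean = k1 * reference_curve
        ct = leakage.contaminate_with_leakage(reference_curve, k1, k2, kep, DT)
        p = leakage.fit_bidirectional(ct, reference_curve, DT)
        corr = leakage.correct_bidirectional(ct, reference_curve, p.k2, p.kep, DT)
        t0, t1 = 4, leakage.replenish_index(reference_curve)
        got = leakage.integrate_nrcbv(corr, t0, t1, DT)
        want = leakage.integrate_nrcbv(clean, t0, t1, DT)
        assert got == pytest.approx(want, rel=0.01)

    def test_determinism(self, reference_curve, rng):
        ct = leakage.contaminate_with_leakage(
            reference_curve, 1.2, 0.05, 0.1, DT
        ) + rng.normal(0, 0.05, reference_curve.shape)
        p1 = leakage.fit_bidirectional(ct, reference_curve, DT)
        p2 = leakage.fit_bidirectional(ct, reference_curve, DT)
        assert (p1.k1, p1.k2, p1.kep) == (p2.k1, p2.k2, p2.kep)
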