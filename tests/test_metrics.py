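"""Comparison metrics and test-retest reliability statistics."""

import itertools

import numpy as np
import pytest

from csdsi.metrics import (acc, angular_peak_difference,
                           crossing_angle_deviation, fiber_count, icc,
                           min_crossing_angle, mse_by_bvalue, nmse,
                           trt_report, wscv)
from csdsi.phantom import trt_replicates
from csdsi.propagator import Peak, PeakSet
from csdsi.sh import SphericalHarmonicFunction, fit_sh, real_sym_sh_basis
from csdsi.sphere import angle_between_lines


def peakset(dirs, fracs=None):
    dirs = [np.asarray(d, float) / np.linalg.norm(d) for d in dirs]
    n = len(dirs)
    fracs = fracs or [1.0 / n] * n
    return PeakSet(peaks=[Peak(direction=d, amplitude=f, relative_fraction=f)
                          for d, f in zip(dirs, fracs)])


class TestNmse:
    def test_identity_gives_zero(self):
        x = np.arange(5.0)
        assert nmse(x, x) == 0.0

    def test_zero_estimate_gives_one(self):
        assert nmse(np.zeros(4), np.array([1.0, 2, 3, 4])) == pytest.approx(1.0)

    def test_matches_independent_sum_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        num = sum((x - y) ** 2 for x, y in zip(a, b))
        den = sum(y * y for y in b)
        assert nmse(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.ones(3), np.zeros(3))


class TestMseByBvalue:
    bvals = np.array([0, 1000, 1000, 2000, 3000])
    bins = [0, 500, 1500, 2500, 3500]

    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 4, 2, 5))
        _, curve = mse_by_bvalue(a, a, self.bvals, self.bins)
        assert np.allclose(curve, 0.0)

    def test_constant_offset_gives_c_squared(self):
        rng = np.random.default_rng(2)
        a = rng.random((3, 3, 1, 5))
        _, curve = mse_by_bvalue(a, a + 0.5, self.bvals, self.bins)
        assert np.allclose(curve, 0.25)

    def test_bin_dependent_noise_gives_two_sigma_squared(self):
        """Independent noise of std sigma_b in each set gives an MSE curve
        of ~2 sigma_b^2 per bin."""
        rng = np.random.default_rng(3)
        sigmas = {1000.0: 0.05, 2000.0: 0.1, 3000.0: 0.2, 0.0: 0.0}
        shape = (40, 40, 2)
        base = rng.random(shape + (5,))
        noise_a = np.stack([rng.normal(0, sigmas[b], shape)
                            for b in self.bvals], axis=-1)
        noise_b = np.stack([rng.normal(0, sigmas[b], shape)
                            for b in self.bvals], axis=-1)
        _, curve = mse_by_bvalue(base + noise_a, base + noise_b,
                                 self.bvals, self.bins)
        expected = [0.0, 2 * 0.05**2, 2 * 0.1**2, 2 * 0.2**2]
        assert np.allclose(curve, expected, rtol=0.1, atol=1e-6)

    def test_mismatched_volume_count_rejected(self):
        with pytest.raises(ValueError):
            mse_by_bvalue(np.zeros((2, 2, 2, 4)), np.zeros((2, 2, 2, 4)),
                          self.bvals, self.bins)


class TestAcc:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        f = SphericalHarmonicFunction(coeffs=rng.standard_normal(15), order=4)
        assert acc(f, f) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        a = np.zeros(15)
        b = np.zeros(15)
        a[2] = 1.0   # an l=2 coefficient
        b[10] = 1.0  # an l=4 coefficient
        f = SphericalHarmonicFunction(coeffs=a, order=4)
        g = SphericalHarmonicFunction(coeffs=b, order=4)
        assert acc(f, g) == pytest.approx(0.0)

    def test_isotropic_function_flagged_undefined(self):
        iso = np.zeros(15)
        iso[0] = 2.0
        f = SphericalHarmonicFunction(coeffs=iso, order=4)
        g = SphericalHarmonicFunction(coeffs=np.ones(15), order=4)
        with pytest.warns(UserWarning):
            assert acc(f, g) is None

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        f = SphericalHarmonicFunction(coeffs=rng.standard_normal(45), order=8)
        g = SphericalHarmonicFunction(coeffs=rng.standard_normal(45), order=8)
        assert acc(f, g) == pytest.approx(acc(g, f))
        f3 = SphericalHarmonicFunction(coeffs=3.0 * f.coeffs, order=8)
        assert acc(f3, g) == pytest.approx(acc(f, g))
        assert -1.0 <= acc(f, g) <= 1.0

    def test_rotated_fiber_matches_quadrature_oracle(self):
        """ACC of a band-limited single-fiber profile against a rotated
        copy equals the dense-quadrature correlation of the mean-removed
        functions on the sphere."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        dirs = rng.standard_normal((500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        v = np.array([0.0, 0.0, 1.0])
        prof = np.exp(3.0 * (dirs @ v) ** 2)
        f = fit_sh(dirs, prof, order=8)  # band-limit the profile

        rot = Rotation.from_euler("y", 40, degrees=True)
        g_vals_at = lambda d: f.evaluate(rot.inv().apply(d))
        g = fit_sh(dirs, g_vals_at(dirs), order=8)

        # quadrature oracle on a dense theta/phi grid with sin(theta) weights
        th = np.linspace(0, np.pi, 200)
        ph = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        quad_dirs = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P),
                              np.cos(T)], axis=-1).reshape(-1, 3)
        w = np.sin(T).ravel()
        fv = f.evaluate(quad_dirs)
        gv = g_vals_at(quad_dirs)
        fm = np.sum(w * fv) / np.sum(w)
        gm = np.sum(w * gv) / np.sum(w)
        num = np.sum(w * (fv - fm) * (gv - gm))
        oracle = num / np.sqrt(np.sum(w * (fv - fm) ** 2)
                               * np.sum(w * (gv - gm) ** 2))
        assert acc(f, g) == pytest.approx(oracle, abs=1e-3)


class TestPeakMatching:
    def test_identical_sets_give_zero(self):
        p = peakset([(1, 0, 0), (0, 1, 0)])
        assert angular_peak_difference(p, p) == pytest.approx(0.0)

    def test_rotated_set_recovers_rotation_angle(self):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("z", 10, degrees=True)
        d1 = [(1, 0, 0), (0, 0, 1)]
        p1 = peakset(d1)
        p2 = peakset([rot.apply(np.array(d, float)) for d in d1])
        got = angular_peak_difference(p1, p2)
        assert got == pytest.approx(5.0, abs=0.2)  # (10 + 0)/2: z-axis fixed

    def test_scrambled_assignment_matches_permutation_oracle(self):
        rng = np.random.default_rng(6)
        d1 = rng.standard_normal((3, 3))
        d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
        perm = [2, 0, 1]
        p1 = peakset(list(d1))
        p2 = peakset([d1[i] for i in perm])
        brute = min(
            np.mean([angle_between_lines(d1[i], d1[perm.index(j)])
                     for i, j in zip(range(3), p)])
            for p in itertools.permutations(range(3)))
        assert angular_peak_difference(p1, p2) == pytest.approx(0.0, abs=1e-9)
        assert brute == pytest.approx(0.0, abs=1e-9)
        # non-trivial case: perturb the second set
        d2 = d1 + rng.normal(0, 0.1, size=(3, 3))
        d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
        p2 = peakset([d2[i] for i in perm])
        brute = min(
            np.mean([angle_between_lines(a, b) for a, b in zip(d1, pp)])
            for pp in itertools.permutations([d2[i] for i in perm]))
        assert angular_peak_difference(p1, p2) == pytest.approx(brute)

    def test_cardinality_mismatch_warns_and_matches_smaller(self):
        p1 = peakset([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        p2 = peakset([(1, 0, 0)])
        with pytest.warns(UserWarning):
            got = angular_peak_difference(p1, p2)
        assert got == pytest.approx(0.0)

    def test_crossing_angle_deviation(self):
        p1 = peakset([(1, 0, 0), (0, 1, 0)])   # 90 degrees
        d = np.radians(60)
        p2 = peakset([(1, 0, 0), (np.cos(d), np.sin(d), 0)])  # 60 degrees
        assert crossing_angle_deviation(p1, p2) == pytest.approx(30.0)
        with pytest.raises(ValueError):
            crossing_angle_deviation(p1, peakset([(1, 0, 0)]))


class TestMinCrossingAngle:
    def test_all_equal_angles(self):
        assert min_crossing_angle([90.0] * 100, 0.01) == 90.0

    def test_uniform_bins_quantile_definition(self):
        angles = np.repeat(np.arange(10, 100, 10), 11)  # 9 bins x 11 voxels
        share = 11 / len(angles)
        assert min_crossing_angle(angles, share) == 10.0

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(8)
        angles = rng.uniform(10, 90, size=500)
        prevalence = 0.01
        s = np.sort(angles)
        k = 0
        for i, a in enumerate(s, start=1):
            if i / len(s) >= prevalence:
                k = a
                break
        assert min_crossing_angle(angles, prevalence) == pytest.approx(k)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            min_crossing_angle([], 0.01)


class TestFiberCount:
    def test_both_two_qualifying(self):
        p = peakset([(1, 0, 0), (0, 1, 0)], [0.6, 0.4])
        assert fiber_count(p, p, 0.1) == 2

    def test_minimum_rule(self):
        p3 = peakset([(1, 0, 0), (0, 1, 0), (0, 0, 1)], [0.4, 0.35, 0.25])
        p1 = peakset([(1, 0, 0)], [1.0])
        assert fiber_count(p3, p1, 0.1) == 1

    def test_threshold_enumeration(self):
        p_a = peakset([(1, 0, 0), (0, 1, 0), (0, 0, 1)], [0.85, 0.1, 0.05])
        p_b = peakset([(1, 0, 0), (0, 1, 0)], [0.7, 0.3])
        # fractions > 0.1: A has 1 (0.85), B has 2 -> min = 1
        assert fiber_count(p_a, p_b, 0.1) == 1
        # threshold 0.04: A has 3, B has 2 -> 2
        assert fiber_count(p_a, p_b, 0.04) == 2

    def test_cap_at_three(self):
        dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1)]
        p = peakset(dirs, [0.2] * 5)
        assert fiber_count(p, p, 0.1) == 3


class TestReliability:
    def test_exact_repeat_gives_perfect_scores(self):
        x = np.array([0.3, 0.5, 0.7, 0.4, 0.6])
        assert icc(x, x.copy()) == pytest.approx(1.0)
        assert wscv(x, x.copy()) == pytest.approx(0.0)

    def test_pure_noise_gives_nonpositive_icc(self):
        rng = np.random.default_rng(0)
        iccs = [icc(0.5 + rng.normal(0, 0.1, 50),
                    0.5 + rng.normal(0, 0.1, 50)) for _ in range(200)]
        assert np.mean(iccs) == pytest.approx(0.0, abs=0.02)

    def test_matches_pingouin_icc1(self):
        """Cross-check against an established implementation (ICC1)."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(1)
        scan = 0.5 + rng.normal(0, 0.05, 30)
        rescan = scan + rng.normal(0, 0.02, 30)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(30), 2),
            "rater": np.repeat(["scan", "rescan"], 30),
            "value": np.concatenate([scan, rescan])})
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="value")
        icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert icc(scan, rescan) == pytest.approx(icc1, abs=1e-10)

    def test_variance_component_recovery(self):
        """Across replicate simulations with known variance components the
        mean ICC and wsCV land within 3 Monte-Carlo SEs of the generating
        closed forms."""
        mu, sb, sw = 0.5, 0.04, 0.01
        iccs, wscvs = [], []
        for rep in range(50):
            ds = trt_replicates(mu, sb, sw, n_subjects=200, seed=1000 + rep)
            iccs.append(icc(ds.scan, ds.rescan))
            wscvs.append(wscv(ds.scan, ds.rescan))
        true_icc = sb**2 / (sb**2 + sw**2)
        true_wscv = sw / mu * 100
        se_icc = np.std(iccs) / np.sqrt(len(iccs))
        se_wscv = np.std(wscvs) / np.sqrt(len(wscvs))
        assert abs(np.mean(iccs) - true_icc) < 3 * se_icc
        assert abs(np.mean(wscvs) - true_wscv) < 3 * se_wscv

    def test_acceptance_band_reachable_at_low_noise(self):
        """A low-noise regime produces ICC > 0.85 and wsCV < 4% — the bands
        used to call a protocol reliable and repeatable."""
        ds = trt_replicates(mu=0.5, sigma_between=0.05, sigma_within=0.005,
                            n_subjects=200, seed=7)
        rep = trt_report(ds.scan, ds.rescan)
        assert rep.icc > 0.85
        assert rep.wscv < 4.0

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValueError):
            wscv(np.array([1.0, -1.0]), np.array([-1.0, 1.0]))
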