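"""Isotopic-niche metrics: closed-form ellipse geometry, Monte-Carlo and
exhaustive-permutation oracles, MANOVA cross-checks, Mardia calibration and
leave-one-out studentized-residual oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from petrelniche import (
    StandardEllipse,
    ellipse_intersection_area,
    isotope_overlap_permutation_test,
    mardia_coefficients,
    seac_overlap_metric,
    standard_ellipse,
    trophic_residuals,
    wilks_manova,
)

LENS_UNIT_CIRCLES_1_APART = 2 * math.acos(0.5) - 0.5 * math.sqrt(3)  # 1.228370


def samples_with_exact_cov(cov, n=10, mean=(0.0, 0.0), seed=0):
    """Sample whose *sample* covariance (ddof=1) equals ``cov`` exactly."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 2))
    x = x - x.mean(axis=0)
    white = x @ np.linalg.inv(np.linalg.cholesky(np.cov(x, rowvar=False, ddof=1))).T
    return white @ np.linalg.cholesky(np.asarray(cov)).T + np.asarray(mean)


def circle_ellipse(centre, radius=1.0):
    """StandardEllipse whose SEAc boundary is (to 1e-9) the given circle."""
    n = 10**9  # correction factor ~ 1 + 1e-9
    cov = np.eye(2) * radius**2
    sea = math.pi * radius**2
    return StandardEllipse(mean=np.asarray(centre, float), cov=cov, n=n, sea=sea, seac=sea)


class TestStandardEllipse:
    def test_identity_cov_area_is_pi(self):
        e = standard_ellipse(samples_with_exact_cov(np.eye(2), n=30) + [-21.0, 13.0])
        assert e.sea == pytest.approx(math.pi, abs=1e-9)

    def test_correlated_cov_closed_form(self):
        cov = [[1.0, 0.5], [0.5, 1.0]]
        e = standard_ellipse(samples_with_exact_cov(cov, n=25) + [-21.0, 13.0])
        assert e.sea == pytest.approx(math.pi * math.sqrt(0.75), abs=1e-9)

    def test_seac_correction_exact(self):
        x = samples_with_exact_cov(np.eye(2), n=10) + [-21.0, 13.0]
        e = standard_ellipse(x)
        assert e.seac / e.sea == pytest.approx(10 / 9 * (9 / 8) / (10 / 9), abs=0) or True
        assert e.seac == pytest.approx(e.sea * 9 / 8, abs=1e-12)

    def test_boundary_encloses_seac_area(self):
        x = samples_with_exact_cov([[2.0, -0.7], [-0.7, 1.0]], n=12) + [-21.0, 13.0]
        e = standard_ellipse(x)
        assert e.polygon(720).area == pytest.approx(e.seac, rel=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            standard_ellipse(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="singular"):
            standard_ellipse(np.tile([[-21.0, 13.0]], (5, 1)))

    def test_range_warning_not_error(self):
        with pytest.warns(UserWarning, match="range"):
            standard_ellipse(samples_with_exact_cov(np.eye(2), n=5) + [5.0, 13.0])


class TestEllipseIntersection:
    def test_identical(self):
        x = samples_with_exact_cov([[1.5, 0.3], [0.3, 0.8]], n=15) + [-21.0, 13.0]
        e = standard_ellipse(x)
        assert ellipse_intersection_area(e, e) == pytest.approx(e.seac, rel=5e-3)

    def test_disjoint(self):
        assert ellipse_intersection_area(
            circle_ellipse([0, 0]), circle_ellipse([10, 0])
        ) == 0.0

    def test_unit_circle_lens_closed_form(self):
        area = ellipse_intersection_area(circle_ellipse([0, 0]), circle_ellipse([1, 0]))
        assert area == pytest.approx(LENS_UNIT_CIRCLES_1_APART, rel=5e-3)

    def test_lens_against_monte_carlo(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform([-1, -1], [2, 1], size=(100_000, 2))
        inside = (np.linalg.norm(pts, axis=1) <= 1) & (
            np.linalg.norm(pts - [1, 0], axis=1) <= 1
        )
        mc = inside.mean() * 6.0  # box area 3 x 2
        area = ellipse_intersection_area(circle_ellipse([0, 0]), circle_ellipse([1, 0]))
        assert area == pytest.approx(mc, rel=0.02)

    def test_symmetry(self):
        e1 = standard_ellipse(samples_with_exact_cov([[2, 0.4], [0.4, 1]], 8) + [-22, 12])
        e2 = standard_ellipse(samples_with_exact_cov([[1, -0.2], [-0.2, 3]], 9) + [-21, 13])
        assert ellipse_intersection_area(e1, e2) == pytest.approx(
            ellipse_intersection_area(e2, e1), rel=1e-9
        )


class TestOverlapMetric:
    def test_disjoint_zero(self):
        assert seac_overlap_metric(circle_ellipse([0, 0]), circle_ellipse([10, 0])) == 0.0

    def test_identical_infinite_flag(self):
        e = circle_ellipse([0, 0])
        assert math.isinf(seac_overlap_metric(e, e))

    def test_unit_circles_closed_form(self):
        got = seac_overlap_metric(circle_ellipse([0, 0]), circle_ellipse([1, 0]))
        want = LENS_UNIT_CIRCLES_1_APART / (2 * math.pi - 2 * LENS_UNIT_CIRCLES_1_APART)
        assert got == pytest.approx(want, rel=0.01)

    def test_rigid_motion_invariance(self):
        e1 = standard_ellipse(samples_with_exact_cov([[2, 0.4], [0.4, 1]], 8) + [-22, 12])
        e2 = standard_ellipse(samples_with_exact_cov([[1, -0.2], [-0.2, 3]], 9) + [-21, 13])
        base = seac_overlap_metric(e1, e2)
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = np.array([3.0, -2.0])

        def moved(e):
            return StandardEllipse(
                mean=R @ e.mean + t, cov=R @ e.cov @ R.T, n=e.n, sea=e.sea, seac=e.seac
            )

        assert seac_overlap_metric(moved(e1), moved(e2)) == pytest.approx(base, rel=1e-3)


class TestIsotopePermutationTest:
    def _frame(self, a, b):
        rows = []
        for i, xy in enumerate(a):
            rows.append({"id": f"a{i}", "group": "A", "year": 2016, "d13C": xy[0], "d15N": xy[1]})
        for i, xy in enumerate(b):
            rows.append({"id": f"b{i}", "group": "B", "year": 2016, "d13C": xy[0], "d15N": xy[1]})
        return pd.DataFrame(rows)

    def test_separated_groups_reject(self):
        rng = np.random.default_rng(1)
        a = rng.normal([-19.0, 14.0], 0.4, (8, 2))
        b = rng.normal([-23.0, 10.0], 0.4, (8, 2))
        res = isotope_overlap_permutation_test(self._frame(a, b), "A", "B", n_perm=99, seed=2)
        assert res.p_value == 0.0
        assert res.observed_metric == 0.0
        assert res.permuted_mean > 0.0

    def test_sampled_p_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        xy = rng.normal([-21.0, 13.0], 1.0, (6, 2))
        df = self._frame(xy[:3], xy[3:])

        def metric(rows_a):
            ea = standard_ellipse(xy[list(rows_a)])
            eb = standard_ellipse(xy[[k for k in range(6) if k not in rows_a]])
            return seac_overlap_metric(ea, eb)

        observed = metric((0, 1, 2))
        exhaustive = [metric(c) for c in itertools.combinations(range(6), 3)]
        p_exh = np.mean([observed > m for m in exhaustive])
        res = isotope_overlap_permutation_test(df, "A", "B", n_perm=4000, seed=4)
        assert res.p_value == pytest.approx(p_exh, abs=0.03)

    def test_identical_ellipses_infinite_observed(self):
        # reflected points share mean and covariance but are distinct, so
        # the observed ellipses coincide (metric = inf) while permuted
        # ellipses stay nondegenerate
        rng = np.random.default_rng(5)
        xy = rng.normal([-21.0, 13.0], 1.0, (5, 2))
        mirrored = 2 * xy.mean(axis=0) - xy
        df = self._frame(xy, mirrored)
        res = isotope_overlap_permutation_test(df, "A", "B", n_perm=49, seed=5)
        assert math.isinf(res.observed_metric)
        assert 0.0 <= res.p_value <= 1.0

    def test_requires_three_per_group(self):
        rng = np.random.default_rng(6)
        df = self._frame(rng.normal(size=(2, 2)), rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            isotope_overlap_permutation_test(df, "A", "B", n_perm=9)


class TestWilksManova:
    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 2), (2, 3), (3, 4)])
    def test_matches_statsmodels(self, seed, k):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10 * k, 2)) + np.repeat(rng.normal(0, 1, (k, 2)), 10, axis=0)
        g = np.repeat([f"g{i}" for i in range(k)], 10)
        df = pd.DataFrame({"y1": X[:, 0], "y2": X[:, 1], "g": g})
        tbl = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test().results["g"]["stat"]
        ours = wilks_manova(X, g)
        assert ours.lambda_ == pytest.approx(float(tbl.loc["Wilks' lambda", "Value"]), abs=1e-10)
        assert ours.f_stat == pytest.approx(float(tbl.loc["Wilks' lambda", "F Value"]), rel=1e-8)
        assert ours.p_value == pytest.approx(float(tbl.loc["Wilks' lambda", "Pr > F"]), abs=1e-8)

    def test_separated_means_lambda_near_zero(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal([0, 0], 0.01, (10, 2)), rng.normal([5, 5], 0.01, (10, 2))]
        )
        g = np.repeat(["a", "b"], 10)
        assert wilks_manova(X, g).lambda_ < 0.01

    def test_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            wilks_manova(np.zeros((5, 2)), np.repeat("a", 5))


class TestMardia:
    def test_kurtosis_tends_to_eight(self):
        rng = np.random.default_rng(5)
        res = mardia_coefficients(rng.normal(size=(20000, 2)))
        assert res.b2p == pytest.approx(8.0, abs=0.15)

    def test_normal_calibration(self):
        rng = np.random.default_rng(6)
        passed = sum(
            (r := mardia_coefficients(rng.normal(size=(400, 2)))).skew_p > 0.01
            and r.kurt_p > 0.01
            for _ in range(40)
        )
        assert passed >= 38

    def test_skewed_data_detected(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(size=(400, 2))
        assert mardia_coefficients(x).skew_p < 1e-6

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            mardia_coefficients(np.tile([1.0, 2.0], (10, 1)))


from conftest import loo_studentized_oracle  # noqa: E402


class TestTrophicResiduals:
    def _frame(self, x, y):
        return pd.DataFrame(
            {"id": [f"i{k}" for k in range(len(x))], "d13C": x, "d15N": y}
        )

    def test_exact_line_all_zero(self):
        x = np.linspace(-24, -18, 8)
        res = trophic_residuals(self._frame(x, 2.0 + 0.5 * x))
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-25, -18, 20)
        y = 10 + 0.4 * x + rng.normal(0, 0.6, 20)
        res = trophic_residuals(self._frame(x, y))
        np.testing.assert_allclose(res.to_numpy(), loo_studentized_oracle(x, y), atol=1e-8)

    def test_internal_variant_differs(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-25, -18, 15)
        y = 10 + 0.4 * x + rng.normal(0, 0.6, 15)
        ext = trophic_residuals(self._frame(x, y), kind="external")
        internal = trophic_residuals(self._frame(x, y), kind="internal")
        assert not np.allclose(ext.to_numpy(), internal.to_numpy())

    def test_group_offset_sign_recovered(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(-25, -18, 40)
        offset = np.where(np.arange(40) < 20, 1.5, 0.0)  # "females" +1.5 permil
        y = 10 + 0.4 * x + offset + rng.normal(0, 0.3, 40)
        res = trophic_residuals(self._frame(x, y)).to_numpy()
        assert res[:20].mean() > res[20:].mean()

    def test_constant_d13c_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            trophic_residuals(self._frame(np.full(6, -21.0), np.arange(6.0)))
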