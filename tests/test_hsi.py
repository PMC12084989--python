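import numpy as np
import pytest
from scipy.stats import chi2

from healthspace import ConfidenceEllipse, ellipse_jaccard, fit_ellipse, pairwise_hsi


def unit_circle(center, level=0.95):
    """Ellipse that is exactly the unit circle around ``center``."""
    r2 = chi2.ppf(level, 2)
    return ConfidenceEllipse(np.asarray(center, float), np.eye(2) / r2, level)


class TestFitEllipse:
    def test_chi_square_radius_closed_form(self):
        # for df = 2 the quantile has the closed form -2 ln(1 - level)
        e = fit_ellipse(np.random.default_rng(0).standard_normal((500, 2)))
        assert e.radius_sq == pytest.approx(-2 * np.log(0.05), rel=1e-9)
        assert e.radius_sq == pytest.approx(5.9915, abs=1e-4)

    def test_standard_normal_sample_is_near_circular(self):
        pts = np.random.default_rng(1).standard_normal((100_000, 2))
        e = fit_ellipse(pts)
        assert np.allclose(e.center, 0.0, atol=0.02)
        assert np.allclose(e.covariance, np.eye(2), atol=0.02)
        # area approximates the chi2 disc pi * r^2
        assert e.area == pytest.approx(np.pi * e.radius_sq, rel=0.02)

    def test_translation_equivariance(self):
        pts = np.random.default_rng(2).standard_normal((50, 2))
        shift = np.array([3.5, -1.25])
        e0, e1 = fit_ellipse(pts), fit_ellipse(pts + shift)
        assert np.allclose(e1.center, e0.center + shift, atol=1e-12)
        assert np.allclose(e1.covariance, e0.covariance, atol=1e-12)

    def test_minimal_input_contains_mean(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        e = fit_ellipse(pts)
        assert e.contains(pts.mean(axis=0)[None, :])[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_ellipse(np.zeros((2, 2)))

    def test_collinear_points_ridge_regularised(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.warns(RuntimeWarning, match="ridge"):
            e = fit_ellipse(pts)
        assert np.linalg.eigvalsh(e.covariance)[0] > 0


class TestEllipseJaccard:
    def test_identical_regions_give_one(self):
        e = unit_circle([0, 0])
        assert ellipse_jaccard(e, e, "grid") == pytest.approx(1.0, abs=1 / 512)
        assert ellipse_jaccard(e, e, "montecarlo", seed=3) == pytest.approx(1.0, abs=0.01)

    def test_distant_regions_give_exact_zero(self):
        a = ConfidenceEllipse(np.zeros(2), np.eye(2))
        b = ConfidenceEllipse(np.array([1000.0, 0.0]), np.eye(2))
        assert ellipse_jaccard(a, b) == 0.0

    def test_circle_overlap_matches_analytic_lens_area(self):
        # two unit circles with centers distance 1 apart
        a, b = unit_circle([0, 0]), unit_circle([1, 0])
        d, r = 1.0, 1.0
        lens = 2 * r * r * np.arccos(d / (2 * r)) - 0.5 * d * np.sqrt(4 * r * r - d * d)
        expected = lens / (2 * np.pi * r * r - lens)
        grid = ellipse_jaccard(a, b, "grid", resolution=512)
        mc = ellipse_jaccard(a, b, "montecarlo", n_samples=200_000, seed=0)
        assert grid == pytest.approx(expected, abs=0.005)
        assert mc == pytest.approx(expected, abs=0.005)
        assert abs(grid - mc) < 0.01

    def test_montecarlo_deterministic_for_fixed_seed(self):
        a, b = unit_circle([0, 0]), unit_circle([0.7, 0.4])
        v1 = ellipse_jaccard(a, b, "montecarlo", seed=11)
        v2 = ellipse_jaccard(a, b, "montecarlo", seed=11)
        assert v1 == v2

    def test_unknown_method_rejected(self):
        e = unit_circle([0, 0])
        with pytest.raises(ValueError, match="method"):
            ellipse_jaccard(e, e, "quadrature")


def four_group_points(rng, offsets, n_per=80, spread=1.0):
    pts, labels = [], []
    for g, off in enumerate(offsets):
        pts.append(rng.standard_normal((n_per, 2)) * spread + np.asarray(off))
        labels.append(np.full(n_per, g))
    return np.vstack(pts), np.concatenate(labels)


class TestPairwiseHsi:
    def test_identical_clouds_give_near_zero_hsi(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((100, 2))
        pts = np.vstack([cloud, cloud])
        labels = np.repeat([0, 1], 100)
        res = pairwise_hsi(pts, labels)
        assert res.pairwise[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_distant_groups_give_exact_one(self):
        rng = np.random.default_rng(1)
        pts, labels = four_group_points(rng, [(0, 0), (1000, 0)][:2], n_per=50)
        res = pairwise_hsi(pts, labels)
        assert res.pairwise[0, 1] == 1.0
        assert res.average == 1.0

    def test_four_groups_yield_six_pairs(self):
        rng = np.random.default_rng(2)
        pts, labels = four_group_points(rng, [(0, 0), (3, 0), (0, 3), (3, 3)])
        res = pairwise_hsi(pts, labels)
        table = res.pair_table()
        assert len(table) == 6
        assert np.all((table["hsi"] >= 0) & (table["hsi"] <= 1))
        assert res.average == pytest.approx(table["hsi"].mean())
        # symmetry with NaN diagonal
        assert np.allclose(res.pairwise, res.pairwise.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(res.pairwise)))

    def test_affine_map_leaves_hsi_unchanged(self):
        rng = np.random.default_rng(3)
        pts, labels = four_group_points(rng, [(0, 0), (2, 0), (0, 2), (2, 2)])
        base = pairwise_hsi(pts, labels).pairwise
        A = np.array([[1.4, 0.5], [-0.3, 0.8]])
        mapped = pairwise_hsi(pts @ A.T + np.array([10, -4]), labels).pairwise
        assert np.nanmax(np.abs(base - mapped)) < 0.01

    def test_translating_a_group_away_never_decreases_separation(self):
        rng = np.random.default_rng(4)
        cloud = rng.standard_normal((80, 2))
        other = rng.standard_normal((80, 2))
        labels = np.repeat([0, 1], 80)
        values = []
        for shift in (0.0, 1.0, 2.0, 4.0, 8.0):
            pts = np.vstack([cloud, other + [shift, 0]])
            values.append(pairwise_hsi(pts, labels).pairwise[0, 1])
        assert np.all(np.diff(values) >= -0.01)

    def test_small_group_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.standard_normal((50, 2)), [[5.0, 5.0], [5.1, 5.0]]])
        labels = np.array([0] * 50 + [1] * 2)
        with pytest.warns(RuntimeWarning, match="fewer than 3"):
            res = pairwise_hsi(pts, labels)
        assert np.isnan(res.pairwise[0, 1])
        assert res.missing_groups == (1,)
        assert np.isnan(res.average)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            pairwise_hsi(np.random.default_rng(6).standard_normal((10, 2)), np.zeros(10))

    def test_json_serialisable(self):
        import json

        rng = np.random.default_rng(7)
        pts, labels = four_group_points(rng, [(0, 0), (4, 0)][:2], n_per=30)
        payload = json.dumps(pairwise_hsi(pts, labels).to_dict())
        assert "average" in payload
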