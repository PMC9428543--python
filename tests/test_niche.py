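"""Standard ellipse areas, SEA_b posteriors and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reefiso.niche import (
    InsufficientDataError,
    StandardEllipseModel,
    compare_sea,
    ellipse_boundary,
    fit_standard_ellipse,
    niche_analysis,
    sample_posterior_sea,
)

DIAMOND = np.array([(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)])


class TestStandardEllipse:
    def test_diamond_worked_example(self):
        # sample covariance diag(2/3, 2/3); SEA = 2pi/3, SEA_c = pi
        res = fit_standard_ellipse(DIAMOND, "diamond")
        np.testing.assert_allclose(res.cov, np.diag([2 / 3, 2 / 3]), atol=1e-12)
        assert res.sea == pytest.approx(2 * np.pi / 3, abs=1e-12)
        assert res.sea_c == pytest.approx(np.pi, abs=1e-12)

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        res = fit_standard_ellipse(pts)
        assert res.degenerate and res.sea == 0.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_ellipse(DIAMOND[:2])

    def test_sea_c_exceeds_sea_and_converges(self, rng):
        pts = rng.standard_normal((50, 2))
        res = fit_standard_ellipse(pts)
        assert res.sea_c > res.sea
        assert res.sea_c == pytest.approx(res.sea * 49 / 48)

    def test_rotation_translation_invariance(self, rng):
        pts = rng.standard_normal((40, 2)) @ np.diag([2.0, 0.5])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([5.0, -3.0])
        a = fit_standard_ellipse(pts).sea
        b = fit_standard_ellipse(moved).sea
        assert b == pytest.approx(a, rel=1e-10)

    def test_uniform_scaling_scales_area_quadratically(self, rng):
        pts = rng.standard_normal((40, 2))
        s = 2.5
        assert fit_standard_ellipse(s * pts).sea == pytest.approx(
            s**2 * fit_standard_ellipse(pts).sea, rel=1e-10)


class TestEllipseBoundary:
    def test_95_coverage_circle_radius(self):
        res = fit_standard_ellipse(DIAMOND)
        # identity-covariance analogue: scale diamond cov to identity
        res.cov = np.eye(2)
        ring = ellipse_boundary(res, coverage=0.95)
        radii = np.linalg.norm(ring - res.mean, axis=1)
        np.testing.assert_allclose(radii, np.sqrt(stats.chi2.ppf(0.95, 2)),
                                   atol=1e-9)

    def test_standard_ellipse_is_unit_circle_for_identity(self):
        res = fit_standard_ellipse(DIAMOND)
        res.cov = np.eye(2)
        # default (coverage=None) is the 1-sd ellipse: the unit circle,
        # enclosing 1 - e^(-1/2) ~ 39.35% of mass
        ring = ellipse_boundary(res)
        np.testing.assert_allclose(np.linalg.norm(ring - res.mean, axis=1), 1.0,
                                   atol=1e-9)
        assert stats.chi2.cdf(1.0, 2) == pytest.approx(1 - np.exp(-0.5))

    def test_boundary_satisfies_quadratic_form(self, rng):
        pts = rng.standard_normal((30, 2)) @ np.array([[1.5, 0.3], [0.0, 0.6]])
        res = fit_standard_ellipse(pts)
        ring = ellipse_boundary(res, coverage=0.40)
        q = stats.chi2.ppf(0.40, 2)
        inv = np.linalg.inv(res.cov)
        d = ring - res.mean
        forms = np.einsum("ij,jk,ik->i", d, inv, d)
        np.testing.assert_allclose(forms, q, atol=1e-9)

    def test_closed_ring(self, rng):
        res = fit_standard_ellipse(rng.standard_normal((10, 2)))
        ring = ellipse_boundary(res)
        np.testing.assert_allclose(ring[0], ring[-1], atol=1e-12)


class TestPosteriorSEA:
    def test_seeded_determinism(self, rng):
        pts = rng.standard_normal((30, 2))
        a = sample_posterior_sea(pts, iterations=500, seed=7)
        b = sample_posterior_sea(pts, iterations=500, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draws_positive_and_intervals_nested(self, rng):
        post = sample_posterior_sea(rng.standard_normal((30, 2)),
                                    iterations=2000, seed=1)
        assert np.all(post.draws > 0)
        ci = post.credible_intervals
        assert ci[0.50][0] >= ci[0.75][0] >= ci[0.95][0]
        assert ci[0.50][1] <= ci[0.75][1] <= ci[0.95][1]

    def test_large_n_posterior_consistency(self, rng):
        pts = rng.standard_normal((500, 2))
        post = sample_posterior_sea(pts, iterations=4000, seed=3)
        assert post.draws.mean() == pytest.approx(np.pi, rel=0.05)


class TestCompareSEA:
    def test_unequal_lengths_rejected(self, rng):
        pts = rng.standard_normal((20, 2))
        a = sample_posterior_sea(pts, iterations=100, seed=0)
        b = sample_posterior_sea(pts, iterations=200, seed=1)
        with pytest.raises(ValueError):
            compare_sea(a, b)

    def test_same_points_different_seeds_symmetric(self, rng):
        pts = rng.standard_normal((100, 2))
        a = sample_posterior_sea(pts, iterations=10_000, seed=11)
        b = sample_posterior_sea(pts, iterations=10_000, seed=12)
        assert compare_sea(a, b).p_a_greater == pytest.approx(0.5, abs=0.02)

    def test_complementarity(self, rng):
        a = sample_posterior_sea(rng.standard_normal((20, 2)), 1000, seed=0)
        b = sample_posterior_sea(2 * rng.standard_normal((20, 2)), 1000, seed=1)
        assert compare_sea(a, b).p_a_greater + compare_sea(b, a).p_a_greater \
            == pytest.approx(1.0)

    def test_doubled_covariance_detected(self, rng):
        base = rng.standard_normal((200, 2))
        big = np.sqrt(2.0) * rng.standard_normal((200, 2))  # doubled covariance
        a = sample_posterior_sea(big, iterations=5000, seed=5)
        b = sample_posterior_sea(base, iterations=5000, seed=6)
        cmp = compare_sea(a, b)
        assert cmp.p_a_greater > 0.99 and cmp.significant


class TestNicheAnalysis:
    @staticmethod
    def _frame(rng):
        rows = []
        for label, scale in (("small", 1.0), ("mid", 2.0), ("large", 4.0)):
            pts = np.sqrt(scale) * rng.standard_normal((200, 2))
            for x, y in pts:
                rows.append({"atoll": label, "d13c_normalized": x, "d15n": y})
        return pd.DataFrame(rows)

    def test_injected_area_ordering_recovered(self, rng):
        res = niche_analysis(self._frame(rng), "atoll", iterations=3000, seed=9)
        modes = {k: p.mode for k, p in res.posteriors.items()}
        assert modes["small"] < modes["mid"] < modes["large"]

    def test_identical_groups_share_letter(self, rng):
        pts = rng.standard_normal((100, 2))
        df = pd.concat([
            pd.DataFrame({"atoll": "A", "d13c_normalized": pts[:, 0],
                          "d15n": pts[:, 1]}),
            pd.DataFrame({"atoll": "B", "d13c_normalized": pts[:, 0],
                          "d15n": pts[:, 1]}),
        ])
        res = niche_analysis(df, "atoll", iterations=2000, seed=4)
        assert set(res.letters["A"]) & set(res.letters["B"])

    def test_significant_pairs_share_no_letter(self, rng):
        res = niche_analysis(self._frame(rng), "atoll", iterations=3000, seed=9)
        for c in res.comparisons:
            common = set(res.letters[c.group_a]) & set(res.letters[c.group_b])
            if c.significant:
                assert not common
            else:
                assert common

    def test_taxon_grouping_segregates_trophic_levels(self, paper_like):
        from reefiso.isotopes import process_tissue_table
        from reefiso.niche import combine_taxa

        _, _, tissue, _, baselines = paper_like
        taxa = combine_taxa(process_tissue_table(tissue), baselines)
        res = niche_analysis(taxa, "taxon", iterations=2000, seed=1)
        assert set(res.ellipses) == {"fish", "POM", "zooplankton"}
        # trophic ordering along the d15n axis: POM < zooplankton < fish
        means = {k: e.mean[1] for k, e in res.ellipses.items()}
        assert means["POM"] < means["zooplankton"] < means["fish"]

    def test_small_group_skipped_with_warning(self, rng):
        df = self._frame(rng)
        df = pd.concat([df, pd.DataFrame({"atoll": ["tiny"] * 2,
                                          "d13c_normalized": [0.0, 1.0],
                                          "d15n": [0.0, 1.0]})])
        with pytest.warns(UserWarning, match="tiny"):
            res = niche_analysis(df, "atoll", iterations=200, seed=0)
        assert "tiny" not in res.ellipses
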