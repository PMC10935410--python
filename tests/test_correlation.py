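"""Correlation grids, significance classes and anchor profiles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from lithnet.correlation import (
    CLASS_MODERATE,
    CLASS_NS,
    CLASS_SELF,
    CLASS_STRONG,
    CorrelationGrid,
    anchor_profile,
    classify_significance,
    compare_grids,
    pairwise_correlation,
)
from lithnet.errors import ValidationError
from lithnet.synthetic import CohortConfig, apply_treatment_effect, generate_cohort


def _table_from_matrix(X, analytes, group="responder", cell_type="CD4",
                       timepoint="baseline"):
    rows = []
    for i, row in enumerate(X):
        for a, v in zip(analytes, row):
            rows.append((f"s{i:02d}", group, timepoint, cell_type, a, float(v)))
    return make_table(rows)


class TestClassify:
    @pytest.mark.parametrize(
        ("p", "expected"),
        [
            (0.005, CLASS_STRONG),
            (0.0099, CLASS_STRONG),
            (0.01, CLASS_MODERATE),  # boundary: strict < for the strong class
            (0.03, CLASS_MODERATE),
            (0.05, CLASS_MODERATE),
            (0.0501, CLASS_NS),
            (0.2, CLASS_NS),
            (1.0, CLASS_NS),
        ],
    )
    def test_legend_thresholds(self, p, expected):
        assert classify_significance(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.0001, float("nan")])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValidationError):
            classify_significance(p)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_unique_function_consistent_with_inequalities(self, p):
        cls = classify_significance(p)
        assert (cls == CLASS_STRONG) == (p < 0.01)
        assert (cls == CLASS_MODERATE) == (0.01 <= p <= 0.05)
        assert (cls == CLASS_NS) == (p > 0.05)


class TestGrid:
    def test_perfect_linear_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = _table_from_matrix(np.column_stack([x, 2 * x + 1]), ("A", "B"))
        grid = pairwise_correlation(table, "CD4", "responder")
        assert grid.r2[0, 1] == pytest.approx(1.0)
        assert grid.p[0, 1] == 0.0
        assert grid.classes()[0, 1] == CLASS_STRONG
        assert grid.classes()[0, 0] == CLASS_SELF
        assert grid.r[0, 0] == 1.0

    def test_symmetry_and_permutation_equivariance(self, study_cohort):
        order = tuple(sorted(study_cohort.analytes()))
        grid = pairwise_correlation(study_cohort, "CD4", "responder",
                                    analytes=order)
        np.testing.assert_allclose(grid.r, grid.r.T)
        np.testing.assert_allclose(grid.p, grid.p.T, equal_nan=True)
        rev = order[::-1]
        grid_rev = pairwise_correlation(study_cohort, "CD4", "responder",
                                        analytes=rev)
        perm = [rev.index(a) for a in order]
        np.testing.assert_allclose(grid.r, grid_rev.r[np.ix_(perm, perm)])

    def test_r2_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3)) + 5.0
        t1 = _table_from_matrix(X, ("A", "B", "C"))
        X2 = X.copy()
        X2[:, 1] = 3.0 * X2[:, 1] + 2.0
        t2 = _table_from_matrix(X2, ("A", "B", "C"))
        g1 = pairwise_correlation(t1, "CD4", "responder")
        g2 = pairwise_correlation(t2, "CD4", "responder")
        np.testing.assert_allclose(g1.r2, g2.r2, atol=1e-12)
        np.testing.assert_allclose(g1.p, g2.p, atol=1e-12)

    def test_constant_analyte_flagged_not_fatal(self):
        X = np.column_stack([np.arange(5.0) + 1, np.full(5, 2.0), np.arange(5.0) ** 2 + 1])
        grid = pairwise_correlation(_table_from_matrix(X, ("A", "B", "C")),
                                    "CD4", "responder")
        assert np.isnan(grid.r[0, 1])
        assert grid.classes()[0, 1] == CLASS_NS
        assert grid.count_significant(0.05) >= 0  # NaNs never counted

    def test_too_few_subjects_rejected(self):
        X = np.array([[1.0, 2.0], [2.0, 3.0]])
        with pytest.raises(ValidationError, match=">= 3 subjects"):
            pairwise_correlation(_table_from_matrix(X, ("A", "B")), "CD4", "responder")

    def test_missing_stratum_rejected(self, study_cohort):
        with pytest.raises(ValidationError, match="no records"):
            pairwise_correlation(study_cohort, "NK", "nonresponder", "baseline")

    def test_pair_universe_of_28_analyte_grid(self, study_cohort):
        grid = pairwise_correlation(study_cohort, "CD4", "responder")
        n_pairs = len(list(combinations(range(28), 2)))
        assert n_pairs == 378
        assert grid.count_significant(1.0) <= n_pairs
        # every p defined here, so counting at level 1.0 covers all pairs
        assert grid.count_significant(1.0) == n_pairs

    def test_responders_more_correlated_than_nonresponders(self):
        cfg = CohortConfig(factor_loading_resp=2.0, factor_loading_nonresp=0.0,
                           rng_seed=21)
        table = generate_cohort(cfg)
        g_resp = pairwise_correlation(table, "CD4", "responder")
        g_non = pairwise_correlation(table, "CD4", "nonresponder")
        assert g_resp.count_significant(0.05) > g_non.count_significant(0.05)
        assert g_resp.count_significant(0.01) > g_non.count_significant(0.01)

    def test_analytic_p_matches_unconditional_null_simulation(self):
        """The t-based p equals the exact null law of r under bivariate normality.

        Oracle: 200,000 fresh independent normal pairs give the Monte-Carlo
        null distribution of |r|; the analytic tail probability must agree
        within 3 Monte-Carlo standard errors.
        """
        n = 9
        rng = np.random.default_rng(123)
        null = rng.standard_normal((200_000, n, 2))
        xc = null[:, :, 0] - null[:, :, 0].mean(axis=1, keepdims=True)
        yc = null[:, :, 1] - null[:, :, 1].mean(axis=1, keepdims=True)
        r_null = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        X = rng.standard_normal((n, 2))
        X[:, 1] = 0.6 * X[:, 0] + 0.8 * X[:, 1]
        grid = pairwise_correlation(_table_from_matrix(X + 10.0, ("A", "B")),
                                    "CD4", "responder")
        r_obs, p_obs = abs(grid.r[0, 1]), grid.p[0, 1]
        p_mc = np.mean(np.abs(r_null) >= r_obs)
        se = max(np.sqrt(p_mc * (1 - p_mc) / len(r_null)), 1 / len(r_null))
        assert abs(p_obs - p_mc) <= 3 * se


class TestAnchorProfile:
    def test_profile_excludes_anchor_and_matches_grid(self, study_cohort):
        prof = anchor_profile(study_cohort, "GSK3β", "CD4", "responder")
        assert len(prof.analytes) == 27
        assert "GSK3β" not in prof.analytes
        assert prof.n_baseline == prof.n_post == 9
        paired = study_cohort.paired_subjects("responder")
        grid = pairwise_correlation(study_cohort, "CD4", "responder", "baseline",
                                    subjects=paired)
        idx = grid.analytes.index("GSK3β")
        for k, a in enumerate(prof.analytes):
            j = grid.analytes.index(a)
            assert prof.r2_baseline[k] == pytest.approx(grid.r2[idx, j], nan_ok=True)

    def test_unknown_anchor_rejected(self, study_cohort):
        with pytest.raises(ValidationError, match="anchor"):
            anchor_profile(study_cohort, "NOTINPANEL", "CD4", "responder")

    def test_too_few_paired_subjects_rejected(self):
        cfg = CohortConfig(n_responders=5, n_nonresponders=4, n_analytes=4,
                           cell_types=("CD4",), n_post_responders=2,
                           n_post_nonresponders=0, rng_seed=1)
        table = apply_treatment_effect(generate_cohort(cfg), cfg)
        with pytest.raises(ValidationError, match="paired subjects"):
            anchor_profile(table, "A01", "CD4", "responder")

    def test_decorrelated_cohort_loses_post_significance(self):
        cfg = CohortConfig(post_decorrelation_resp=0.0, rng_seed=17)
        table = apply_treatment_effect(generate_cohort(cfg), cfg)
        prof = anchor_profile(table, "GSK3β", "CD4", "responder")
        assert prof.count_significant(0.05, "post") < prof.count_significant(0.05, "baseline")


class TestCompareGrids:
    @staticmethod
    def _grid_with_p(analytes, p, n=10):
        m = len(analytes)
        P = np.asarray(p, dtype=float)
        R = np.sqrt(1 - np.minimum(P, 1.0))  # placeholder r of matching shape
        np.fill_diagonal(P, 0.0)
        np.fill_diagonal(R, 1.0)
        return CorrelationGrid("CD4", "responder", "baseline", tuple(analytes), n, R, P)

    def test_identity_comparison(self):
        p = [[0, 0.001, 0.2], [0.001, 0, 0.04], [0.2, 0.04, 0]]
        g = self._grid_with_p(("A", "B", "C"), p)
        cmp = compare_grids(g, g)
        assert cmp.difference == {0.05: 0, 0.01: 0}
        assert cmp.shared_pairs == g.significant_pairs(0.05) == {("A", "B"), ("B", "C")}

    def test_disjoint_significant_sets(self):
        p1 = [[0, 0.001, 0.8], [0.001, 0, 0.9], [0.8, 0.9, 0]]
        p2 = [[0, 0.8, 0.9], [0.8, 0, 0.001], [0.9, 0.001, 0]]
        g1 = self._grid_with_p(("A", "B", "C"), p1)
        g2 = self._grid_with_p(("A", "B", "C"), p2)
        cmp = compare_grids(g1, g2)
        assert cmp.shared_pairs == frozenset()
        assert cmp.counts_a[0.05] == cmp.counts_b[0.05] == 1

    def test_panel_mismatch_rejected(self):
        p = [[0, 0.5], [0.5, 0]]
        g1 = self._grid_with_p(("A", "B"), p)
        g2 = self._grid_with_p(("A", "C"), p)
        with pytest.raises(ValidationError, match="different analyte panels"):
            compare_grids(g1, g2)
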