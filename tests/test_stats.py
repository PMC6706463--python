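"""Group statistics: ANOVA, chi-squared, correlations, ROI machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plinet.montage import Montage
from plinet.stats import (
    ROISet,
    anova_from_summary,
    anova_oneway,
    chi_square_contingency,
    default_rois,
    define_rois,
    electrodewise_anova,
    pearson_correlation,
    posthoc_bonferroni,
)

# Published three-group demographics: per-group mean, SD, n = 28/21/28,
# and the F statistic printed alongside.
TABLE_SUMMARIES = {
    "education": ([13.43, 13.76, 12.25], [3.72, 3.10, 3.30], 1.399),
    "GAF": ([86.86, 57.14, 54.75], [8.99, 13.04, 11.84], 68.278),
    "CDSST": ([0.14, 1.90, 1.21], [0.53, 2.41, 1.19], 8.918),
}


class TestAnovaOneway:
    def test_identical_group_means_give_zero_f(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_within_variance_reported(self):
        res = anova_oneway({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        assert np.isinf(res.statistic)
        assert res.p == 0.0

    def test_all_constant_equal_groups(self):
        res = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_dfs(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [2, 3, 4], "c": [0, 1, 5]})
        assert res.df == (2, 6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.lists(
        st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        min_size=2, max_size=4,
    ))
    def test_raw_data_matches_summary_form(self, groups):
        named = {str(i): np.asarray(g) for i, g in enumerate(groups)}
        raw = anova_oneway(named)
        summ = anova_from_summary(
            [v.mean() for v in named.values()],
            [v.std(ddof=1) for v in named.values()],
            [len(v) for v in named.values()],
        )
        if np.isfinite(raw.statistic):
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
            assert raw.p == pytest.approx(summ.p, abs=1e-10)


class TestAnovaFromSummary:
    @pytest.mark.parametrize("name", sorted(TABLE_SUMMARIES))
    def test_reproduces_published_f_values(self, name):
        means, sds, f_printed = TABLE_SUMMARIES[name]
        res = anova_from_summary(means, sds, [28, 21, 28])
        assert res.df == (2, 74)
        assert res.statistic == pytest.approx(f_printed, rel=0.01)

    def test_equal_means_give_zero(self):
        res = anova_from_summary([5.0, 5.0], [1.0, 2.0], [10, 12])
        assert res.statistic == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_from_summary([1.0, 2.0], [0.5, 0.5], [1, 5])


class TestChiSquare:
    def test_sex_ratio_contingency_reproduces_published_value(self):
        res = chi_square_contingency([[19, 9], [13, 8], [14, 14]])
        assert res.df == (2,)
        assert res.statistic == pytest.approx(1.912, abs=5e-4)
        assert res.p == pytest.approx(0.384, abs=5e-3)

    def test_proportional_table_gives_zero(self):
        res = chi_square_contingency([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_hand_computation(self):
        res = chi_square_contingency([[12, 8], [6, 14]])
        assert res.statistic == pytest.approx(40.0 / 11.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 30, (3, 4))
        base = chi_square_contingency(table).statistic
        perm = table[np.ix_([2, 0, 1], [3, 1, 0, 2])]
        assert chi_square_contingency(perm).statistic == pytest.approx(base)

    def test_zero_margin_named(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_square_contingency([[5, 0], [3, 0]])


class TestPosthocBonferroni:
    def test_identical_groups_all_capped_at_one(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                  "c": [1.0, 2.0, 3.0]}
        assert all(p == 1.0 for p in posthoc_bonferroni(groups).values())

    def test_adjustment_is_pair_count_times_raw(self, rng):
        from scipy.stats import ttest_ind

        groups = {g: rng.standard_normal(8) + shift
                  for g, shift in [("a", 0.0), ("b", 0.5), ("c", 2.0)]}
        adj = posthoc_bonferroni(groups)
        for (g1, g2), p in adj.items():
            raw = ttest_ind(groups[g1], groups[g2]).pvalue
            assert p == pytest.approx(min(1.0, 3 * raw))


class TestPearsonCorrelation:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.n == 5

    def test_affine_invariance_and_negation(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r0 = pearson_correlation(x, y).r
        assert pearson_correlation(3 * x + 2, 0.5 * y - 7).r == pytest.approx(r0)
        assert pearson_correlation(x, -y).r == pytest.approx(-r0)

    def test_bonferroni_adjustment(self, rng):
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        res = pearson_correlation(x, y, n_tests=6)
        assert res.p_adjusted == pytest.approx(min(1.0, 6 * res.p))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestElectrodewiseAnova:
    def test_identical_subjects_give_zero_f(self):
        maps = {"a": np.ones((4, 6)), "b": np.ones((3, 6))}
        out = electrodewise_anova(maps)
        assert len(out) == 6
        assert np.allclose(out["F"], 0.0, atol=1e-12)

    def test_injected_effect_attains_minimum_p(self, rng):
        n_el = 12
        maps = {g: rng.standard_normal((8, n_el)) for g in ("a", "b", "c")}
        maps["c"][:, 5] += 10.0
        out = electrodewise_anova(maps)
        assert out["p"].idxmin() == 5

    def test_mismatched_electrode_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="electrode set"):
            electrodewise_anova({"a": np.ones((3, 5)), "b": np.ones((3, 6))})


def clustered_montage():
    """Three tight spatial clusters matching the reference ROI electrode
    lists, on a 128-electrode layout with explicit chain adjacency."""
    rois = default_rois().rois
    ids = tuple(range(1, 129))
    xy = np.zeros((128, 2))
    regions = []
    centers = {"ROI1": (0.0, 0.1), "ROI2": (0.6, 0.0), "ROI3": (-0.5, -0.6)}
    labels = {"ROI1": "P", "ROI2": "T_R", "ROI3": "O"}
    roi_of = {}
    for name, members in rois.items():
        for k, eid in enumerate(members):
            roi_of[eid] = name
            cx, cy = centers[name]
            xy[eid - 1] = (cx + 0.01 * k, cy)
    rest = [i for i in ids if i not in roi_of]
    for k, eid in enumerate(rest):
        xy[eid - 1] = (-0.9 + 1.8 * (k / len(rest)), 0.9)
    for eid in ids:
        regions.append(labels.get(roi_of.get(eid), "F"))
    neighbors = set()
    for name, members in rois.items():
        for a, b in zip(members, members[1:]):
            neighbors.add(frozenset((a, b)))
    for a, b in zip(rest, rest[1:]):
        neighbors.add(frozenset((a, b)))
    return Montage(ids=ids, xy=xy, regions=tuple(regions),
                   neighbors=frozenset(neighbors))


class TestDefineRois:
    def test_reference_electrode_lists_recovered(self):
        montage = clustered_montage()
        pmap = np.ones(128)
        expected = default_rois().rois
        for members in expected.values():
            for eid in members:
                pmap[eid - 1] = 1e-5
        rois = define_rois(pmap, montage, alpha=0.001)
        got = {frozenset(v) for _, v in rois}
        assert got == {frozenset(v) for v in expected.values()}
        assert set(rois.rois) == {"P", "T_R", "O"}

    def test_all_insignificant_gives_empty_set(self):
        montage = clustered_montage()
        with pytest.warns(UserWarning, match="no electrode"):
            rois = define_rois(np.ones(128), montage)
        assert len(rois) == 0

    def test_single_significant_electrode_is_singleton_roi(self):
        montage = clustered_montage()
        pmap = np.ones(128)
        pmap[11] = 1e-6  # electrode id 12
        rois = define_rois(pmap, montage)
        assert list(rois.rois.values()) == [(12,)]

    def test_roiset_disjointness_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            ROISet({"a": (1, 2), "b": (2, 3)})


class TestRoiSummary:
    @staticmethod
    def make_inputs(rng, degree_fn):
        from plinet.metrics import SubjectNetworkProfile

        rows, profiles = [], {}
        for k, group in enumerate(["HC"] * 3 + ["UHR"] * 3 + ["FES"] * 3):
            sid = f"{group}{k}"
            rows.append({"subject_id": sid, "group": group,
                         "MCCB": 40.0 - k, "GAF": 80.0 - 2 * k})
            profiles[sid] = SubjectNetworkProfile(
                subject_id=sid, auc={}, degree_auc=degree_fn(k),
            )
        return profiles, pd.DataFrame(rows)

    def test_uniform_degree_map_gives_uniform_roi_means(self, rng):
        from plinet.stats import roi_summary

        profiles, cohort = self.make_inputs(rng, lambda k: np.full(128, 2.5))
        out = roi_summary(profiles, default_rois(), cohort)
        for vals in out["roi_means"].values():
            assert all(v == pytest.approx(2.5) for v in vals.values())

    def test_single_electrode_roi_mean_is_that_electrode(self, rng):
        from plinet.stats import roi_summary

        degmaps = {}

        def degree_fn(k):
            d = rng.uniform(0, 1, 12)
            degmaps[k] = d
            return d

        profiles, cohort = self.make_inputs(rng, degree_fn)
        out = roi_summary(profiles, ROISet({"solo": (5,)}), cohort)
        for k, (sid, v) in enumerate(out["roi_means"]["solo"].items()):
            assert v == pytest.approx(degmaps[k][4])

    def test_correlations_adjusted_over_roi_scale_pairs(self, rng):
        from plinet.stats import roi_summary

        profiles, cohort = self.make_inputs(
            rng, lambda k: np.full(128, 1.0 + 0.1 * k)
        )
        out = roi_summary(profiles, default_rois(), cohort,
                          scales=("MCCB", "GAF"))
        n_tests = 3 * 2
        for corr in out["correlations"].values():
            assert corr.p_adjusted == pytest.approx(
                min(1.0, n_tests * corr.p))
            assert corr.r < 0 or np.isnan(corr.r)
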