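"""Differential-analysis oracles: hand-computed normalization factors,
t statistics, BH step-up, consistent-set rules, imputation geometry, and
the mass-spectrometry arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibronet import differential as diff
from fibronet.matrix import OmicsMatrix, StudyDesign


def _counts(data, index=None, columns=None):
    n, m = np.asarray(data).shape
    index = index or [f"g{i}" for i in range(n)]
    columns = columns or [f"s{i}" for i in range(m)]
    return OmicsMatrix(pd.DataFrame(data, index=index, columns=columns, dtype=float),
                       "counts")


def _design(groups_per_sample, samples, reference):
    order = list(dict.fromkeys(groups_per_sample))
    return StudyDesign(dict(zip(samples, groups_per_sample)), order, reference)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = _counts([[10, 10], [5, 5]])
        assert np.allclose(diff.size_factors(m), [1.0, 1.0])

    def test_doubled_sample_splits_symmetrically(self):
        """sample2 = 2 x sample1: ratios to the geometric mean are 1/sqrt(2)
        and sqrt(2) for every gene, hence the factors."""
        m = _counts([[10, 20], [4, 8], [7, 14]])
        assert np.allclose(diff.size_factors(m), [1 / math.sqrt(2), math.sqrt(2)])

    def test_genes_with_zeros_ignored(self):
        m = _counts([[10, 10], [0, 1000]])
        assert np.allclose(diff.size_factors(m), [1.0, 1.0])

    def test_no_all_positive_gene_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            diff.size_factors(_counts([[0, 1], [1, 0]]))


class TestDeTest:
    def test_log2fc_by_direct_substitution(self):
        """Unit factors, y-scale group means 10 vs 40 on log2(count+1):
        log2fc = log2(41) - log2(11)."""
        m = _counts([[10, 10, 40, 40]])
        design = _design(["ref", "ref", "t", "t"], m.samples, "ref")
        unit = pd.Series(1.0, index=m.samples)
        table = diff.de_test(m, design, "t", factors=unit)
        assert table.loc[0, "log2fc"] == pytest.approx(math.log2(41) - math.log2(11))

    def test_welch_t_matches_closed_form(self):
        """y values {1,2,3} vs {4,5,6} (via counts 2^y - 1): Welch t =
        -3.674, df = 4, two-sided p from the t distribution."""
        from scipy import stats

        m = _counts([[1, 3, 7, 15, 31, 63]])
        design = _design(["a", "a", "a", "b", "b", "b"], m.samples, "b")
        unit = pd.Series(1.0, index=m.samples)
        table = diff.de_test(m, design, "a", factors=unit)
        t_expected = (2 - 5) / math.sqrt(1 / 3 + 1 / 3)
        assert t_expected == pytest.approx(-3.6742, abs=1e-4)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert table.loc[0, "pvalue"] == pytest.approx(p_expected, rel=1e-10)
        assert table.loc[0, "log2fc"] == pytest.approx(-3.0)

    def test_constant_equal_gene_gets_p_one(self):
        m = _counts([[5, 5, 5, 5], [1, 2, 9, 10]])
        design = _design(["a", "a", "b", "b"], m.samples, "a")
        table = diff.de_test(m, design, "b", factors=pd.Series(1.0, index=m.samples))
        row = table.set_index("feature").loc["g0"]
        assert row["pvalue"] == 1.0
        assert row["log2fc"] == 0.0

    def test_missing_contrast_group_is_error(self):
        m = _counts([[1, 2, 3, 4]])
        design = _design(["a", "a", "b", "b"], m.samples, "a")
        with pytest.raises(ValueError, match="contrast"):
            diff.de_test(m, design, "zzz")

    def test_column_order_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(50, size=(20, 10))
        m = _counts(data)
        design = _design(["a"] * 5 + ["b"] * 5, m.samples, "a")
        t1 = diff.de_test(m, design, "b")
        shuffled = m.values[list(reversed(m.samples))]
        m2 = OmicsMatrix(shuffled, "counts")
        t2 = diff.de_test(m2, design, "b")
        pd.testing.assert_frame_equal(t1, t2)


class TestBH:
    def test_singleton_identity(self):
        assert diff.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_applied_step_up(self):
        assert np.allclose(diff.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(diff.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        """Independent step-up oracle: sort ascending, q_i = p_i * n / i,
        enforce monotonicity from the largest down, cap at 1."""
        p = np.asarray(pvals)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q = p[order] * n / np.arange(1, n + 1)
        for i in range(n - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        expected = np.empty(n)
        expected[order] = np.minimum(q, 1.0)
        assert np.allclose(diff.bh_adjust(p), expected, atol=1e-12)


def _diff_table(rows):
    return pd.DataFrame(rows, columns=["feature", "log2fc", "pvalue", "padj"]).assign(
        contrast="t_vs_ref")


class TestConsistentSets:
    def test_rules_for_all_timepoint_consistency(self):
        tables = []
        for _ in range(4):
            tables.append(_diff_table([
                ("always_up", 1.0, 0.001, 0.01),
                ("always_down", -1.0, 0.001, 0.01),
                ("sometimes", 1.0, 0.001, 0.01),
            ]))
        tables[3].loc[2, "padj"] = 0.5  # "sometimes" misses one time point
        sets = diff.consistent_deg_sets(tables)
        assert sets.up == {"always_up"}
        assert sets.down == {"always_down"}

    def test_sign_flip_excluded_from_both(self):
        up2 = _diff_table([("flip", 1.0, 0.001, 0.01)])
        down2 = _diff_table([("flip", -1.0, 0.001, 0.01)])
        sets = diff.consistent_deg_sets([up2, up2, down2, down2])
        assert sets.up == set() and sets.down == set()

    def test_gene_missing_from_a_table_warns_and_excluded(self):
        a = _diff_table([("g1", 1.0, 0.001, 0.01), ("g2", 1.0, 0.001, 0.01)])
        b = _diff_table([("g1", 1.0, 0.001, 0.01)])
        with pytest.warns(UserWarning, match="missing"):
            sets = diff.consistent_deg_sets([a, b])
        assert sets.up == {"g1"}

    def test_recurrent_rule_two_of_four(self):
        sig_up = ("m1", 1.0, 0.001, 0.01)
        ns = ("m1", 1.0, 0.5, 0.9)
        tables = [_diff_table([sig_up]), _diff_table([sig_up]),
                  _diff_table([ns]), _diff_table([ns])]
        assert diff.recurrent_dm_sets(tables).up == {"m1"}

    def test_recurrent_single_timepoint_excluded(self):
        sig_up = ("m1", 1.0, 0.001, 0.01)
        ns = ("m1", 1.0, 0.5, 0.9)
        tables = [_diff_table([sig_up])] + [_diff_table([ns])] * 3
        assert diff.recurrent_dm_sets(tables).up == set()

    def test_recurrent_conflict_rule(self):
        """Up at two time points but down at one: excluded from both sets."""
        sig_up = ("m1", 1.0, 0.001, 0.01)
        sig_down = ("m1", -1.0, 0.001, 0.01)
        tables = [_diff_table([sig_up]), _diff_table([sig_up]),
                  _diff_table([sig_down])]
        sets = diff.recurrent_dm_sets(tables)
        assert sets.up == set() and sets.down == set()


def _metab(data, columns):
    return OmicsMatrix(
        pd.DataFrame(data, index=[f"m{i}" for i in range(len(data))],
                     columns=columns, dtype=float),
        "relative_peak_area")


class TestMissingFilter:
    def _design(self):
        samples = [f"s{i}" for i in range(6)]
        return samples, _design_groups(samples)

    def test_filter_rules(self):
        samples = [f"s{i}" for i in range(6)]
        design = StudyDesign(dict(zip(samples, ["a"] * 3 + ["b"] * 3)),
                             ["a", "b"], "a")
        nan = np.nan
        m = _metab([[1, 2, 3, 4, 5, 6],        # fully observed -> kept
                    [1, nan, nan, 4, 5, 6],    # 1 observed in group a -> removed
                    [1, 2, nan, nan, 5, 6]],   # 2 per group -> kept
                   samples)
        kept, removed = diff.metabolite_missing_filter(m, design, min_present=2)
        assert removed == ["m1"]
        assert list(kept.values.index) == ["m0", "m2"]

    def test_group_too_small_is_error(self):
        samples = ["s0", "s1", "s2"]
        design = StudyDesign(dict(zip(samples, ["a", "a", "b"])), ["a", "b"], "a")
        m = _metab([[1, 2, 3]], samples)
        with pytest.raises(ValueError, match="min_present"):
            diff.metabolite_missing_filter(m, design, min_present=2)

    def test_fixture_removed_count_matches_per_group_tally(self, fixture_data):
        """Exhaustive oracle: count observed values per group directly."""
        m = fixture_data["metabolites"]
        design = fixture_data["design"]
        _, removed = diff.metabolite_missing_filter(m, design, min_present=2)
        expected = []
        for feat in m.features:
            for g in design.groups:
                cols = design.samples_in(g)
                if m.values.loc[feat, cols].notna().sum() < 2:
                    expected.append(feat)
                    break
        assert sorted(removed) == sorted(expected)


def _design_groups(samples):
    return StudyDesign(dict(zip(samples, ["a"] * 3 + ["b"] * 3)), ["a", "b"], "a")


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        samples = [f"s{i}" for i in range(6)]
        m = _metab(np.arange(12).reshape(2, 6) + 1.0, samples)
        design = _design_groups(samples)
        out = diff.knn_impute(m, design)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_k1_copies_nearest_sample(self):
        samples = ["s0", "s1", "s2"]
        design = StudyDesign(dict(zip(samples, ["a"] * 3)), ["a"], "a")
        # s1 is far closer to s0 than s2 on the observed metabolite m1
        m = _metab([[np.nan, 5.0, 100.0], [10.0, 10.5, 90.0]], samples)
        out = diff.knn_impute(m, design, k=1)
        assert out.values.loc["m0", "s0"] == 5.0

    def test_equidistant_neighbors_average(self):
        samples = ["s0", "s1", "s2"]
        design = StudyDesign(dict(zip(samples, ["a"] * 3)), ["a"], "a")
        m = _metab([[np.nan, 4.0, 8.0], [10.0, 9.0, 11.0]], samples)
        out = diff.knn_impute(m, design, k=2)
        assert out.values.loc["m0", "s0"] == pytest.approx(6.0)

    def test_observed_values_never_change_and_range_respected(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        data = rng.lognormal(1, 0.5, size=(8, 6))
        mask = rng.uniform(size=data.shape) < 0.2
        mask[:, :2] = False  # keep >= 2 observed per group guaranteed
        mask[:, 3:5] = False
        holed = np.where(mask, np.nan, data)
        m = _metab(holed, samples)
        out = diff.knn_impute(m, design, k=3)
        observed = ~np.isnan(holed)
        assert np.allclose(out.values.to_numpy()[observed], holed[observed])
        for g in design.groups:
            cols = design.samples_in(g)
            block_in = m.values[cols]
            block_out = out.values[cols]
            for feat in m.features:
                lo, hi = block_in.loc[feat].min(), block_in.loc[feat].max()
                assert block_out.loc[feat].between(lo, hi).all()

    def test_all_missing_group_is_error(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = _metab([[np.nan, np.nan, np.nan, 1.0, 2.0, 3.0]], samples)
        with pytest.raises(ValueError, match="no observed value"):
            diff.knn_impute(m, design)


class TestDmTest:
    def test_identical_groups(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = _metab([[2, 2, 2, 2, 2, 2]], samples)
        t = diff.dm_test(m, design, "b")
        assert t.loc[0, "pvalue"] == 1.0
        assert t.loc[0, "log2fc"] == 0.0

    def test_effect_is_log2_ratio_of_means(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = _metab([[1.0, 1.001, 0.999, 2.0, 2.001, 1.999]], samples)
        t = diff.dm_test(m, design, "b")
        assert t.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-3)

    def test_pooled_t_matches_closed_form(self):
        """{1,2,3} vs {2,3,4}: pooled s^2 = 1, t = -1/sqrt(2/3) = -1.225,
        df = 4."""
        from scipy import stats

        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = _metab([[1, 2, 3, 2, 3, 4]], samples)
        t = diff.dm_test(m, design, "b")
        t_expected = -1 / math.sqrt(2 / 3)
        assert t_expected == pytest.approx(-1.2247, abs=1e-4)
        assert t.loc[0, "pvalue"] == pytest.approx(2 * stats.t.sf(abs(t_expected), 4),
                                                   rel=1e-10)


class TestMassSpec:
    @pytest.mark.parametrize("area,istd,amount,expected",
                             [(100, 100, 1, 1.0), (500, 200, 2, 1.25)])
    def test_relative_peak_area(self, area, istd, amount, expected):
        assert diff.relative_peak_area(area, istd, amount) == pytest.approx(expected)

    def test_relative_peak_area_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            diff.relative_peak_area(10, 0, 1)
        with pytest.raises(ValueError):
            diff.relative_peak_area(10, 10, 0)

    def test_mass_error_examples(self):
        assert diff.mass_error_ppm(100.0, 100.0) == 0.0
        assert diff.mass_error_ppm(100.001, 100.000) == pytest.approx(9.99990,
                                                                      abs=1e-4)
        with pytest.raises(ValueError):
            diff.mass_error_ppm(0.0, 100.0)

    def test_mode_tolerances(self):
        """12 ppm fails the CE window (+-10) but passes LC (+-25)."""
        assert not diff.within_tolerance(12.0, "CE")
        assert diff.within_tolerance(12.0, "LC")
        assert diff.within_tolerance(-9.9, "CE")

    def test_time_tolerances(self):
        assert diff.time_within_tolerance(0.4, "MT")
        assert not diff.time_within_tolerance(0.4, "RT")
        assert diff.time_within_tolerance(-0.3, "RT")


class TestTrajectories:
    def _mat(self, data, samples):
        return OmicsMatrix(pd.DataFrame(
            data, index=[f"f{i}" for i in range(len(data))], columns=samples,
            dtype=float), "phenotype")

    def test_constant_feature_is_zero_with_warning(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = self._mat([[3, 3, 3, 3, 3, 3]], samples)
        with pytest.warns(UserWarning, match="zero-variance"):
            traj = diff.trajectories(m, design)
        assert (traj.loc["f0"] == 0).all()

    def test_monotone_feature_gives_increasing_medians(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = self._mat([[1, 1, 1, 5, 5, 5]], samples)
        traj = diff.trajectories(m, design)
        assert traj.loc["f0", "a"] < traj.loc["f0", "b"]

    def test_feature_set_trajectory_is_median_of_member_medians(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        rng = np.random.default_rng(1)
        m = self._mat(rng.normal(size=(3, 6)), samples)
        per_feature = diff.trajectories(m, design)
        combined = diff.trajectories(m, design,
                                     feature_sets={"set": {"f0", "f1", "f2"}})
        for g in design.groups:
            assert combined.loc["set", g] == pytest.approx(
                np.median(per_feature[g]))


class TestPcaView:
    def _tpm(self, data, samples):
        return OmicsMatrix(pd.DataFrame(
            data, index=[f"g{i}" for i in range(len(data))], columns=samples,
            dtype=float), "tpm")

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 1, size=(30, 3))
        data = np.hstack([base, base])
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        coords, evr = diff.pca_view(self._tpm(data, samples), design)
        assert np.allclose(coords.loc["s0", ["PC1", "PC2"]].astype(float),
                           coords.loc["s3", ["PC1", "PC2"]].astype(float))
        assert evr.sum() <= 1.0 + 1e-9

    def test_rank_one_matrix_explained_by_pc1(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        u = np.array([[10, 20, 40, 80, 160, 320]], dtype=float)
        data = np.vstack([u * (i + 1) for i in range(10)])
        # log2(x+1) of an exact rank-1 positive matrix is near rank-1;
        # construct instead in log space: gene rows shifted copies
        data = 2 ** (np.arange(10)[:, None] + np.array([1, 2, 3, 4, 5, 6])[None, :])
        coords, evr = diff.pca_view(self._tpm(data, samples), design)
        assert evr[0] > 0.999

    def test_too_few_genes_is_error(self):
        samples = [f"s{i}" for i in range(6)]
        design = _design_groups(samples)
        m = self._tpm(np.full((3, 6), 1.0), samples)
        with pytest.raises(ValueError, match="tpm_min"):
            diff.pca_view(m, design)
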