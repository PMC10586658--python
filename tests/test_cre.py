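import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regcircuit import cre
from tests.conftest import make_peak


class TestMergeTopPeaks:
    def test_close_summits_merge_to_mean(self):
        peaks = {"A": [make_peak("chr1", 50, 150, summit_offset=50)],
                 "B": [make_peak("chr1", 100, 200, summit_offset=50)]}
        # summits 100 and 150, radius 200: windows overlap -> one CRE at 125
        cat = cre.merge_top_peaks(peaks, top_n=10, merge_radius=200)
        assert len(cat) == 1
        assert cat["summit"].iloc[0] == 125
        assert cat["source_states"].iloc[0] == "A,B"

    def test_distant_summits_stay_separate(self):
        peaks = {"A": [make_peak("chr1", 50, 150, summit_offset=50),
                       make_peak("chr1", 350, 450, summit_offset=50)]}
        cat = cre.merge_top_peaks(peaks, top_n=10, merge_radius=200)
        assert list(cat["summit"]) == [100, 400]

    def test_top_n_selection_by_score(self):
        peaks = {"A": [make_peak("chr1", i * 1000, i * 1000 + 100, name=f"p{i}", score=s)
                       for i, s in enumerate([5, 1, 9, 3, 7])]}
        cat = cre.merge_top_peaks(peaks, top_n=3, merge_radius=200)
        # scores 9, 7, 5 -> summits at peaks 2, 4, 0
        assert sorted(cat["summit"]) == [50, 2050, 4050]

    def test_empty_input_gives_empty_catalogue(self):
        cat = cre.merge_top_peaks({"A": []}, top_n=5, merge_radius=200)
        assert len(cat) == 0

    def test_ids_sorted_and_unique(self):
        peaks = {"A": [make_peak("chr2", 0, 100), make_peak("chr1", 0, 100),
                       make_peak("chr1", 5000, 5100)]}
        cat = cre.merge_top_peaks(peaks, top_n=10, merge_radius=200)
        assert list(cat["chrom"]) == ["chr1", "chr1", "chr2"]
        assert cat["cre"].is_unique

    def test_merged_summits_respect_radius(self):
        rng = np.random.default_rng(0)
        peaks = {"A": [make_peak("chr1", int(s), int(s) + 100, summit_offset=50)
                       for s in rng.integers(0, 100_000, 100)]}
        cat = cre.merge_top_peaks(peaks, top_n=1000, merge_radius=200)
        gaps = np.diff(np.sort(cat["summit"].to_numpy()))
        assert (gaps >= 200).all()

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None)
    def test_merge_order_independent(self, order):
        starts = [0, 120, 600, 5000, 5100, 9000]
        base = [make_peak("chr1", starts[i], starts[i] + 100, name=f"p{i}", summit_offset=50)
                for i in order]
        cat = cre.merge_top_peaks({"A": base}, top_n=100, merge_radius=200)
        ref = cre.merge_top_peaks(
            {"A": [make_peak("chr1", s, s + 100, summit_offset=50) for s in starts]},
            top_n=100, merge_radius=200,
        )
        assert list(cat["summit"]) == list(ref["summit"])


class TestQuantifyWindows:
    def _cat(self):
        return pd.DataFrame({"cre": ["c1"], "chrom": ["chr1"], "summit": [1000],
                             "source_states": ["A"]})

    def test_manual_overlap_count(self):
        # window [900, 1100): fragments [950,1000) and [1090,1200) overlap, [1200,1300) not
        frags = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [950, 1090, 1200],
                              "end": [1000, 1200, 1300]})
        mat = cre.quantify_windows(self._cat(), {"s1": frags}, window=200)
        assert mat.loc["c1", "s1"] == 2

    def test_no_fragments_zero_row(self):
        frags = pd.DataFrame({"chrom": [], "start": [], "end": []})
        mat = cre.quantify_windows(self._cat(), {"s1": frags}, window=200)
        assert mat.loc["c1", "s1"] == 0

    def test_abutting_fragment_not_counted(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [1100], "end": [1150]})
        mat = cre.quantify_windows(self._cat(), {"s1": frags}, window=200)
        assert mat.loc["c1", "s1"] == 0

    def test_unknown_chrom_skipped(self, caplog):
        frags = pd.DataFrame({"chrom": ["chrZ"], "start": [900], "end": [1000]})
        with caplog.at_level("WARNING"):
            mat = cre.quantify_windows(self._cat(), {"s1": frags}, window=200)
        assert mat.loc["c1", "s1"] == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        cat = pd.DataFrame({
            "cre": [f"c{i}" for i in range(50)],
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "summit": rng.integers(500, 50_000, 50),
            "source_states": ["A"] * 50,
        })
        starts = rng.integers(0, 50_000, 400)
        frags = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 400),
                              "start": starts, "end": starts + rng.integers(50, 400, 400)})
        window = 200
        mat = cre.quantify_windows(cat, {"s": frags}, window=window)
        for _, row in cat.iterrows():
            lo, hi = row.summit - 100, row.summit + 100
            expected = int(((frags.chrom == row.chrom) & (frags.start < hi) & (frags.end > lo)).sum())
            assert mat.loc[row.cre, "s"] == expected


class TestNormalizeSignal:
    def test_hand_quantile_example(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 6.0, 5.0]})
        out = cre.normalize_signal(mat, method="quantile")
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 4.5, 3.5])

    def test_identical_columns_fixed_point(self):
        mat = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        out = cre.normalize_signal(mat, method="quantile")
        pd.testing.assert_frame_equal(out, mat)

    def test_columns_share_sorted_values(self):
        # exact identity of the per-column distributions holds for tie-free
        # input; tie-averaging (tested separately) perturbs it by construction
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.random(size=(100, 4)) * 50, columns=list("abcd"))
        out = cre.normalize_signal(mat)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_array_equal(np.sort(out[col].to_numpy()), ref)

    def test_ties_get_mean_of_rank_positions(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = cre.normalize_signal(mat, method="quantile")
        # reference = mean of sorted cols = [1.5, 2.5, 4.5]; ties in a share (1.5+2.5)/2
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 4.5])

    def test_log_applied_before_quantile(self):
        mat = pd.DataFrame({"a": [0, 9, 99], "b": [0, 9, 99]})
        out = cre.normalize_signal(mat, method="log_quantile")
        np.testing.assert_allclose(out["a"], [0.0, 1.0, 2.0])

    def test_single_column_falls_back_to_log(self, caplog):
        mat = pd.DataFrame({"a": [0, 9]})
        with caplog.at_level("WARNING"):
            out = cre.normalize_signal(mat)
        np.testing.assert_allclose(out["a"], [0.0, 1.0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cre.normalize_signal(pd.DataFrame({"a": [1]}), method="rank")


class TestDifferentialCountTest:
    def test_identical_counts_nonvariable(self):
        mat = pd.DataFrame(
            {f"{s}_{i}": [50, 100, 20] for s in "AB" for i in range(3)},
            index=["c1", "c2", "c3"],
        )
        res = cre.differential_count_test(mat, ["A"] * 3 + ["B"] * 3)
        assert (res["log2fc"] == 0).all()
        assert (res["class"] == "nonvariable").all()

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(0)
        mu = np.full(300, 200.0)
        mu_a = mu.copy()
        mu_a[:30] *= 4
        k = 10.0
        a = rng.negative_binomial(k, k / (k + mu_a[:, None]), size=(300, 4))
        b = rng.negative_binomial(k, k / (k + mu[:, None]), size=(300, 4))
        mat = pd.DataFrame(np.hstack([a, b]), index=[f"c{i}" for i in range(300)])
        res = cre.differential_count_test(mat, ["A"] * 4 + ["B"] * 4)
        planted = res.iloc[:30]
        assert (planted["class"] == "A-high").mean() >= 0.9
        assert (res.iloc[30:]["class"] != "nonvariable").mean() <= 0.05

    def test_padj_at_least_p_and_class_consistency(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.poisson(100, size=(100, 6)))
        res = cre.differential_count_test(mat, ["A"] * 3 + ["B"] * 3)
        assert (res["padj"] >= res["p"] - 1e-15).all()
        classed = res[res["class"] != "nonvariable"]
        assert (classed["padj"] < 0.05).all()

    def test_single_sample_state_rejected(self):
        mat = pd.DataFrame(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError):
            cre.differential_count_test(mat, ["A", "B", "B"])


class TestTwoClassThreshold:
    def test_matches_brute_force_on_bimodal(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0.1, 0.05, 300), rng.normal(3.0, 0.3, 300)])
        t = cre.two_class_threshold(values)
        # brute-force oracle over fine candidate grid
        best, best_score = None, np.inf
        for cand in np.linspace(values.min(), values.max(), 2000)[1:-1]:
            lo, hi = values[values < cand], values[values >= cand]
            if len(lo) == 0 or len(hi) == 0:
                continue
            score = len(lo) * lo.var() + len(hi) * hi.var()
            if score < best_score:
                best_score, best = score, cand
        assert 0.1 < t < 3.0
        assert abs(t - best) < 0.3  # same valley region between the modes

    def test_constant_input(self):
        assert cre.two_class_threshold(np.full(10, 2.0)) == 2.0


class TestThresholdVarianceSelect:
    def _bimodal_matrix(self, n_low=40, n_high=40, seed=0):
        rng = np.random.default_rng(seed)
        low = rng.normal(0.1, 0.02, size=(n_low, 8))
        high = rng.normal(3.0, 0.1, size=(n_high, 8))
        high[: n_high // 2, :4] += 1.5  # A-high block
        mat = pd.DataFrame(
            np.vstack([low, high]),
            index=[f"c{i}" for i in range(n_low + n_high)],
            columns=[f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)],
        )
        return mat

    def test_low_mode_discarded(self):
        mat = self._bimodal_matrix()
        res = cre.threshold_variance_select(mat, ["A"] * 4 + ["B"] * 4)
        low_rows = res.iloc[:40]
        assert (low_rows["class"] == "nonvariable").all()

    def test_planted_high_variance_selected(self):
        mat = self._bimodal_matrix()
        res = cre.threshold_variance_select(mat, ["A"] * 4 + ["B"] * 4)
        selected = res[res["class"] != "nonvariable"]
        # the quantile rule caps selection at ~25% of retained rows; everything
        # selected must come from the planted A-high block
        assert len(selected) >= 8
        assert (selected["class"] == "A-high").all()
        assert selected.index.isin(range(40, 60)).all()

    def test_all_zero_matrix_empty_selection(self):
        mat = pd.DataFrame(np.zeros((10, 6)), columns=[f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(3)])
        res = cre.threshold_variance_select(mat, ["A"] * 3 + ["B"] * 3)
        assert (res["class"] == "nonvariable").all()

    def test_zero_difference_rows_never_selected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(3, 0.5, size=(30, 1))
        mat = pd.DataFrame(np.repeat(base, 8, axis=1),
                           columns=[f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)])
        res = cre.threshold_variance_select(mat, ["A"] * 4 + ["B"] * 4)
        assert (res["class"] == "nonvariable").all()

    def test_each_cre_classified_once(self):
        mat = self._bimodal_matrix()
        res = cre.threshold_variance_select(mat, ["A"] * 4 + ["B"] * 4, mark="H3K4me3")
        assert res["cre"].is_unique
        n_a = (res["class"] == "A-high").sum()
        n_b = (res["class"] == "B-high").sum()
        n_nv = (res["class"] == "nonvariable").sum()
        assert n_a + n_b + n_nv == len(mat)


class TestSummary:
    def test_paper_percentage_arithmetic(self):
        assert cre.differential_fraction_percent(35_348, 124_062) == 28.5

    def test_union_semantics(self):
        t1 = pd.DataFrame({"cre": ["c1", "c2", "c3"], "mark": "ATAC",
                           "class": ["A-high", "nonvariable", "B-high"]})
        t2 = pd.DataFrame({"cre": ["c1", "c2", "c3"], "mark": "H3K27ac",
                           "class": ["A-high", "B-high", "nonvariable"]})
        summ = cre.summarize_differential([t1, t2], n_total=4)
        assert summ["n_differential"] == 3  # union of {c1, c3} and {c1, c2}
        assert summ["percent_differential"] == 75.0

    def test_invalid_totals(self):
        with pytest.raises(ValueError):
            cre.differential_fraction_percent(5, 0)
        with pytest.raises(ValueError):
            cre.differential_fraction_percent(10, 5)
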