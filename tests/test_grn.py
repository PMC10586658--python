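import itertools

import numpy as np
import pandas as pd
import pytest

from regcircuit.grn import (
    build_binding_network,
    classify_edge_regulation,
    classify_tfs,
    cre_state_activity,
    differential_influence,
)
from regcircuit.linking import WeightFunction


def _toy_world():
    genes = pd.DataFrame({"gene": ["g1", "g2"], "chrom": ["chr1", "chr1"],
                          "tss": [10_000, 300_000]})
    cat = pd.DataFrame({"cre": ["c1", "c2", "c3"], "chrom": ["chr1"] * 3,
                        "summit": [10_000, 60_000, 290_000]})
    return genes, cat


class TestBuildBindingNetwork:
    def test_zero_motif_tf_all_zero(self):
        genes, cat = _toy_world()
        hits = pd.DataFrame({"t1": [1, 1, 0], "t2": [0, 0, 0]},
                            index=pd.Index(cat["cre"], name="cre"))
        act = pd.Series([1.0, 0.5, 0.2], index=hits.index)
        net = build_binding_network(hits, act, cat, genes, WeightFunction())
        assert (net["t2"] == 0).all()

    def test_max_edge_scaled_to_one(self):
        genes, cat = _toy_world()
        hits = pd.DataFrame({"t1": [1, 0, 1]}, index=pd.Index(cat["cre"], name="cre"))
        act = pd.Series([0.9, 0.1, 0.4], index=hits.index)
        net = build_binding_network(hits, act, cat, genes, WeightFunction())
        assert net.to_numpy().max() == pytest.approx(1.0)

    def test_hand_weighted_sum_before_scaling(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [10_000]})
        # both CREs inside the full-weight radius -> w = 1 for c1, 0.5 via half-weight for c2
        cat = pd.DataFrame({"cre": ["c1", "c2"], "chrom": ["chr1", "chr1"],
                            "summit": [10_000, 60_000]})
        hits = pd.DataFrame({"t1": [1, 1]}, index=pd.Index(cat["cre"], name="cre"))
        act = pd.Series([0.4, 0.2], index=hits.index)
        net = build_binding_network(hits, act, cat, genes, WeightFunction())
        # raw = 1*0.4 + 0.5*0.2 = 0.5, then scaled by itself (single edge) -> 1
        assert net.loc["g", "t1"] == pytest.approx(1.0)

    def test_unknown_cre_rows_rejected(self):
        genes, cat = _toy_world()
        hits = pd.DataFrame({"t1": [1]}, index=pd.Index(["nope"], name="cre"))
        with pytest.raises(ValueError, match="catalogue"):
            build_binding_network(hits, pd.Series([1.0], index=hits.index), cat, genes,
                                  WeightFunction())

    def test_activity_scaling(self):
        atac = pd.DataFrame({"A_1": [1.0, 3.0], "A_2": [1.0, 3.0], "B_1": [0.0, 0.0]},
                            index=pd.Index(["c1", "c2"], name="cre"))
        k27 = atac.copy()
        act = cre_state_activity(atac, k27, ["A_1", "A_2"])
        np.testing.assert_allclose(act.to_numpy(), [0.0, 1.0])


class TestDifferentialInfluence:
    def _nets(self):
        genes = [f"g{i}" for i in range(6)]
        src = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=["t1", "t2"])
        tgt = src.copy()
        # t1 gains edges to g0..g2; t2 gains a single weak edge to g5
        tgt.loc[["g0", "g1", "g2"], "t1"] = [1.0, 0.8, 0.6]
        tgt.loc["g5", "t2"] = 0.1
        return src, tgt

    def test_exclusive_tf_gets_influence_one(self):
        src, tgt = self._nets()
        de = pd.DataFrame({"log2fc": [2.0, 2.0, 2.0, 0.0, 0.0, 0.5],
                           "padj": [0.001] * 3 + [0.9, 0.9, 0.5]},
                          index=src.index)
        res = differential_influence(src, tgt, de)
        assert res.iloc[0]["tf"] == "t1"
        assert res.iloc[0]["influence"] == 1.0
        assert res.iloc[0]["n_targets"] == 3

    def test_no_differential_genes_all_zero(self, caplog):
        src, tgt = self._nets()
        de = pd.DataFrame({"log2fc": [1.0] * 6, "padj": [0.9] * 6}, index=src.index)
        with caplog.at_level("WARNING"):
            res = differential_influence(src, tgt, de)
        assert (res["influence"] == 0).all()

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        genes = pd.Index([f"g{i}" for i in range(30)], name="gene")
        src = pd.DataFrame(rng.random((30, 5)), index=genes, columns=list("abcde"))
        tgt = pd.DataFrame(rng.random((30, 5)), index=genes, columns=list("abcde"))
        de = pd.DataFrame({"log2fc": rng.normal(0, 2, 30), "padj": rng.random(30)},
                          index=genes)
        res = differential_influence(src, tgt, de)
        assert ((res["influence"] >= 0) & (res["influence"] <= 1)).all()

    def test_invariant_to_gene_relabeling(self):
        src, tgt = self._nets()
        de = pd.DataFrame({"log2fc": [2.0, 1.5, 1.0, 0.0, 0.0, 3.0],
                           "padj": [0.001] * 6}, index=src.index)
        res1 = differential_influence(src, tgt, de)
        mapping = {g: f"x_{g}" for g in src.index}
        res2 = differential_influence(src.rename(index=mapping), tgt.rename(index=mapping),
                                      de.rename(index=mapping))
        np.testing.assert_allclose(res1["influence"], res2["influence"])

    def test_max_edges_truncation(self):
        src, tgt = self._nets()
        de = pd.DataFrame({"log2fc": [2.0] * 6, "padj": [0.001] * 6}, index=src.index)
        res = differential_influence(src, tgt, de, max_edges=1)
        # only the single strongest edge (t1 -> g0) survives
        assert res.set_index("tf").loc["t2", "influence"] == 0.0

    def test_invalid_max_edges(self):
        src, tgt = self._nets()
        de = pd.DataFrame({"log2fc": [1.0] * 6, "padj": [0.5] * 6}, index=src.index)
        with pytest.raises(ValueError):
            differential_influence(src, tgt, de, max_edges=0)


class TestClassifyTfs:
    def _mk(self, pairs):
        return pd.DataFrame({"tf": list(pairs), "influence": list(pairs.values()),
                             "n_targets": 1})

    def test_shared_rule(self):
        res = classify_tfs(self._mk({"t": 0.8}), self._mk({"t": 0.7}))
        assert res.iloc[0]["class"] == "shared-epithelial"

    def test_a_specific_undetected_in_b(self):
        res = classify_tfs(self._mk({"t": 0.8}), self._mk({"t": 0.0}))
        assert res.iloc[0]["class"] == "A-specific"

    def test_neither(self):
        res = classify_tfs(self._mk({"t": 0.3}), self._mk({"t": 0.2}))
        assert res.iloc[0]["class"] == "neither"

    def test_low_but_detected_still_specific(self):
        res = classify_tfs(self._mk({"t": 0.9}), self._mk({"t": 0.2}))
        assert res.iloc[0]["class"] == "A-specific"

    def test_above_low_threshold_not_specific(self):
        res = classify_tfs(self._mk({"t": 0.9}), self._mk({"t": 0.3}))
        assert res.iloc[0]["class"] == "neither"

    def test_missing_tf_counts_as_zero(self):
        res = classify_tfs(self._mk({"t1": 0.8, "t2": 0.6}), self._mk({"t2": 0.9}))
        d = res.set_index("tf")["class"]
        assert d["t1"] == "A-specific"
        assert d["t2"] == "shared-epithelial"


def _edge_net(values, tf_genes, tfs):
    return pd.DataFrame(values, index=pd.Index(tf_genes, name="gene"), columns=tfs)


class TestClassifyEdgeRegulation:
    def _classify_one(self, b_ref, b_a, b_b):
        tfs = ["t1"]
        targets = ["t2"]
        net = lambda v: _edge_net([[v]], targets, tfs)
        res = classify_edge_regulation(net(b_ref), net(b_a), net(b_b), ["t1", "t2"])
        assert len(res) == 1
        return res.iloc[0]

    def test_shared_example(self):
        # dRA=0.6, dRB=0.5 -> mean 0.55 >= |direct=0.1| -> shared
        row = self._classify_one(0.2, 0.8, 0.7)
        assert row["label"] == "shared"

    def test_a_specific_example(self):
        # dRA=0.7, dRB=0.05 -> mean 0.375 < |0.65|, direct > 0 -> A-specific
        row = self._classify_one(0.05, 0.75, 0.10)
        assert row["label"] == "A-specific"
        assert row["delta_direct"] == pytest.approx(0.65)

    def test_b_specific_symmetric(self):
        row = self._classify_one(0.05, 0.10, 0.75)
        assert row["label"] == "B-specific"

    def test_absent_everywhere_skipped(self):
        row_count = len(classify_edge_regulation(
            _edge_net([[0.0]], ["t2"], ["t1"]),
            _edge_net([[0.0]], ["t2"], ["t1"]),
            _edge_net([[0.0]], ["t2"], ["t1"]),
            ["t1", "t2"],
        ))
        assert row_count == 0

    def test_exact_tie_defaults_to_shared(self):
        # dRA=0.3, dRB=0.1 -> mean_ref = 0.2 == |direct = 0.2|
        row = self._classify_one(0.0, 0.3, 0.1)
        assert row["delta_direct"] == pytest.approx(0.2)
        assert row["label"] == "shared"

    def test_exhaustive_grid_against_rule_oracle(self):
        grid = [0.0, 0.1, 0.25, 0.5, 0.75, 1.0]
        for b_ref, b_a, b_b in itertools.product(grid, repeat=3):
            if b_ref == b_a == b_b == 0.0:
                continue
            row = self._classify_one(b_ref, b_a, b_b)
            d_ra, d_rb = b_a - b_ref, b_b - b_ref
            direct = b_a - b_b
            mean_ref = (d_ra + d_rb) / 2
            if direct == 0 or mean_ref >= abs(direct):
                expected = "shared"
            elif direct > 0:
                expected = "A-specific"
            else:
                expected = "B-specific"
            assert row["label"] == expected, (b_ref, b_a, b_b)

    def test_state_swap_antisymmetry(self):
        grid = [0.0, 0.2, 0.5, 0.9]
        swap = {"A-specific": "B-specific", "B-specific": "A-specific", "shared": "shared"}
        for b_ref, b_a, b_b in itertools.product(grid, repeat=3):
            if b_ref == b_a == b_b == 0.0:
                continue
            fwd = self._classify_one(b_ref, b_a, b_b)
            rev = self._classify_one(b_ref, b_b, b_a)
            assert rev["label"] == swap[fwd["label"]]
            assert rev["delta_direct"] == pytest.approx(-fwd["delta_direct"])
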