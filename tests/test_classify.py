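"""OE-set selection, Venn algebra, class assignment, PCA reassignment
and ectopic/independent calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from luxuptake import FoldChangeTable
from luxuptake import classify as cl


def _fc_table(rows):
    """rows: (gene, contrast, fc)"""
    data = pd.DataFrame(rows, columns=["gene_id", "contrast", "fc"])
    data["log2fc"] = np.log2(data["fc"])
    data["padj"] = np.nan
    return FoldChangeTable(data)


def _oe_table(strong_fcs, weak_fcs, days=(2, 3, 6)):
    rows = []
    for gene in strong_fcs:
        for d, v in zip(days, strong_fcs[gene]):
            rows.append((gene, f"S_d{d}", v))
        for d, v in zip(days, weak_fcs[gene]):
            rows.append((gene, f"W_d{d}", v))
    return _fc_table(rows)


class TestSelectOeSet:
    def test_single_line_exceedance_included_up(self):
        fc = _oe_table({"g": [1.5, 2.1, 1.8]}, {"g": [1.0, 1.0, 1.0]})
        out = cl.select_oe_set(fc, "S", "W", [2, 3, 6])
        assert list(out.index) == ["g"]
        assert out.loc["g", "direction"] == "up"
        assert bool(out.loc["g", "A"]) and not bool(out.loc["g", "B"])

    def test_direction_follows_greatest_magnitude(self):
        fc = _oe_table({"g": [2.3, 1.0, 1.0]}, {"g": [1.0, 1.0, 0.1]})
        out = cl.select_oe_set(fc, "S", "W", [2, 3, 6])
        assert out.loc["g", "direction"] == "down"  # |log2 0.1| > |log2 2.3|

    def test_all_within_band_excluded(self):
        fc = _oe_table({"g": [0.5, 2.0, 1.0]}, {"g": [1.0, 0.6, 1.9]})
        out = cl.select_oe_set(fc, "S", "W", [2, 3, 6])
        assert out.empty

    def test_tie_breaks_toward_earlier_day_then_stronger_line(self):
        fc = _oe_table({"g": [1.0, 4.0, 1.0]}, {"g": [0.25, 1.0, 1.0]})
        out = cl.select_oe_set(fc, "S", "W", [2, 3, 6])
        # |log2| ties at 2.0: day 2 (weak, down) precedes day 3 (strong, up)
        assert out.loc["g", "direction"] == "down"
        fc2 = _oe_table({"g": [4.0, 1.0, 1.0]}, {"g": [0.25, 1.0, 1.0]})
        out2 = cl.select_oe_set(fc2, "S", "W", [2, 3, 6])
        assert out2.loc["g", "direction"] == "up"  # same day: strong line wins


def _ref(rows):
    return _fc_table(rows)


class TestVennAndClasses:
    def test_sector_strings_and_pooling(self):
        oe = pd.DataFrame(
            {"direction": ["up"], "A": [True], "B": [True]}, index=["g"]
        )
        ref = _ref([("g", "early", 4.0), ("g", "late", 1.0)])
        out = cl.venn_assign(oe, ref)
        assert out.loc["g", "sector"] == "ABC"
        assert out.loc["g", "pooled_sector"] == "ABC/D"

    def test_absent_from_reference_gets_no_cd(self):
        oe = pd.DataFrame({"direction": ["up"], "A": [True], "B": [False]}, index=["g"])
        ref = _ref([("other", "early", 4.0), ("other", "late", 4.0)])
        out = cl.venn_assign(oe, ref)
        assert not out.loc["g", "C"] and not out.loc["g", "D"]
        assert out.loc["g", "sector"] == "A"

    def test_all_sector_combinations_match_bruteforce(self):
        # 12 possible sectors: (A,B) in {10,01,11} x (C,D) in {00,10,01,11}
        combos = [
            (a, b, c, d)
            for a, b, c, d in itertools.product([True, False], repeat=4)
            if a or b
        ]
        genes = [f"g{i}" for i in range(len(combos))]
        oe = pd.DataFrame(
            {
                "direction": "up",
                "A": [c[0] for c in combos],
                "B": [c[1] for c in combos],
            },
            index=genes,
        )
        rows = []
        for g, (_, _, c, d) in zip(genes, combos):
            rows.append((g, "early", 4.0 if c else 1.0))
            rows.append((g, "late", 0.2 if d else 1.2))
        out = cl.venn_assign(oe, _ref(rows))
        for g, (a, b, c, d) in zip(genes, combos):
            expected = "".join(
                letter for letter, flag in zip("ABCD", (a, b, c, d)) if flag
            )
            assert out.loc[g, "sector"] == expected

    @pytest.mark.parametrize(
        "flags,label",
        [
            ((1, 1, 0, 1), "I"),
            ((1, 1, 1, 0), "I"),
            ((1, 0, 1, 1), "II"),
            ((1, 0, 0, 0), "II"),
            ((0, 1, 1, 0), "III"),
            ((0, 1, 0, 0), "III"),
            ((1, 1, 0, 0), "IV"),
        ],
    )
    def test_class_key(self, flags, label):
        venn = pd.DataFrame(
            [dict(zip("ABCD", map(bool, flags)))], index=["g"]
        )
        assert cl.assign_class(venn).loc["g"] == label

    def test_classes_partition_the_oe_set(self):
        combos = [
            dict(zip("ABCD", c))
            for c in itertools.product([True, False], repeat=4)
            if c[0] or c[1]
        ]
        venn = pd.DataFrame(combos)
        labels = cl.assign_class(venn)
        assert set(labels) <= {"I", "II", "III", "IV"}
        assert labels.notna().all()


class TestPcaReassign:
    def _fixture(self):
        # three well-separated class centroids; one gene mislabeled
        rng = np.random.default_rng(0)
        rows, labels = [], []
        for lab, center in (("I", (5, 0)), ("II", (-5, 0)), ("IV", (0, 5))):
            for i in range(5):
                rows.append(center + rng.normal(0, 0.1, 2))
                labels.append(lab)
        rows.append((5.0, 0.0))  # sits on class I centroid
        labels.append("IV")  # ... but labeled IV
        genes = [f"g{i}" for i in range(len(rows))]
        scores = pd.DataFrame(rows, index=genes, columns=["PC1", "PC2"])
        classification = pd.DataFrame({"class_label": labels}, index=genes)
        return classification, scores

    def test_planted_mislabel_is_reassigned(self):
        classification, scores = self._fixture()
        out = cl.pca_reassign(classification, scores, distance_margin=0.2)
        assert out.loc["g15", "class_label"] == "I"
        assert bool(out.loc["g15", "reassigned_by_pca"])

    def test_gene_at_own_centroid_never_moves(self):
        classification, scores = self._fixture()
        out = cl.pca_reassign(classification.drop("g15"), scores.drop("g15"))
        assert not out["reassigned_by_pca"].any()

    def test_degenerate_margin_disables_reassignment(self):
        classification, scores = self._fixture()
        out = cl.pca_reassign(classification, scores, distance_margin=1.0)
        assert not out["reassigned_by_pca"].any()

    def test_small_classes_contribute_no_centroid(self):
        classification, scores = self._fixture()
        small = classification.copy()
        small.loc[small["class_label"] == "I", "class_label"] = "III"
        small.loc[["g0", "g1"], "class_label"] = "I"  # only 2 members
        out = cl.pca_reassign(small, scores)
        assert not (out.loc[out["reassigned_by_pca"], "class_label"] == "I").any()


class TestEctopicIndependent:
    def _call(self, wt_early, mut_early, wt_late=1.0, mut_late=1.0):
        genes = pd.Index(["g"])
        wt = _ref([("g", "early", wt_early), ("g", "late", wt_late)])
        mut = _ref([("g", "early", mut_early), ("g", "late", mut_late)])
        return cl.call_ectopic_independent(genes, wt, mut).loc["g"]

    def test_mutant_only_significance_is_ectopic(self):
        out = self._call(1.1, 3.0)
        assert out["ectopic"] == "up" and out["independent"] == "none"

    def test_concordant_significance_is_independent(self):
        out = self._call(4.0, 3.5)
        assert out["independent"] == "up" and out["ectopic"] == "none"

    def test_opposite_direction_large_delta_is_ectopic(self):
        out = self._call(4.0, 0.3)
        assert out["ectopic"] == "down"

    def test_missing_mutant_reference_gives_no_calls(self):
        genes = pd.Index(["g"])
        wt = _ref([("g", "early", 4.0), ("g", "late", 1.0)])
        out = cl.call_ectopic_independent(genes, wt, None)
        assert (out["ectopic"] == "none").all()
        assert (out["independent"] == "none").all()

    def test_anchor_contrast_has_larger_mutant_change(self):
        genes = pd.Index(["g"])
        wt = _ref([("g", "early", 1.0), ("g", "late", 1.1)])
        mut = _ref([("g", "early", 2.5), ("g", "late", 8.0)])
        out = cl.call_ectopic_independent(genes, wt, mut)
        assert out.loc["g", "anchor"] == "late"
        assert out.loc["g", "ectopic"] == "up"


def test_end_to_end_class_recovery_on_small_bundle(small_bundle):
    from luxuptake import classify_genes, per_line_day_fold_changes

    fc = per_line_day_fold_changes(small_bundle.counts, control="UVM4")
    res = classify_genes(
        fc, "8-27", "8-42", [2, 3, 6],
        small_bundle.reference.wild_type, small_bundle.reference.mutant,
    )
    truth = small_bundle.truth.genes
    reg = truth[truth["class_label"] != "null"]
    joined = reg.join(res.table, how="left", rsuffix="_est")
    assert (joined["class_label_est"] == joined["class_label"]).mean() >= 0.95
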