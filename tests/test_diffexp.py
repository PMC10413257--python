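"""Fold-change stand-in, BH adjustment, importer and ranked sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from luxuptake import Contrast, CountMatrix, FoldChangeTable
from luxuptake import diffexp as de
from luxuptake.errors import InsufficientReplicatesError, ParseError


def _cm(values, sids, totals=None):
    counts = pd.DataFrame(values, columns=sids)
    counts.index = [f"g{i}" for i in range(len(counts))]
    t = None if totals is None else pd.Series(totals, index=sids, dtype=float)
    return CountMatrix(counts=counts, totals=t)


def bh_bruteforce(pvals):
    """Textbook Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestFoldChange:
    def _two_group(self, a, b):
        sids = [f"x_d2_r{r}" for r in (1, 2, 3)] + [f"y_d2_r{r}" for r in (1, 2, 3)]
        return _cm(np.column_stack([a, a, a, b, b, b]), sids,
                   totals=[1e6] * 6)

    def test_identical_groups_give_unit_fc(self):
        vals = np.array([10, 100, 1000])
        cm = self._two_group(vals, vals)
        out = de.fold_change(cm, Contrast("x", 2, "y", 2))
        assert np.allclose(out.data["fc"], 1.0)
        assert np.allclose(out.data["log2fc"], 0.0)

    def test_fourfold_means_small_pseudocount(self):
        cm = self._two_group(np.array([400, 4000]), np.array([100, 1000]))
        out = de.fold_change(cm, Contrast("x", 2, "y", 2), pseudocount=1e-9)
        assert np.allclose(out.data["fc"], 4.0)

    def test_reciprocal_contrasts_multiply_to_one(self):
        rng = np.random.default_rng(3)
        sids = [f"{ln}_d2_r{r}" for ln in ("x", "y") for r in (1, 2, 3)]
        cm = _cm(rng.integers(0, 500, (40, 6)), sids)
        ab = de.fold_change(cm, Contrast("x", 2, "y", 2))
        ba = de.fold_change(cm, Contrast("y", 2, "x", 2))
        assert np.allclose(ab.data["fc"].to_numpy() * ba.data["fc"].to_numpy(), 1.0,
                           atol=1e-9)

    def test_insufficient_replicates_rejected(self):
        sids = ["x_d2_r1", "y_d2_r1", "y_d2_r2"]
        cm = _cm([[1, 2, 3]], sids)
        with pytest.raises(InsufficientReplicatesError):
            de.fold_change(cm, Contrast("x", 2, "y", 2))


class TestBenjaminiHochberg:
    def test_matches_bruteforce_on_random_pvalues(self):
        rng = np.random.default_rng(7)
        sids = [f"{ln}_d2_r{r}" for ln in ("x", "y") for r in (1, 2, 3)]
        cm = _cm(rng.integers(1, 300, (50, 6)), sids)
        out = de.fold_change(cm, Contrast("x", 2, "y", 2))
        # recompute raw Welch p to feed the oracle
        from scipy import stats

        cpm = cm.cpm()
        lx = np.log2(cpm[[s for s in sids if s.startswith("x")]] + 0.5)
        ly = np.log2(cpm[[s for s in sids if s.startswith("y")]] + 0.5)
        raw = stats.ttest_ind(lx, ly, axis=1, equal_var=False).pvalue
        raw = np.where(np.isnan(raw), 1.0, raw)
        assert np.allclose(out.data["padj"], bh_bruteforce(raw), atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_bh_monotone_in_rank(self, pvals):
        adj = bh_bruteforce(pvals)
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestImporter:
    def test_fc_row_stored_as_log2(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tcontrast\tfc\tpadj\ng1\tearly\t2.5\t0.01\n")
        table = de.import_fold_changes(p)
        assert table.data["log2fc"].iloc[0] == pytest.approx(np.log2(2.5))
        assert table.provenance == "imported"

    def test_log2_only_row_derives_fc(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tcontrast\tlog2fc\ng1\tearly\t-1\n")
        table = de.import_fold_changes(p)
        assert table.data["fc"].iloc[0] == pytest.approx(0.5)
        assert table.data["padj"].isna().all()

    def test_nonpositive_fc_is_a_parse_error(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tcontrast\tfc\ng1\tearly\t2.0\ng2\tearly\t-3\n")
        with pytest.raises(ParseError) as err:
            de.import_fold_changes(p)
        assert err.value.line == 3

    def test_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "contrast": "early",
                "fc": np.exp(rng.normal(0, 1, 30)),
                "padj": rng.random(30),
            }
        )
        data["log2fc"] = np.log2(data["fc"])
        table = FoldChangeTable(data[["gene_id", "contrast", "fc", "log2fc", "padj"]])
        p = tmp_path / "t.tsv"
        table.to_tsv(p)
        back = FoldChangeTable.from_tsv(p)
        assert np.allclose(back.data["fc"], table.data["fc"], atol=1e-12)
        assert np.allclose(back.data["padj"], table.data["padj"], atol=1e-12)


class TestRankedSets:
    def _table(self, fcs, padjs):
        data = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(fcs))],
                "contrast": "c",
                "fc": fcs,
                "padj": padjs,
            }
        )
        data["log2fc"] = np.log2(data["fc"])
        return FoldChangeTable(data)

    def test_strict_cutoffs(self):
        table = self._table([2.0, 3.0, 2.5], [0.01, 0.2, 0.01])
        out = de.ranked_sets(table, "c")
        assert out.up == {"g2"}  # FC exactly 2 excluded; padj 0.2 excluded
        assert out.down == set()

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(9)
        fcs = np.exp(rng.normal(0, 1.5, 80))
        padjs = rng.random(80)
        table = self._table(fcs, padjs)
        out = de.ranked_sets(table, "c", top_n=10)
        up = {f"g{i}" for i in range(80) if fcs[i] > 2 and padjs[i] < 0.05}
        down = {f"g{i}" for i in range(80) if fcs[i] < 0.5 and padjs[i] < 0.05}
        assert out.up == up and out.down == down
        ranked = sorted(up, key=lambda g: (-abs(np.log2(fcs[int(g[1:])])), g))
        assert out.top_up == ranked[:10]


def test_planted_truth_passes_the_significance_filter(bundle):
    """Regulated genes pass >2-fold & padj<0.05 in an affected contrast;
    null genes rarely do anywhere."""
    fc = de.per_line_day_fold_changes(bundle.counts, control="UVM4")
    truth = bundle.truth
    l2 = fc.matrix("log2fc")
    padj = fc.matrix("padj")
    hits = (l2.abs() > 1.0) & (padj < 0.05)
    reg_ok = []
    for g, rec in truth.genes[truth.genes["class_label"] != "null"].iterrows():
        affected = [
            f"{ln}_d{d}"
            for ln, d in truth.log2fc.columns
            if truth.log2fc.at[g, (ln, d)] != 0
        ]
        reg_ok.append(hits.loc[g, affected].any())
    assert np.mean(reg_ok) >= 0.90
    null_genes = truth.genes.index[truth.genes["class_label"] == "null"]
    assert hits.loc[null_genes].any(axis=1).mean() <= 0.10
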