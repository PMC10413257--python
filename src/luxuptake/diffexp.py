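"""Per-gene fold changes with adjusted p-values, and ranked significant sets.

The differential-expression engine is a deliberately simple, documented
stand-in: fold change is the ratio of group-mean CPM (plus a pseudocount),
the p-value a two-sided Welch t-test on log2(CPM + pseudocount), adjusted
by Benjamini-Hochberg within each contrast. Externally computed tables
(e.g. shrunken-estimator output) can be imported instead and flow through
the same downstream classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, FoldChangeTable
from .errors import InsufficientReplicatesError, ParseError

DEFAULT_PSEUDOCOUNT = 0.5  # CPM units; bounds FC on zero counts


@dataclass(frozen=True)
class Contrast:
    """Numerator vs denominator condition, each a (line, day) pair."""

    num_line: str
    num_day: int
    den_line: str
    den_day: int
    label: str = ""

    def __post_init__(self):
        if (self.num_line, self.num_day) == (self.den_line, self.den_day):
            raise ValueError("contrast conditions must differ")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.num_line}_d{self.num_day}_vs_{self.den_line}_d{self.den_day}",
            )


def fold_change(
    counts: CountMatrix,
    contrast: Contrast,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTable:
    """One contrast's fold changes and BH-adjusted Welch-t p-values."""
    num_ids = counts.sample_ids(contrast.num_line, contrast.num_day)
    den_ids = counts.sample_ids(contrast.den_line, contrast.den_day)
    if len(num_ids) < 2 or len(den_ids) < 2:
        raise InsufficientReplicatesError(
            f"{contrast.label}: need >=2 replicates per side "
            f"(got {len(num_ids)} vs {len(den_ids)})"
        )
    cpm = counts.cpm()
    num, den = cpm[num_ids], cpm[den_ids]
    fc = (num.mean(axis=1) + pseudocount) / (den.mean(axis=1) + pseudocount)
    log_num = np.log2(num + pseudocount)
    log_den = np.log2(den + pseudocount)
    t = stats.ttest_ind(log_num, log_den, axis=1, equal_var=False)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    padj = multipletests(p, method="fdr_bh")[1]
    data = pd.DataFrame(
        {
            "gene_id": counts.genes,
            "contrast": contrast.label,
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "padj": padj,
        }
    )
    return FoldChangeTable(data, provenance="internal")


def per_line_day_fold_changes(
    counts: CountMatrix,
    control: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTable:
    """Transgenic-vs-control fold changes per line per day.

    Contrast labels follow ``<line>_d<day>`` so downstream set selection
    can group them by line.
    """
    lines = counts.lines
    if control is None:
        control = lines[0]
    tables = []
    for line in lines:
        if line == control:
            continue
        for day in counts.days:
            c = Contrast(line, day, control, day, label=f"{line}_d{day}")
            tables.append(fold_change(counts, c, pseudocount))
    return FoldChangeTable.concat(tables)


def import_fold_changes(path) -> FoldChangeTable:
    """Read an externally computed fold-change TSV.

    Accepts ``fc`` and/or ``log2fc`` columns (one is derived from the
    other); a missing ``padj`` column is tolerated, mirroring reference
    datasets published without adjusted p-values.
    """
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    if "gene_id" not in cols or "contrast" not in cols:
        raise ParseError(f"{path}: need gene_id and contrast columns")
    out = pd.DataFrame(
        {"gene_id": frame[cols["gene_id"]], "contrast": frame[cols["contrast"]]}
    )
    if "fc" in cols:
        fc = frame[cols["fc"]].astype(float)
        bad = fc.index[~(fc > 0)]
        if len(bad):
            raise ParseError(f"{path}: non-positive FC", line=int(bad[0]) + 2)
        out["fc"] = fc
        out["log2fc"] = np.log2(fc)
    elif "log2fc" in cols:
        out["log2fc"] = frame[cols["log2fc"]].astype(float)
        out["fc"] = 2.0 ** out["log2fc"]
    else:
        raise ParseError(f"{path}: need an fc or log2fc column")
    out["padj"] = frame[cols["padj"]].astype(float) if "padj" in cols else np.nan
    return FoldChangeTable(out, provenance="imported")


@dataclass
class RankedSets:
    """Significantly regulated genes for one contrast, plus top-N lists."""

    up: set
    down: set
    top_up: list
    top_down: list


def ranked_sets(
    fc: FoldChangeTable,
    contrast: str,
    fc_cutoff: float = 2.0,
    padj_cutoff: float = 0.05,
    top_n: int = 200,
) -> RankedSets:
    """Strict >cutoff / <1/cutoff filters with p-adj gating, ranked by |log2FC|.

    When the table carries no adjusted p-values (imported reference data)
    the FC cutoff alone applies.
    """
    sub = fc.for_contrast(contrast)
    if sub.empty:
        raise KeyError(f"contrast {contrast!r} not in table")
    padj_ok = sub["padj"].isna() | (sub["padj"] < padj_cutoff)
    up = sub[(sub["fc"] > fc_cutoff) & padj_ok]
    down = sub[(sub["fc"] < 1.0 / fc_cutoff) & padj_ok]

    def top(frame):
        ordered = frame.assign(absl=frame["log2fc"].abs(), gid=frame.index)
        ordered = ordered.sort_values(["absl", "gid"], ascending=[False, True])
        return list(ordered.index[:top_n])

    return RankedSets(
        up=set(up.index), down=set(down.index), top_up=top(up), top_down=top(down)
    )
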