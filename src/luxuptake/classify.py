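"""Gene-set algebra for overexpression time courses.

Selects the overexpression-responsive set (>2-fold at any timepoint in
any transgenic line), assigns each gene a direction by its
greatest-magnitude change, intersects the set with a reference
starvation dataset (Venn letters A = strong line, B = weak line,
C = reference early, D = reference late), pools sectors into Classes
I-IV, optionally reassigns borderline genes by nearest PCA centroid, and
calls ectopic / regulator-independent behaviour from the mutant-background
reference.

Class key: I = both lines and the reference (ABC/D); II = strong line
only (A or AC/D); III = weak line only (B or BC/D); IV = both lines but
absent from the reference (AB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FoldChangeTable
from .errors import LuxuptakeError

log = logging.getLogger(__name__)


def select_oe_set(
    fc: FoldChangeTable,
    strong_line: str,
    weak_line: str,
    days: list[int],
    fc_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Overexpression-responsive genes with per-line flags and direction.

    A gene is included iff max over (line, day) of max(FC, 1/FC) exceeds
    ``fc_cutoff`` (strict). Direction is the sign of log2FC at the cell
    with the greatest |log2FC|; exact ties resolve toward the earlier
    day, then the stronger line. Per-line flags A (strong) and B (weak)
    record which line carried a >cutoff change. Missing cells are treated
    as FC = 1 with a logged warning.

    Contrast labels in ``fc`` must follow ``<line>_d<day>``.
    """
    cells = [
        (line, day, f"{line}_d{day}")
        for day in sorted(days)
        for line in (strong_line, weak_line)
    ]
    mat = fc.matrix("log2fc")
    missing = [lab for _, _, lab in cells if lab not in mat.columns]
    if missing:
        log.warning("missing FC contrasts treated as FC=1: %s", missing)
        for lab in missing:
            mat[lab] = 0.0
    mat = mat[[lab for _, _, lab in cells]]
    filled = mat.fillna(0.0)
    if mat.isna().any().any():
        log.warning("missing FC cells treated as FC=1")
    arr = filled.to_numpy()
    absarr = np.abs(arr)
    log2_cut = np.log2(fc_cutoff)
    included = absarr.max(axis=1) > log2_cut
    # cells are ordered (day asc, strong before weak); argmax takes the
    # first maximum, which realises the documented tie-break
    arg = np.argmax(absarr, axis=1)
    direction = np.where(arr[np.arange(len(arr)), arg] >= 0, "up", "down")
    strong_cols = [i for i, (ln, _, _) in enumerate(cells) if ln == strong_line]
    weak_cols = [i for i, (ln, _, _) in enumerate(cells) if ln == weak_line]
    a_flag = absarr[:, strong_cols].max(axis=1) > log2_cut
    b_flag = absarr[:, weak_cols].max(axis=1) > log2_cut
    out = pd.DataFrame(
        {"direction": direction, "A": a_flag, "B": b_flag}, index=filled.index
    )
    return out[included]


def venn_assign(
    oe: pd.DataFrame,
    reference_wt: FoldChangeTable,
    fc_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Add reference-membership flags C ('early') and D ('late') and sectors.

    C/D are set where the wild-type reference |FC| exceeds the cutoff in
    the respective contrast; genes absent from the reference get
    C = D = False (the published tables mark such cells N/A).
    """
    log2_cut = np.log2(fc_cutoff)
    out = oe.copy()
    for flag, contrast in (("C", "early"), ("D", "late")):
        ref = reference_wt.for_contrast(contrast)["log2fc"]
        vals = ref.reindex(out.index)
        out[flag] = (vals.abs() > log2_cut).fillna(False).to_numpy()
    absent = ~oe.index.isin(reference_wt.data["gene_id"])
    if absent.any():
        log.info("%d gene(s) absent from the reference dataset", int(absent.sum()))
    out["sector"] = [
        "".join(l for l in "ABCD" if row[l]) for _, row in out.iterrows()
    ]
    out["pooled_sector"] = [
        "".join(l for l in "AB" if row[l]) + ("C/D" if (row["C"] or row["D"]) else "")
        for _, row in out.iterrows()
    ]
    return out


def assign_class(venn: pd.DataFrame) -> pd.Series:
    """Class I-IV per gene; the four cases partition A or B membership."""
    a, b = venn["A"].to_numpy(), venn["B"].to_numpy()
    cd = venn["C"].to_numpy() | venn["D"].to_numpy()
    label = np.select(
        [a & b & cd, a & b & ~cd, a & ~b, ~a & b],
        ["I", "IV", "II", "III"],
        default="",
    )
    if (label == "").any():
        raise LuxuptakeError("gene in OE set without A or B membership")
    return pd.Series(label, index=venn.index, name="class_label")


def pca_reassign(
    classification: pd.DataFrame,
    scores: pd.DataFrame,
    distance_margin: float = 0.2,
    min_members: int = 3,
) -> pd.DataFrame:
    """Relabel genes clearly closer to another class's PCA centroid.

    A gene moves to class ``k`` iff its distance (first two score
    columns) to ``k``'s centroid is below ``(1 - distance_margin)`` times
    the distance to its own class centroid. Classes with fewer than
    ``min_members`` genes contribute no centroid and receive no genes.
    """
    out = classification.copy()
    out["reassigned_by_pca"] = False
    pcs = scores.iloc[:, :2].reindex(out.index)
    centroids = {}
    for lab, sub in out.groupby("class_label"):
        members = pcs.loc[sub.index].dropna()
        if len(members) >= min_members:
            centroids[lab] = members.mean(axis=0).to_numpy()
    for gene in out.index:
        own = out.at[gene, "class_label"]
        if own not in centroids or pcs.loc[gene].isna().any():
            continue
        point = pcs.loc[gene].to_numpy()
        d_own = float(np.linalg.norm(point - centroids[own]))
        best, d_best = None, np.inf
        for lab, cen in centroids.items():
            if lab == own:
                continue
            d = float(np.linalg.norm(point - cen))
            if d < d_best:
                best, d_best = lab, d
        if best is not None and d_best < (1.0 - distance_margin) * d_own:
            out.at[gene, "class_label"] = best
            out.at[gene, "reassigned_by_pca"] = True
    return out


def call_ectopic_independent(
    oe_genes: pd.Index,
    reference_wt: FoldChangeTable,
    reference_mut: FoldChangeTable | None,
    fc_cutoff: float = 2.0,
    delta_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Ectopic / regulator-independent calls from the mutant background.

    Per gene the call is anchored at the contrast with the larger mutant
    |log2FC|. Ectopic: mutant |FC| > cutoff and the wild type is either
    not significant there or altered from the mutant by more than
    ``delta_cutoff``-fold (ΔFC taken as the fold ratio
    max(FCwt, FCmut)/min(FCwt, FCmut)). Independent: ΔFC < cutoff, same
    direction, and significant in both backgrounds. A gene meeting both
    definitions is resolved as independent (the stricter, concordant
    condition); call direction follows the mutant.
    """
    none = pd.DataFrame(
        {"ectopic": "none", "independent": "none", "anchor": ""}, index=oe_genes
    )
    if reference_mut is None:
        log.warning("mutant reference missing; ectopic/independent calls skipped")
        return none
    log2_cut = np.log2(fc_cutoff)
    log2_delta = np.log2(delta_cutoff)
    wt = {c: reference_wt.for_contrast(c)["log2fc"] for c in ("early", "late")}
    mut = {c: reference_mut.for_contrast(c)["log2fc"] for c in ("early", "late")}
    rows = []
    for gene in oe_genes:
        cand = [
            c
            for c in ("early", "late")
            if gene in mut[c].index and gene in wt[c].index
        ]
        if not cand:
            rows.append(("none", "none", ""))
            continue
        anchor = max(cand, key=lambda c: abs(mut[c][gene]))
        w, m = wt[anchor][gene], mut[anchor][gene]
        mut_sig = abs(m) > log2_cut
        wt_sig = abs(w) > log2_cut
        delta = abs(w - m)  # log2 of the fold ratio between backgrounds
        mdir = "up" if m > 0 else "down"
        independent = (
            delta < log2_delta and np.sign(w) == np.sign(m) and wt_sig and mut_sig
        )
        ectopic = mut_sig and (not wt_sig or delta > log2_delta)
        if independent:
            rows.append(("none", mdir, anchor))
        elif ectopic:
            rows.append((mdir, "none", anchor))
        else:
            rows.append(("none", "none", anchor))
    return pd.DataFrame(rows, columns=["ectopic", "independent", "anchor"], index=oe_genes)


@dataclass
class ClassificationResult:
    """Full per-gene classification table (one row per OE-set gene)."""

    table: pd.DataFrame

    def counts_by_class(self) -> pd.Series:
        return self.table["class_label"].value_counts().sort_index()

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ClassificationResult":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def classify_genes(
    fc: FoldChangeTable,
    strong_line: str,
    weak_line: str,
    days: list[int],
    reference_wt: FoldChangeTable,
    reference_mut: FoldChangeTable | None = None,
    fc_cutoff: float = 2.0,
    delta_cutoff: float = 2.0,
    pca_scores: pd.DataFrame | None = None,
    distance_margin: float = 0.2,
) -> ClassificationResult:
    """Run the complete classification chain on one fold-change table."""
    oe = select_oe_set(fc, strong_line, weak_line, days, fc_cutoff)
    venn = venn_assign(oe, reference_wt, fc_cutoff)
    venn["class_label"] = assign_class(venn)
    if pca_scores is not None:
        venn = pca_reassign(venn, pca_scores, distance_margin)
    else:
        venn["reassigned_by_pca"] = False
    calls = call_ectopic_independent(
        venn.index, reference_wt, reference_mut, fc_cutoff, delta_cutoff
    )
    venn[["ectopic", "independent"]] = calls[["ectopic", "independent"]]
    return ClassificationResult(venn)
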