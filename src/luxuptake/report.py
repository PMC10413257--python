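"""End-to-end pipeline: quantify, contrast, classify, correlate, summarize.

``run_report`` chains every stage on file inputs and writes all result
tables, a machine-readable summary (gene counts per class and sector,
up/down fractions, the nutrient-removal table) and a run log echoing
seed, versions and every cutoff, so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, FoldChangeTable, PhysiologySeries
from .errors import LuxuptakeError, StageError
from . import classify as _classify
from . import diffexp as _diffexp
from . import expression as _expression
from . import ordination as _ordination
from . import physiology as _physiology
from .io import read_fasta

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    totals: str | None = None
    lengths: str = ""
    reference_wt: str = ""
    reference_mut: str | None = None
    physiology: str | None = None
    reads: str | None = None
    fragments: str | None = None
    control_line: str | None = None
    strong_line: str | None = None
    weak_line: str | None = None
    fc_cutoff: float = 2.0
    padj_cutoff: float = 0.05
    top_n: int = 200
    alpha: float = 0.05
    delta_cutoff: float = 2.0
    apply_pca_reassign: bool = False
    pca_margin: float = 0.2
    pseudocount: float = 0.5
    window: tuple[int, int] = (1, 4)
    uptake_mode: str = "times_mu"
    seed: int = 0
    outdir: str = "report"

    def validate(self) -> None:
        for name in ("fc_cutoff", "padj_cutoff", "top_n", "alpha", "delta_cutoff"):
            if getattr(self, name) <= 0:
                raise LuxuptakeError(f"cutoff {name} must be positive")
        for name in ("counts", "lengths", "reference_wt"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise LuxuptakeError(f"required input {name!r} missing: {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise LuxuptakeError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - stage naming is the contract
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_report(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict written to summary.json."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("luxuptake")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_report(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_report(config: PipelineConfig, out: Path) -> dict:
    log.info("luxuptake %s seed=%d cutoffs: %s", __version__, config.seed,
             {k: v for k, v in dataclasses.asdict(config).items()
              if k.endswith(("cutoff", "_n", "alpha", "margin", "pseudocount", "mode"))})

    counts = _stage("load-counts")(CountMatrix.from_tsv)(config.counts, config.totals)
    lengths = _stage("load-lengths")(_load_lengths)(config.lengths)
    lines = counts.lines
    control = config.control_line or lines[0]
    oe_lines = [ln for ln in lines if ln != control]
    strong = config.strong_line or oe_lines[0]
    weak = config.weak_line or oe_lines[-1]
    days = counts.days

    expr = _stage("rpkm")(_expression.rpkm)(counts, lengths)
    expr.to_tsv(out / "rpkm.tsv")
    means = _stage("replicate-means")(_expression.mean_over_replicates)(expr)
    means.to_tsv(out / "rpkm_means.tsv")
    norm = _stage("normalize")(_expression.normalize_profile_to_max)(means)
    norm.to_tsv(out / "rpkm_normalized.tsv")

    fc = _stage("diffexp")(_diffexp.per_line_day_fold_changes)(
        counts, control=control, pseudocount=config.pseudocount
    )
    fc.to_tsv(out / "fold_changes.tsv")

    ref_wt = _stage("load-reference")(FoldChangeTable.from_tsv)(
        config.reference_wt, "imported"
    )
    ref_mut = None
    if config.reference_mut and Path(config.reference_mut).exists():
        ref_mut = FoldChangeTable.from_tsv(config.reference_mut, "imported")
    elif config.reference_mut:
        log.warning("mutant reference %s not found; degraded mode", config.reference_mut)

    profiles6 = _stage("profiles")(_ordination.log2fc_profiles)(
        fc, [strong, weak], days
    )
    oe_preview = _stage("classify")(_classify.select_oe_set)(
        fc, strong, weak, days, config.fc_cutoff
    )
    pca_fc = _stage("pca-log2fc")(_ordination.pca)(
        profiles6.loc[oe_preview.index], n_components=2
    )
    classification = _stage("classify")(_classify.classify_genes)(
        fc, strong, weak, days, ref_wt, ref_mut,
        fc_cutoff=config.fc_cutoff, delta_cutoff=config.delta_cutoff,
        pca_scores=pca_fc.scores if config.apply_pca_reassign else None,
        distance_margin=config.pca_margin,
    )
    classification.to_tsv(out / "classification.tsv")
    pca_fc.scores.rename_axis("gene_id").to_csv(out / "pca_log2fc_scores.tsv", sep="\t")
    pca_fc.loadings.rename_axis("axis_point").to_csv(out / "pca_log2fc_loadings.tsv", sep="\t")

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_genes": int(len(counts.genes)),
        "oe_set_size": int(len(classification.table)),
        "class_counts": {
            k: int(v) for k, v in classification.counts_by_class().items()
        },
        "sector_counts": {
            k: int(v)
            for k, v in classification.table["pooled_sector"].value_counts().items()
        },
        "up_fraction": float(
            (classification.table["direction"] == "up").mean()
        ) if len(classification.table) else float("nan"),
        "ectopic_counts": {
            k: int(v) for k, v in classification.table["ectopic"].value_counts().items()
        },
        "independent_counts": {
            k: int(v)
            for k, v in classification.table["independent"].value_counts().items()
        },
        "pca_log2fc_variance_explained": [
            float(v) for v in pca_fc.explained_variance_ratio
        ],
    }

    if config.physiology and Path(config.physiology).exists():
        phys = PhysiologySeries.from_tsv(config.physiology)
        rates = _stage("physiology")(_physiology.summarize)(
            phys, window=config.window, mode=config.uptake_mode
        )
        rates.to_csv(out / "rate_summary.tsv", sep="\t")
        summary["rmax_table"] = {
            line: {
                "rmax_p_mM_per_day": float(row["rmax_p"]),
                "rmax_mg_mM_per_day": float(row["rmax_mg"]),
                "p_mg_molar_ratio": float(row["p_mg_molar_ratio"]),
                "mu": float(row["mu"]),
                "doubling_time_d": float(row["doubling_time"]),
            }
            for line, row in rates.iterrows()
        }

        covs = _stage("correlate")(_ordination.physiology_covariates)(
            phys, lines, days
        )
        profiles9 = _stage("correlate")(_ordination.expression_profiles)(
            norm, lines, days
        )
        corr = _stage("correlate")(_ordination.pearson_vs_covariates)(
            profiles9.loc[profiles9.index.intersection(classification.table.index)],
            covs,
            alpha=config.alpha,
        )
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        pca9 = _stage("pca-rpkm")(_ordination.pca)(
            profiles9.loc[profiles9.index.intersection(classification.table.index)],
            n_components=2,
        )
        pca9.scores.rename_axis("gene_id").to_csv(out / "pca_rpkm_scores.tsv", sep="\t")
        pca9.loadings.rename_axis("axis_point").to_csv(
            out / "pca_rpkm_loadings.tsv", sep="\t"
        )
        summary["pca_rpkm_variance_explained"] = [
            float(v) for v in pca9.explained_variance_ratio
        ]

    if config.reads and config.fragments:
        reads = read_fasta(config.reads)
        frags = read_fasta(config.fragments)
        hits = _stage("fragments")(_expression.count_fragment_matches)(reads, frags)
        frag_lengths = {n: len(s) for n, s in frags}
        frpkm = _expression.fragment_rpkm(hits.counts, frag_lengths, len(reads))
        frame = pd.DataFrame(
            {"count": pd.Series(hits.counts), "rpkm": frpkm}
        ).rename_axis("fragment")
        frame.to_csv(out / "fragment_counts.tsv", sep="\t")
        summary["fragment_counts"] = {k: int(v) for k, v in hits.counts.items()}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("report complete: %s", out)
    return summary


def _load_lengths(path):
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return _expression.lengths_from_gff3(p)
    return _expression.lengths_from_tsv(p)
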