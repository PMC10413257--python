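"""FASTA helpers and on-disk layout for synthetic bundles."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import FoldChangeTable
from .synthetic import SyntheticBundle


def write_fasta(pairs: list[tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in pairs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every pipeline input plus the ground truth to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "totals": out / "totals.tsv",
        "lengths": out / "gene_lengths.tsv",
        "ref_wt": out / "reference_wt_fc.tsv",
        "ref_mut": out / "reference_mut_fc.tsv",
        "physiology": out / "physiology.tsv",
        "reads": out / "reads.fasta",
        "fragments": out / "fragments.fasta",
        "truth_genes": out / "truth_genes.tsv",
        "truth_log2fc": out / "truth_log2fc.tsv",
    }
    bundle.counts.to_tsv(paths["counts"], totals_path=paths["totals"])
    # synthetic genes get a fixed nominal length so RPKM stays well defined
    with open(paths["lengths"], "w") as fh:
        fh.write("gene_id\tlength\n")
        for g in bundle.counts.genes:
            fh.write(f"{g}\t1000\n")
    bundle.reference.wild_type.to_tsv(paths["ref_wt"])
    bundle.reference.mutant.to_tsv(paths["ref_mut"])
    bundle.physiology.to_tsv(paths["physiology"])
    write_fasta(bundle.reads, paths["reads"])
    write_fasta(bundle.fragments, paths["fragments"])
    bundle.truth.genes.rename_axis("gene_id").to_csv(paths["truth_genes"], sep="\t")
    flat = bundle.truth.log2fc.copy()
    flat.columns = [f"{ln}_d{d}" for ln, d in flat.columns]
    flat.rename_axis("gene_id").to_csv(paths["truth_log2fc"], sep="\t")
    return paths


def read_reference(path, provenance="imported") -> FoldChangeTable:
    return FoldChangeTable.from_tsv(path, provenance=provenance)
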