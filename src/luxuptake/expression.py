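"""Expression quantification: RPKM, replicate means, profile normalization
and exact-match fragment counting.

RPKM = count / (gene length in kb) / (total assigned reads in millions).
Totals come from the count-matrix metadata (all assigned reads), not the
column sums of whatever gene subset happens to be loaded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, sample_id
from .errors import (
    InvalidFragmentError,
    InvalidSampleError,
    MissingCellError,
    MissingLengthError,
)
from .synthetic import _revcomp, validate_fragments

log = logging.getLogger(__name__)


def rpkm(counts: CountMatrix, lengths: pd.Series | dict) -> ExpressionMatrix:
    """Reads per kilobase of gene length per million total reads."""
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.genes.difference(lengths.index)
    if len(missing):
        raise MissingLengthError(missing)
    lengths = lengths.reindex(counts.genes)
    if (lengths <= 0).any():
        raise MissingLengthError(lengths.index[lengths <= 0])
    totals = counts.totals
    if (totals <= 0).any():
        raise InvalidSampleError(
            f"non-positive totals: {list(totals.index[totals <= 0])}"
        )
    values = counts.counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(values=values, samples=counts.samples.copy())


def mean_over_replicates(x: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean per line x day; one output column per condition."""
    meta = x.samples
    cols, names = [], []
    for (line, day), sub in meta.groupby(["line", "day"], sort=False):
        sids = list(sub.index)
        if not sids:
            raise MissingCellError(f"no replicates for {line} d{day}")
        cols.append(x.values[sids].mean(axis=1))
        names.append(sample_id(line, day, 0))
    out = pd.concat(cols, axis=1)
    out.columns = names
    # preserve line order of the input, days ascending within line
    order = sorted(
        range(len(names)),
        key=lambda i: (list(dict.fromkeys(meta["line"])).index(names[i].rsplit("_", 2)[0]),
                       int(names[i].rsplit("_", 2)[1][1:])),
    )
    out = out.iloc[:, order]
    return ExpressionMatrix(values=out)


def normalize_profile_to_max(x: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's profile by its maximum; all-zero genes dropped."""
    maxima = x.values.max(axis=1)
    zero = maxima <= 0
    if zero.any():
        log.warning("dropping %d gene(s) with all-zero profiles", int(zero.sum()))
    kept = x.values.loc[~zero]
    return ExpressionMatrix(
        values=kept.div(maxima[~zero], axis=0), samples=x.samples
    )


@dataclass
class FragmentCounts:
    counts: dict[str, int]
    ambiguous: list[tuple[str, list[str]]]  # (read name, fragments hit)


def count_fragment_matches(
    reads: list[tuple[str, str]], fragments: list[tuple[str, str]]
) -> FragmentCounts:
    """Exact bidirectional substring matching of reads against fragments.

    A read increments fragment ``f`` iff the read is a substring of ``f``
    or ``f`` is a substring of the read, on either strand; a read hitting
    several fragments is counted for all and flagged.
    """
    validate_fragments(fragments)
    counts = {name: 0 for name, _ in fragments}
    ambiguous = []
    for rname, rseq in reads:
        rrc = _revcomp(rseq)
        hits = [
            name
            for name, fseq in fragments
            if rseq in fseq or rrc in fseq or fseq in rseq or fseq in rrc
        ]
        for h in hits:
            counts[h] += 1
        if len(hits) > 1:
            ambiguous.append((rname, hits))
    if ambiguous:
        log.warning("%d read(s) matched multiple fragments", len(ambiguous))
    return FragmentCounts(counts=counts, ambiguous=ambiguous)


def fragment_rpkm(
    fragment_counts: dict[str, int],
    fragment_lengths: dict[str, int],
    total_reads: float,
) -> pd.Series:
    """RPKM with the fragment's own length in place of the gene length."""
    if total_reads <= 0:
        raise InvalidSampleError("total reads must be positive")
    missing = [f for f in fragment_counts if f not in fragment_lengths]
    if missing:
        raise MissingLengthError(missing)
    if any(fragment_lengths[f] <= 0 for f in fragment_counts):
        raise MissingLengthError([f for f in fragment_counts if fragment_lengths[f] <= 0])
    return pd.Series(
        {
            f: c / (fragment_lengths[f] / 1e3) / (total_reads / 1e6)
            for f, c in fragment_counts.items()
        }
    )


def lengths_from_tsv(path) -> pd.Series:
    """Two-column TSV: gene_id, length (bp)."""
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(frame.columns[0])[frame.columns[1]].astype(float)


def lengths_from_gff3(path) -> pd.Series:
    """Gene length as the merged-exon (union) span per gene from a GFF3.

    Overlapping exons from alternative isoforms are merged so a gene's
    length is the number of distinct exonic bases, not a per-transcript
    sum. GFF3 coordinates are 1-based inclusive.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    lengths = {}
    for gene in db.features_of_type("gene"):
        intervals = sorted(
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon")
        )
        if not intervals:
            lengths[gene.id] = gene.end - gene.start + 1
            continue
        total, cur_s, cur_e = 0, *intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        lengths[gene.id] = total
    return pd.Series(lengths, dtype=float)
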