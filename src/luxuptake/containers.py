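"""Core tabular containers shared across the pipeline.

All containers wrap pandas objects and read/write plain TSV
(tab-separated, header row, UTF-8, '.' decimal).  Sample identifiers
follow the ``<line>_<day>_r<replicate>`` convention, e.g. ``8-27_d3_r2``;
line labels therefore must not contain underscores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSampleError, ParseError


def sample_id(line: str, day: int, replicate: int) -> str:
    if "_" in line:
        raise ValueError(f"line label may not contain '_': {line!r}")
    return f"{line}_d{day}_r{replicate}"


def parse_sample_id(sid: str) -> tuple[str, int, int]:
    try:
        line, day, rep = sid.rsplit("_", 2)
        if not (day.startswith("d") and rep.startswith("r")):
            raise ValueError
        return line, int(day[1:]), int(rep[1:])
    except ValueError:
        raise ParseError(f"malformed sample id {sid!r}; expected <line>_d<day>_r<rep>")


def _samples_frame(sample_ids) -> pd.DataFrame:
    rows = [parse_sample_id(s) for s in sample_ids]
    return pd.DataFrame(rows, columns=["line", "day", "replicate"], index=list(sample_ids))


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``totals`` holds the total assigned reads per sample; it may exceed the
    column sum because unannotated reads count toward the library size.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = None
    totals: pd.Series = None

    def __post_init__(self):
        if self.samples is None:
            self.samples = _samples_frame(self.counts.columns)
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample descriptors")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def sample_ids(self, line=None, day=None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if line is not None:
            mask &= self.samples["line"] == line
        if day is not None:
            mask &= self.samples["day"] == day
        return list(self.samples.index[mask])

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))

    @property
    def days(self) -> list[int]:
        return sorted(self.samples["day"].unique())

    def cpm(self) -> pd.DataFrame:
        """Counts per million of total assigned reads."""
        if (self.totals <= 0).any():
            bad = self.totals.index[self.totals <= 0]
            raise InvalidSampleError(f"non-positive totals for samples: {list(bad)}")
        return self.counts / self.totals * 1e6

    def to_tsv(self, path, totals_path=None) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")
        if totals_path is not None:
            self.totals.rename("total_reads").rename_axis("sample").to_csv(
                totals_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, path, totals_path=None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        totals = None
        if totals_path is not None:
            totals = pd.read_csv(totals_path, sep="\t", index_col=0)["total_reads"]
            totals = totals.reindex(counts.columns).astype(float)
        return cls(counts=counts, totals=totals)


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM values (reads per kb of gene per million total reads)."""

    values: pd.DataFrame
    samples: pd.DataFrame = None

    def __post_init__(self):
        if self.samples is None:
            self.samples = _samples_frame(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class FoldChangeTable:
    """Long-format per-gene, per-contrast fold changes.

    Columns: gene_id, contrast, fc, log2fc, padj (padj may be NaN when the
    source table, such as an imported reference dataset, did not provide
    adjusted p-values).
    """

    data: pd.DataFrame
    provenance: str = "internal"

    REQUIRED = ("gene_id", "contrast", "fc", "log2fc", "padj")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"fold-change table missing columns {missing}")
        if (self.data["fc"] <= 0).any():
            raise ValueError("fold changes must be positive")

    @property
    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.data["contrast"]))

    def matrix(self, field: str = "fc") -> pd.DataFrame:
        """Gene x contrast pivot of one field."""
        return self.data.pivot(index="gene_id", columns="contrast", values=field)

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        sub = self.data[self.data["contrast"] == contrast]
        return sub.set_index("gene_id")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, provenance="internal") -> "FoldChangeTable":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)

    @classmethod
    def concat(cls, tables) -> "FoldChangeTable":
        tables = list(tables)
        prov = {t.provenance for t in tables}
        return cls(
            pd.concat([t.data for t in tables], ignore_index=True),
            provenance=prov.pop() if len(prov) == 1 else "mixed",
        )


PHYSIOLOGY_FIELDS = ("biomass", "pe", "pi", "mg", "nh4n")


@dataclass
class PhysiologySeries:
    """Per-line daily culture measurements.

    Long frame with columns: line, day, biomass (g dw/L), pe (medium PO4-P,
    mg P/L), pi (biomass P, % dw), mg (medium Mg, mg/L), nh4n (medium
    NH4-N, mg N/L).
    """

    data: pd.DataFrame

    def __post_init__(self):
        needed = ("line", "day") + PHYSIOLOGY_FIELDS
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"physiology table missing columns {missing}")
        for line, sub in self.data.groupby("line"):
            days = sub["day"].to_numpy()
            if not (np.diff(days) > 0).all():
                raise ValueError(f"days not strictly increasing for line {line}")

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.data["line"]))

    def series(self, line: str, fieldname: str) -> pd.Series:
        sub = self.data[self.data["line"] == line]
        return sub.set_index("day")[fieldname]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhysiologySeries":
        return cls(pd.read_csv(path, sep="\t"))
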