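"""Correlation of expression profiles against physiology, and PCA.

Profiles are per-gene vectors over an ordered (line, day) axis — six
points (2 transgenic lines x 3 days of mean log2FC) or nine points
(3 lines x 3 days of mean normalized RPKM). Physiology covariates (PE,
PI, N) are aligned on the same axis so a gene's expression can be
correlated with, or co-ordinated against, the culture's phosphate state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, FoldChangeTable, PhysiologySeries, parse_sample_id


def log2fc_profiles(
    fc: FoldChangeTable, lines: list[str], days: list[int]
) -> pd.DataFrame:
    """Genes x (line, day) matrix of log2FC; contrast labels <line>_d<day>."""
    mat = fc.matrix("log2fc")
    cols = [f"{ln}_d{d}" for ln in lines for d in days]
    missing = [c for c in cols if c not in mat.columns]
    if missing:
        raise KeyError(f"contrasts missing from table: {missing}")
    return mat[cols]


def expression_profiles(
    x: ExpressionMatrix, lines: list[str], days: list[int]
) -> pd.DataFrame:
    """Genes x (line, day) matrix from a replicate-mean expression matrix."""
    cols = []
    by_key = {
        (parse_sample_id(c)[0], parse_sample_id(c)[1]): c for c in x.values.columns
    }
    for ln in lines:
        for d in days:
            if (ln, d) not in by_key:
                raise KeyError(f"no column for line {ln} day {d}")
            cols.append(by_key[(ln, d)])
    return x.values[cols]


def physiology_covariates(
    physiology: PhysiologySeries,
    lines: list[str],
    days: list[int],
    fields: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Covariate vectors on the same (line, day) axis as the profiles."""
    if fields is None:
        fields = {"PE": "pe", "PI": "pi", "N": "nh4n"}
    rows = []
    for ln in lines:
        for d in days:
            sub = physiology.data[
                (physiology.data["line"] == ln) & (physiology.data["day"] == d)
            ]
            if sub.empty:
                raise KeyError(f"no physiology record for line {ln} day {d}")
            rows.append([float(sub.iloc[0][col]) for col in fields.values()])
    index = [f"{ln}_d{d}" for ln in lines for d in days]
    return pd.DataFrame(rows, index=index, columns=list(fields))


def pearson_vs_covariates(
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson r against each covariate with two-sided t p-values.

    Zero-variance profiles or covariates yield undefined r (NaN, flagged)
    rather than 0. Long output: gene_id, covariate, r, p, significant,
    undefined.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 axis points")
    if profiles.shape[1] != covariates.shape[0]:
        raise ValueError("profiles and covariates disagree on axis length")
    if not np.isfinite(covariates.to_numpy()).all():
        raise ValueError("covariates must be finite")
    rows = []
    x = profiles.to_numpy(float)
    for cov in covariates.columns:
        y = covariates[cov].to_numpy(float)
        y_var = y.var() > 0
        for i, gene in enumerate(profiles.index):
            xi = x[i]
            if not y_var or xi.var() == 0 or not np.isfinite(xi).all():
                rows.append((gene, cov, np.nan, np.nan, False, True))
                continue
            r, p = stats.pearsonr(xi, y)
            rows.append((gene, cov, r, p, bool(p < alpha), False))
    return pd.DataFrame(
        rows, columns=["gene_id", "covariate", "r", "p", "significant", "undefined"]
    )


@dataclass
class PCAResult:
    """Scores per gene, loadings per axis point, variance-explained ratios."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series
    scale: pd.Series | None = None

    def reconstruct(self) -> pd.DataFrame:
        """Back-transform scores to the (centered/scaled-undone) data."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        if self.scale is not None:
            x = x * self.scale.to_numpy()
        return pd.DataFrame(
            x + self.mean.to_numpy(), index=self.scores.index, columns=self.loadings.index
        )


def pca(
    profiles: pd.DataFrame,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA by SVD of the (centered) gene x axis matrix.

    Genes are observations, axis points variables. Each component is
    oriented so its largest-magnitude loading entry is positive.
    """
    n_genes, n_vars = profiles.shape
    if n_genes < n_components:
        raise ValueError(f"fewer genes ({n_genes}) than components ({n_components})")
    if n_components > n_vars:
        raise ValueError("more components than variables")
    x = profiles.to_numpy(float)
    mean = x.mean(axis=0) if center else np.zeros(n_vars)
    xc = x - mean
    scl = None
    if scale:
        scl = xc.std(axis=0, ddof=1)
        scl[scl == 0] = 1.0
        xc = xc / scl
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # orient: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{k+1}" for k in range(n_components)]
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components], index=profiles.index, columns=pcs
    )
    loadings = pd.DataFrame(vt[:n_components].T, index=profiles.columns, columns=pcs)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components],
        mean=pd.Series(mean, index=profiles.columns),
        scale=None if scl is None else pd.Series(scl, index=profiles.columns),
    )
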