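"""Shared compositional-data primitives.

Both the microbiome and the glycome side of the pipeline treat their
measurements as compositions: only relative information is meaningful, so
analyses run on log-ratio coordinates.  This module holds the primitives both
sides share — closure, minimal-fraction zero imputation, the centered
log-ratio transform, and a deterministic centered PCA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["closure", "impute_min_fraction", "clr_transform", "centered_pca"]


def closure(mat: pd.DataFrame) -> pd.DataFrame:
    """Renormalize rows to sum to 1.  Raises on non-positive row sums."""
    arr = mat.to_numpy(dtype=float)
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative entry at sample {mat.index[r]!r}, part {mat.columns[c]!r}"
        )
    sums = arr.sum(axis=1)
    bad = np.where(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"zero row sum for sample {mat.index[bad[0]]!r}")
    return pd.DataFrame(arr / sums[:, None], index=mat.index, columns=mat.columns)


def impute_min_fraction(rel: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by the column's minimum positive fraction, then re-close.

    For every part (taxon or glycan peak), each zero cell becomes that part's
    smallest positive relative abundance observed over all rows; rows are then
    renormalized to sum to 1.  A part that is zero everywhere has no minimum
    positive fraction and is rejected — upstream filters should have removed it.
    """
    rel = closure(rel)
    arr = rel.to_numpy(dtype=float)
    out = arr.copy()
    for j, col in enumerate(rel.columns):
        pos = arr[:, j][arr[:, j] > 0]
        if pos.size == 0:
            raise ValueError(f"part {col!r} is zero in every sample")
        out[arr[:, j] == 0, j] = pos.min()
    return closure(pd.DataFrame(out, index=rel.index, columns=rel.columns))


def clr_transform(rel: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform, natural log.

    Per row: ``log(x_i) - mean_i log(x_i)``.  Rows of the output sum to zero
    (Aitchison closure).  Entries must be strictly positive.
    """
    arr = rel.to_numpy(dtype=float)
    if np.any(arr <= 0):
        r, c = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive entry at sample {rel.index[r]!r}, part "
            f"{rel.columns[c]!r}; impute zeros first"
        )
    logs = np.log(arr)
    out = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=rel.index, columns=rel.columns)


def centered_pca(mat: pd.DataFrame, k: int):
    """Centered PCA by SVD with a deterministic sign convention.

    Returns ``(scores, loadings, variance_fractions)``: scores is an
    (n, k) DataFrame (columns PC1..PCk), loadings a (p, k) DataFrame, and
    variance_fractions the fraction of total variance per retained component.
    Each component's sign is fixed by making its largest-magnitude loading
    positive.
    """
    X = mat.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    # sign convention: largest-|loading| entry of each PC is positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s**2 / (n - 1)
    frac = var / var.sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=mat.index, columns=cols)
    loadings = pd.DataFrame(Vt[:k].T, index=mat.columns, columns=cols)
    return scores, loadings, frac[:k].copy()
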