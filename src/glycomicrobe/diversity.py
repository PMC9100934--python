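"""Alpha/beta diversity and multi-omics concordance analyses.

Alpha diversity is the Shannon index on genus relative abundances; beta
diversity is Euclidean distance on batch-corrected CLR profiles (Aitchison
geometry).  The permutation analyses — PERMANOVA (Anderson's pseudo-F),
the Mantel test between two distance matrices, and Procrustes superposition
of two ordinations — all take explicit seeds and report p-values with the
``(1 + #{extreme}) / (1 + B)`` estimator, so a permutation p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from .assoc import TraitAssociationScan, TraitAssociationResults

__all__ = [
    "PermutationResult",
    "shannon",
    "aitchison_distance",
    "permanova",
    "mantel",
    "procrustes",
    "beta_pc_association",
]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation analysis."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    name: str


def shannon(rel: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i (nats) per row.

    Rows must be relative abundances (sum 1); zero components contribute 0.
    """
    arr = rel.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative relative abundances")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr), 0.0)
    return pd.Series(-terms.sum(axis=1), index=rel.index, name="shannon")


def aitchison_distance(clrm: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix on CLR coordinates."""
    d = squareform(pdist(clrm.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=clrm.index, columns=clrm.index)


def _as_square(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return d


def _pseudo_f(gower: np.ndarray, labels: np.ndarray) -> float:
    n = gower.shape[0]
    groups, inv = np.unique(labels, return_inverse=True)
    a = len(groups)
    H = np.zeros((n, a))
    H[np.arange(n), inv] = 1.0
    H /= np.sqrt(np.bincount(inv))[inv][:, None]
    ss_total = np.trace(gower)
    ss_among = float(np.einsum("ia,ij,ja->", H, gower, H))
    ss_within = ss_total - ss_among
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dist: pd.DataFrame, grouping, n_permutations: int = 9_999,
              seed: int = 0, strata=None) -> PermutationResult:
    """Permutational multivariate ANOVA (Anderson's pseudo-F) on a distance matrix.

    ``strata`` (optional labels) restricts label permutations to within-stratum
    shuffles — e.g. permute individual labels within gut-location strata when
    location itself is under test.
    """
    d = _as_square(dist)
    labels = np.asarray(grouping)
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    n = d.shape[0]
    # Gower-centered matrix of -d^2/2: trace blocks give the sums of squares
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    f_obs = _pseudo_f(G, labels)
    rng = np.random.default_rng(seed)
    strata_arr = np.asarray(strata) if strata is not None else None
    hits = 0
    idx = np.arange(n)
    for _ in range(n_permutations):
        if strata_arr is None:
            perm = rng.permutation(n)
        else:
            perm = idx.copy()
            for lev in np.unique(strata_arr):
                where = np.where(strata_arr == lev)[0]
                perm[where] = where[rng.permutation(len(where))]
        if _pseudo_f(G, labels[perm]) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationResult(statistic=float(f_obs), p_value=p,
                             n_permutations=n_permutations, seed=seed,
                             name="PERMANOVA")


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, n_permutations: int = 9_999,
           seed: int = 0) -> PermutationResult:
    """Mantel test: Pearson correlation of off-diagonal distances.

    Significance by co-permuting rows/columns of the second matrix; two-sided
    p-value on |R|.
    """
    a = _as_square(d1)
    b = _as_square(d2)
    if a.shape != b.shape:
        raise ValueError(f"size mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = float(np.corrcoef(a[iu], b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if abs(np.corrcoef(a[iu], bp[iu])[0, 1]) >= abs(r_obs):
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationResult(statistic=r_obs, p_value=p,
                             n_permutations=n_permutations, seed=seed,
                             name="Mantel")


def _procrustes_corr(X: np.ndarray, Y: np.ndarray) -> float:
    _, _, m2 = _scipy_procrustes(X, Y)
    return float(np.sqrt(max(0.0, 1.0 - m2)))


def procrustes(X: pd.DataFrame, Y: pd.DataFrame, n_permutations: int = 9_999,
               seed: int = 0) -> PermutationResult:
    """Procrustes concordance of two score matrices.

    Y is optimally translated/rotated/scaled onto X; the statistic is
    ``sqrt(1 - m^2)`` where m^2 is the standardized residual sum of squares.
    Significance by permuting the rows of Y.
    """
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("row count mismatch")
    for M, name in ((Xa, "X"), (Ya, "Y")):
        if np.linalg.matrix_rank(M - M.mean(axis=0)) < 1:
            raise ValueError(f"{name} is rank-deficient after centering")
    c_obs = _procrustes_corr(Xa, Ya)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _procrustes_corr(Xa, Ya[rng.permutation(Ya.shape[0])]) >= c_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationResult(statistic=c_obs, p_value=p,
                             n_permutations=n_permutations, seed=seed,
                             name="Procrustes")


def beta_pc_association(micro_pcs: pd.DataFrame, traits: pd.DataFrame,
                        covariates: pd.DataFrame | None = None,
                        m_eff_glycome: int | None = None
                        ) -> TraitAssociationResults:
    """Regress each glycan trait on each microbiome PC (beta-diversity scan).

    PC scores enter as-is (no quantile normalization).  If ``m_eff_glycome``
    is given, Sidak correction is applied over ``m_eff_glycome x n_PCs``
    tests (e.g. 24 effective glycome tests x 10 PCs = 240).
    """
    res = TraitAssociationScan(traits, micro_pcs, covariates, level="beta_pc",
                               quantile_normalize_predictors=False).fit()
    if m_eff_glycome is not None:
        res.apply_sidak(m_eff_glycome * micro_pcs.shape[1])
    return res
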