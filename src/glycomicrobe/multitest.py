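"""Effective-number-of-tests estimation and multiplicity correction.

Univariate scans over correlated omics blocks (log-ratio transformed glycan
traits, CLR genus abundances) do not perform anything close to
``n_traits * n_taxa`` independent tests.  The machinery here estimates the
effective number of independent tests per block from the eigenvalue spectrum
of the block's correlation matrix (Galwey's estimator), combines blocks by
multiplication, and applies the Sidak step ``1 - (1 - p)^M`` at the combined
count.  Benjamini-Hochberg adjustment is also exposed because the contaminant
screen uses it within each rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffTests",
    "effective_tests_galwey",
    "sidak",
    "combine_effective",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class EffTests:
    """Effective number of independent tests for one variable block."""

    block: str
    m_eff: int
    n_variables: int
    eigenvalues: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 1 <= self.m_eff <= max(self.n_variables, 1):
            raise ValueError(
                f"m_eff={self.m_eff} outside [1, {self.n_variables}] "
                f"for block {self.block!r}"
            )


def effective_tests_galwey(data, block: str = "block") -> EffTests:
    """Galwey's effective number of tests for a matrix of variables.

    Eigenvalues ``lam`` of the variables' Pearson correlation matrix are
    clipped at zero and summarised as ``floor((sum sqrt(lam))^2 / sum(lam))``.
    For mutually independent variables this returns the variable count; for
    perfectly collinear ones it returns 1.

    Parameters
    ----------
    data : array-like or DataFrame, shape (n_obs, n_variables)
        Analysis-ready (already transformed) variables, observations in rows.
        Pairwise-complete correlations are used, so NaNs are tolerated.
    block : str
        Label carried into the result (e.g. ``"glycome"`` or ``"genus"``).
    """
    df = pd.DataFrame(data)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    sds = df.std(ddof=1)
    # relative threshold: a column of identical values can carry std ~1e-15
    tol = 1e-10 * (df.mean().abs() + 1.0)
    constant = sds[sds <= tol].index.tolist()
    if constant:
        raise ValueError(f"constant variable(s): {constant}")
    corr = df.corr(method="pearson").to_numpy()
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    # floor with a guard against 7.999999... artefacts of exact-identity input
    m_eff = int(np.floor(np.sqrt(lam).sum() ** 2 / lam.sum() + 1e-9))
    m_eff = max(1, min(m_eff, df.shape[1]))
    return EffTests(block=block, m_eff=m_eff, n_variables=df.shape[1],
                    eigenvalues=lam[::-1].copy())


def sidak(p, m: int):
    """Sidak-corrected p-value ``1 - (1 - p)^M``, numerically safe for tiny p.

    Computed as ``-expm1(M * log1p(-p))`` so that e.g. p = 4.24e-08 at
    M = 2,088 yields 8.85e-05 rather than losing precision to cancellation;
    results are capped at 1.  Scalar or array input.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(m * np.log1p(-p))
    out = np.where(p >= 1.0, 1.0, out)
    out = np.minimum(out, 1.0)
    return out if out.ndim else float(out)


def combine_effective(blocks: list[EffTests]) -> EffTests:
    """Product of per-block effective test counts (independent blocks)."""
    if not blocks:
        raise ValueError("empty block list")
    if len(blocks) == 1:
        return blocks[0]
    m = 1
    n = 1
    for b in blocks:
        m *= b.m_eff
        n *= b.n_variables
    return EffTests(block="*".join(b.block for b in blocks), m_eff=m,
                    n_variables=n)


def benjamini_hochberg(p):
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
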