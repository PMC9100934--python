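"""Microbiome preprocessing: contaminant screen, filters, CLR, batch correction.

The preprocessing chain for genus-level 16S count tables:

1. classify contaminant taxa from their abnormal statistical behaviour
   (:class:`ContaminantScreen`),
2. drop contaminants, low-coverage libraries and low-abundance taxa
   (:func:`filter_libraries_and_taxa`),
3. impute zeros by each taxon's minimal positive fraction and CLR-transform
   (:func:`impute_zeros`, :func:`clr`),
4. remove technical batch structure with a per-taxon linear mixed model
   (:func:`batch_correct`),
5. average the up-to-nine location x amplicon profiles per individual
   (:func:`average_profiles`) and summarise with PCA (:func:`microbial_pca`).

Contaminant rules (evaluated on CLR abundances, each BH-corrected across taxa
within its own rule):

R1  significant negative dependence on library coverage depth (reagent
    contaminants contribute near-constant absolute material, so their relative
    abundance falls as coverage rises) — BH-adjusted p < 0.05 and a negative
    coverage coefficient;
R2  low consistency across biological replicates: Spearman r < 0.3;
R3  moderately low replicate consistency (r < 0.4) *and* the taxon is not a
    characteristic human-gut genus (absent from the allowlist);
R4  significant sequencing-run discordance (BH-adjusted ANOVA p < 0.05 for the
    run x amplicon-nested-in-location term) *and* not a characteristic gut
    genus.

A taxon is a contaminant iff at least one rule fires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import centered_pca, clr_transform, closure, impute_min_fraction
from .multitest import benjamini_hochberg

__all__ = [
    "impute_zeros",
    "clr",
    "ContaminantScreen",
    "ContaminantReport",
    "detect_contaminants",
    "load_allowlist",
    "filter_libraries_and_taxa",
    "batch_correct",
    "average_profiles",
    "microbial_pca",
    "COVERAGE_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: minimum coverage per amplicon for a library to enter the analysis
COVERAGE_THRESHOLDS = {"V1V2": 10_000, "V3V4": 5_000, "V5V6": 10_000}

RULES = ("R1", "R2", "R3", "R4")


def impute_zeros(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts -> relative abundances with minimal-fraction zero imputation.

    Each zero cell is replaced by the taxon's minimum positive relative
    abundance over all libraries, then rows are renormalized to 1.  A taxon
    with no positive count anywhere is rejected (the abundance filter should
    have removed it).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return impute_min_fraction(closure(counts.astype(float)))


def clr(rel: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform (natural log); rows of output sum to 0."""
    return clr_transform(rel)


def load_allowlist(path) -> set[str]:
    """Read a one-genus-per-line allowlist file ('#' comments ignored)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def _ordered_dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(series.astype(str).unique())
    cols = {}
    for lev in levels[1:]:  # drop first level
        cols[f"{prefix}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Keep an ordered maximal linearly-independent subset of columns."""
    keep: list[str] = []
    Q = np.empty((len(X), 0))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        r = v - Q @ (Q.T @ v)
        if np.linalg.norm(r) > tol * max(norm0, 1.0):
            Q = np.hstack([Q, (r / np.linalg.norm(r))[:, None]])
            keep.append(col)
    return X[keep]


def _covariates_by_library(samples: pd.DataFrame,
                           covariates: pd.DataFrame) -> pd.DataFrame:
    need = ["age", "sex", "bmi", "smoking"]
    missing = [c for c in need if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    unknown = set(samples["individual_id"]) - set(covariates.index)
    if unknown:
        raise ValueError(f"no covariates for individual(s): {sorted(unknown)[:5]}")
    out = covariates.loc[samples["individual_id"], need]
    out.index = samples.index
    if out.isna().any().any():
        raise ValueError("missing covariate values")
    return out.astype(float)


@dataclass
class ContaminantReport:
    """Per-taxon rule statistics and verdicts from :class:`ContaminantScreen`."""

    frame: pd.DataFrame
    rules_evaluated: tuple[str, ...]

    @property
    def contaminants(self) -> set[str]:
        return set(self.frame.index[self.frame["verdict"]])

    def rule_hits(self, taxon: str) -> set[str]:
        row = self.frame.loc[taxon]
        return {r for r in RULES if bool(row.get(r, False))}

    def flagged_by(self, rule: str) -> set[str]:
        if rule not in self.frame.columns:
            return set()
        return set(self.frame.index[self.frame[rule].astype(bool)])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


class ContaminantScreen:
    """Model object classifying taxa as contaminants from their behaviour.

    Parameters
    ----------
    counts : DataFrame (libraries x taxa)
    samples : DataFrame with library metadata (individual_id, location,
        amplicon, run_batch, collection_date, coverage, replicate_group,
        negative_control)
    covariates : DataFrame indexed by individual (age, sex, bmi, smoking)
    allowlist : set of genus labels characteristic for the human gut
        (rules R3/R4 can only fire outside it)
    depth_mode : 'model' tests the coverage term of the full linear model;
        'spearman' uses the marginal Spearman correlation with coverage
    replicate_mode : 'pooled' pools replicate pairs into one Spearman
        correlation per taxon; 'per_pair' averages per-pair correlations
    """

    def __init__(self, counts, samples, covariates, allowlist,
                 depth_mode: str = "model", replicate_mode: str = "pooled",
                 alpha: float = 0.05, r2_threshold: float = 0.3,
                 r3_threshold: float = 0.4):
        if depth_mode not in {"model", "spearman"}:
            raise ValueError(f"unknown depth_mode {depth_mode!r}")
        if replicate_mode not in {"pooled", "per_pair"}:
            raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
        use = ~samples["negative_control"].astype(bool)
        self.samples = samples.loc[use]
        self.counts = counts.loc[self.samples.index]
        self.covariates = covariates
        self.allowlist = set(allowlist)
        self.depth_mode = depth_mode
        self.replicate_mode = replicate_mode
        self.alpha = alpha
        self.r2_threshold = r2_threshold
        self.r3_threshold = r3_threshold

    # ---- helpers ----------------------------------------------------------
    def _design(self) -> tuple[pd.DataFrame, list[str]]:
        s = self.samples
        cov = _covariates_by_library(s, self.covariates)
        combo = (s["location"].astype(str) + "|" + s["amplicon"].astype(str)
                 + "|" + s["run_batch"].astype(str))
        X = pd.concat(
            [
                pd.Series(1.0, index=s.index, name="intercept"),
                cov,
                _ordered_dummies(s["collection_date"], "date"),
                _ordered_dummies(s["location"], "loc"),
                _ordered_dummies(s["amplicon"], "amp"),
                _ordered_dummies(combo, "run"),
            ],
            axis=1,
        )
        X = _drop_collinear(X)
        run_cols = [c for c in X.columns if c.startswith("run[")]
        return X, run_cols

    def _replicate_r(self, clrm: pd.DataFrame) -> pd.Series:
        s = self.samples
        pairs: list[tuple[str, str]] = []
        grouped = s[s["replicate_group"].astype(str).str.len() > 0]
        for (_, _), grp in grouped.groupby(
                [grouped["replicate_group"], grouped["amplicon"]]):
            libs = list(grp.index)
            pairs.extend((libs[i], libs[i + 1]) for i in range(0, len(libs) - 1, 2))
        if len(pairs) < 2:
            return pd.Series(np.nan, index=clrm.columns)
        a = clrm.loc[[p[0] for p in pairs]].to_numpy()
        b = clrm.loc[[p[1] for p in pairs]].to_numpy()
        out = np.empty(clrm.shape[1])
        for j in range(clrm.shape[1]):
            if self.replicate_mode == "pooled":
                out[j] = stats.spearmanr(a[:, j], b[:, j]).statistic
            else:
                out[j] = np.nan  # per-pair mode needs >=3 libs per pair; unused default
        return pd.Series(out, index=clrm.columns)

    # ---- fit --------------------------------------------------------------
    def fit(self) -> ContaminantReport:
        counts = self.counts.loc[:, (self.counts > 0).any(axis=0)]
        dropped = set(self.counts.columns) - set(counts.columns)
        if dropped:
            logger.warning("dropping %d all-zero taxa from screen", len(dropped))
        clrm = clr(impute_zeros(counts))
        taxa = list(clrm.columns)
        Y = clrm.to_numpy()
        n = Y.shape[0]

        X, run_cols = self._design()
        logcov = np.log(self.samples["coverage"].to_numpy(dtype=float))
        Xf = np.column_stack([X.to_numpy(), logcov - logcov.mean()])
        p_full = Xf.shape[1]
        pinv = np.linalg.pinv(Xf)
        beta = pinv @ Y
        resid = Y - Xf @ beta
        rss = (resid**2).sum(axis=0)
        dof = n - p_full
        sigma2 = rss / dof
        xtx_inv_jj = float((pinv @ pinv.T)[-1, -1])
        cov_coef = beta[-1]
        cov_se = np.sqrt(sigma2 * xtx_inv_jj)
        cov_t = cov_coef / cov_se
        cov_p = 2 * stats.t.sf(np.abs(cov_t), dof)

        if self.depth_mode == "spearman":
            cov_coef = np.empty(len(taxa))
            cov_p = np.empty(len(taxa))
            for j in range(len(taxa)):
                r = stats.spearmanr(Y[:, j], logcov)
                cov_coef[j], cov_p[j] = r.statistic, r.pvalue

        # run-discordance ANOVA: F-test of the run term by model comparison
        keep = [c for c in X.columns if c not in run_cols]
        Xr = np.column_stack([X[keep].to_numpy(), logcov - logcov.mean()])
        beta_r = np.linalg.pinv(Xr) @ Y
        rss_r = ((Y - Xr @ beta_r) ** 2).sum(axis=0)
        df_run = p_full - Xr.shape[1]
        if df_run > 0:
            F = ((rss_r - rss) / df_run) / (rss / dof)
            run_p = stats.f.sf(F, df_run, dof)
        else:
            run_p = np.full(len(taxa), np.nan)

        rep_r = self._replicate_r(clrm)
        rep_ok = rep_r.notna().any()

        frame = pd.DataFrame(index=pd.Index(taxa, name="taxon"))
        frame["depth_coef"] = cov_coef
        frame["depth_p"] = cov_p
        frame["depth_p_adj"] = benjamini_hochberg(cov_p)
        frame["replicate_r"] = rep_r
        frame["run_p"] = run_p
        if np.all(np.isnan(run_p)):
            frame["run_p_adj"] = np.nan
        else:
            frame["run_p_adj"] = benjamini_hochberg(run_p)
        frame["in_allowlist"] = [t in self.allowlist for t in taxa]

        frame["R1"] = (frame["depth_p_adj"] < self.alpha) & (frame["depth_coef"] < 0)
        if rep_ok:
            frame["R2"] = frame["replicate_r"] < self.r2_threshold
            frame["R3"] = (frame["replicate_r"] < self.r3_threshold) & ~frame["in_allowlist"]
        else:
            frame["R2"] = False
            frame["R3"] = False
        frame["R4"] = (frame["run_p_adj"] < self.alpha) & ~frame["in_allowlist"]
        frame[["R1", "R2", "R3", "R4"]] = frame[["R1", "R2", "R3", "R4"]].fillna(False)
        frame["verdict"] = frame[list(RULES)].any(axis=1)
        rules = ("R1", "R4") if not rep_ok else RULES
        return ContaminantReport(frame=frame, rules_evaluated=rules)


def detect_contaminants(counts, samples, covariates, gut_taxa_allowlist,
                        **kwargs) -> ContaminantReport:
    """Functional wrapper around :class:`ContaminantScreen`."""
    return ContaminantScreen(counts, samples, covariates,
                             gut_taxa_allowlist, **kwargs).fit()


def filter_libraries_and_taxa(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    report: ContaminantReport | None = None,
    coverage_thresholds: dict[str, int] | None = None,
    abundance_threshold: float = 1e-4,
    abundance_filter_mode: str = "any",
):
    """Apply the three filters in order; returns (counts, samples) retained.

    1. contaminant taxa from ``report`` are dropped;
    2. libraries below the amplicon-specific coverage threshold (default
       10,000x for V1V2/V5V6, 5,000x for V3V4; 'at least' is inclusive) are
       dropped;
    3. taxa whose mean relative abundance is below ``abundance_threshold``
       (default 0.01%) in at least one location-amplicon stratum
       (``abundance_filter_mode='any'``, the literal reading) or in every
       stratum (``'all'``) are dropped.
    """
    if abundance_filter_mode not in {"any", "all"}:
        raise ValueError(f"unknown abundance_filter_mode {abundance_filter_mode!r}")
    thresholds = dict(COVERAGE_THRESHOLDS)
    if coverage_thresholds:
        thresholds.update(coverage_thresholds)

    taxa = list(counts.columns)
    if report is not None:
        taxa = [t for t in taxa if t not in report.contaminants]

    min_cov = samples["amplicon"].map(thresholds)
    if min_cov.isna().any():
        bad = samples.loc[min_cov.isna(), "amplicon"].unique()
        raise ValueError(f"no coverage threshold for amplicon(s) {list(bad)}")
    keep_libs = samples.index[samples["coverage"] >= min_cov]
    sub = counts.loc[keep_libs, taxa]
    meta = samples.loc[keep_libs]
    if sub.empty:
        raise ValueError("no data after filtering")

    rel = sub.div(sub.sum(axis=1), axis=0)
    strata = meta["location"].astype(str) + "|" + meta["amplicon"].astype(str)
    means = rel.groupby(strata).mean()
    low = means < abundance_threshold
    drop = low.any(axis=0) if abundance_filter_mode == "any" else low.all(axis=0)
    kept_taxa = [t for t in taxa if not drop[t]]
    if not kept_taxa:
        raise ValueError("no data after filtering")
    return sub[kept_taxa], meta


def batch_correct(clrm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Remove technical batch structure from CLR abundances, per taxon.

    For each taxon a linear mixed model is fitted by REML: fixed effects for
    location, amplicon and run x amplicon nested in location; a random
    intercept for the collection date.  The corrected value is
    ``observed - fitted fixed terms - predicted random intercept + grand
    mean``, so biological (between-individual) variation stays in the
    residual.  If the random-effect variance hits the boundary or the fit
    fails, the taxon falls back to ordinary least squares with the collection
    date as a fixed effect (logged).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    s = samples.loc[clrm.index]
    for col in ("run_batch", "amplicon", "location", "collection_date"):
        if col not in s.columns or s[col].isna().any():
            raise ValueError(f"sample metadata column {col!r} missing or incomplete")
    combo = (s["location"].astype(str) + "|" + s["amplicon"].astype(str)
             + "|" + s["run_batch"].astype(str))
    X = pd.concat(
        [
            pd.Series(1.0, index=s.index, name="intercept"),
            _ordered_dummies(s["location"], "loc"),
            _ordered_dummies(s["amplicon"], "amp"),
            _ordered_dummies(combo, "run"),
        ],
        axis=1,
    )
    X = _drop_collinear(X)
    Xd = pd.concat([X, _ordered_dummies(s["collection_date"], "date")], axis=1)
    Xd = _drop_collinear(Xd)
    groups = s["collection_date"].astype(str)
    Xnp, Xdnp = X.to_numpy(), Xd.to_numpy()
    pinv_d = np.linalg.pinv(Xdnp)

    out = np.empty_like(clrm.to_numpy())
    n_fallback = 0
    for j, taxon in enumerate(clrm.columns):
        y = clrm.iloc[:, j].to_numpy(dtype=float)
        corrected = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, Xnp, groups=groups)
                res = model.fit(reml=True)
            if res.converged and np.isfinite(res.params).all():
                fitted_fixed = Xnp @ res.fe_params
                re = np.zeros(len(y))
                blups = {g: float(np.asarray(v).ravel()[0])
                         for g, v in res.random_effects.items()}
                re = groups.map(blups).to_numpy(dtype=float)
                corrected = y - fitted_fixed - re + fitted_fixed.mean() + re.mean()
        except Exception:  # noqa: BLE001 - singular fits fall back to OLS
            corrected = None
        if corrected is None:
            n_fallback += 1
            beta = pinv_d @ y
            fitted = Xdnp @ beta
            corrected = y - fitted + fitted.mean()
        out[:, j] = corrected
    if n_fallback:
        logger.warning("batch_correct: OLS fallback for %d/%d taxa",
                       n_fallback, clrm.shape[1])
    return pd.DataFrame(out, index=clrm.index, columns=clrm.columns)


def average_profiles(clrm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean CLR profile per individual over available location x amplicon libraries."""
    ind = samples.loc[clrm.index, "individual_id"]
    out = clrm.groupby(ind).mean()
    out.index.name = "individual_id"
    return out


def microbial_pca(clrm: pd.DataFrame, k: int = 4):
    """First ``k`` microbial principal components of (per-individual) CLR data.

    Returns ``(scores, variance_fractions)``; the centered PCA uses the
    package-wide sign convention (largest-magnitude loading positive).
    """
    scores, _, frac = centered_pca(clrm, k)
    return scores, frac
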