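"""End-to-end pipeline: simulate/load -> QC -> traits -> diversity -> associations.

One :class:`RunConfig` drives a reproducible run.  Inputs are either loaded
from plain-text tables or generated by :mod:`glycomicrobe.synthdata`; the
stages then execute in a fixed order and the run writes versioned outputs, a
machine-readable ``summary.yaml`` (counts surviving each filter, effective
test numbers, top associations, every threshold used) and a human-readable
``report.md``.  All randomness funnels through ``RunConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, diversity, glycotraits, microqc, multitest, synthdata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults mirror the analysis protocol)."""

    outdir: str = "glycomicrobe_run"
    # input tables; None means simulate with `synth`
    counts: str | None = None
    samples: str | None = None
    glycome: str | None = None
    covariates: str | None = None
    prs: str | None = None
    allowlist: str | None = None
    synth: synthdata.SynthConfig | None = None
    # thresholds (defaults: the protocol's stated constants)
    coverage_thresholds: dict = field(
        default_factory=lambda: dict(microqc.COVERAGE_THRESHOLDS))
    abundance_threshold: float = 1e-4  # 0.01%
    abundance_filter_mode: str = "any"
    contaminant_alpha: float = 0.05
    replicate_r2: float = 0.3
    replicate_r3: float = 0.4
    n_micro_pcs: int = 4
    n_beta_pcs: int = 10
    n_glycan_pcs: int = 10
    n_permutations: int = 9_999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance_threshold <= 0 or self.contaminant_alpha <= 0:
            raise ValueError("thresholds must be positive")
        if any(v <= 0 for v in self.coverage_thresholds.values()):
            raise ValueError("coverage thresholds must be positive")


def _load_inputs(config: RunConfig):
    if config.counts is None:
        synth = config.synth or synthdata.SynthConfig(seed=config.seed)
        counts, samples, glycome, covariates, prs, _ = synthdata.simulate_all(synth)
        allowlist = set(synth.gut_taxon_names())
        return counts, samples, glycome, covariates, prs, allowlist
    paths = dict(counts=config.counts, samples=config.samples,
                 glycome=config.glycome, covariates=config.covariates)
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            raise PipelineError(f"stage=load: missing input {name!r} ({p})")
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    samples = pd.read_csv(config.samples, sep="\t", index_col=0)
    samples["replicate_group"] = samples.get(
        "replicate_group", pd.Series("", index=samples.index)).fillna("")
    if "negative_control" not in samples.columns:
        samples["negative_control"] = False
    glycome = pd.read_csv(config.glycome, index_col=0)
    covariates = pd.read_csv(config.covariates, index_col=0)
    prs = (pd.read_csv(config.prs, index_col=0)
           if config.prs and Path(config.prs).exists() else None)
    if config.allowlist and Path(config.allowlist).exists():
        allowlist = microqc.load_allowlist(config.allowlist)
    else:
        allowlist = set()
    return counts, samples, glycome, covariates, prs, allowlist


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage={name}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "thresholds": {
        "coverage": dict(config.coverage_thresholds),
        "abundance": config.abundance_threshold,
        "abundance_filter_mode": config.abundance_filter_mode,
        "contaminant_alpha": config.contaminant_alpha,
        "replicate_r": [config.replicate_r2, config.replicate_r3],
        "n_permutations": config.n_permutations,
    }}

    counts, samples, glycome, covariates, prs, allowlist = _stage("load")(
        _load_inputs)(config)
    summary["input"] = {"libraries": int(len(counts)),
                        "taxa": int(counts.shape[1]),
                        "individuals": int(samples["individual_id"].nunique())}

    # --- microbiome QC -----------------------------------------------------
    report = _stage("contaminants")(microqc.detect_contaminants)(
        counts, samples, covariates, allowlist,
        alpha=config.contaminant_alpha, r2_threshold=config.replicate_r2,
        r3_threshold=config.replicate_r3)
    report.to_csv(outdir / "contaminant_report.csv")
    summary["contaminants"] = {
        "flagged": sorted(report.contaminants),
        "per_rule": {r: sorted(report.flagged_by(r)) for r in microqc.RULES},
    }

    counts_f, samples_f = _stage("filter")(microqc.filter_libraries_and_taxa)(
        counts, samples, report,
        coverage_thresholds=config.coverage_thresholds,
        abundance_threshold=config.abundance_threshold,
        abundance_filter_mode=config.abundance_filter_mode)
    summary["after_filter"] = {"libraries": int(len(counts_f)),
                               "taxa": int(counts_f.shape[1])}

    rel = _stage("impute")(microqc.impute_zeros)(counts_f)
    clrm = _stage("clr")(microqc.clr)(rel)
    corrected = _stage("batch_correct")(microqc.batch_correct)(clrm, samples_f)
    by_ind = _stage("average")(microqc.average_profiles)(corrected, samples_f)
    by_ind.to_csv(outdir / "clr_by_individual.tsv", sep="\t")
    mpc_scores, mpc_frac = _stage("microbial_pca")(microqc.microbial_pca)(
        by_ind, k=max(config.n_micro_pcs, config.n_beta_pcs))
    mpc_scores.to_csv(outdir / "microbial_pcs.csv")
    cov_pcs = mpc_scores.iloc[:, : config.n_micro_pcs]
    summary["microbial_pca_variance"] = [round(float(v), 4)
                                         for v in mpc_frac[: config.n_micro_pcs]]

    # --- glycome -----------------------------------------------------------
    traits = _stage("glycotraits")(glycotraits.build_trait_matrix)(glycome)
    traits.to_csv(outdir / "traits.csv")
    summary["traits"] = int(traits.shape[1])
    gpc_scores, _, gpc_frac = _stage("glycan_pca")(glycotraits.glycan_pca)(
        traits, k=config.n_glycan_pcs)

    individuals = by_ind.index.intersection(traits.index).intersection(
        covariates.index).sort_values()
    summary["individuals_analyzed"] = int(len(individuals))

    # --- effective tests ---------------------------------------------------
    eff_gly = _stage("efftests")(multitest.effective_tests_galwey)(
        traits.loc[individuals], block="glycome")
    eff_gen = _stage("efftests")(multitest.effective_tests_galwey)(
        by_ind.loc[individuals], block="genus")
    m_product = multitest.combine_effective([eff_gly, eff_gen])
    summary["effective_tests"] = {"glycome": eff_gly.m_eff,
                                  "genus": eff_gen.m_eff,
                                  "product": m_product.m_eff}

    # --- diversity ---------------------------------------------------------
    rng_seed = config.seed
    h_lib = diversity.shannon(rel)
    h_ind = h_lib.groupby(samples_f.loc[rel.index, "individual_id"]).mean()
    h_ind.to_csv(outdir / "shannon.csv")
    alpha_scan = _stage("alpha_assoc")(
        lambda: assoc.TraitAssociationScan(
            traits.loc[individuals],
            h_ind.loc[individuals].to_frame("shannon"),
            covariates.loc[individuals],
            quantile_normalize_predictors=False, level="alpha").fit()
    )()
    alpha_scan.apply_sidak(eff_gly.m_eff)
    alpha_scan.to_csv(outdir / "alpha_associations.csv")

    # location PERMANOVA on per-individual-per-location mean profiles
    key = (samples_f.loc[corrected.index, "individual_id"].astype(str) + "|"
           + samples_f.loc[corrected.index, "location"].astype(str))
    loc_prof = corrected.groupby(key).mean()
    loc_labels = [k.split("|")[1] for k in loc_prof.index]
    ind_labels = [k.split("|")[0] for k in loc_prof.index]
    dist_loc = diversity.aitchison_distance(loc_prof)
    perm_loc = _stage("permanova")(diversity.permanova)(
        dist_loc, loc_labels, n_permutations=config.n_permutations,
        seed=rng_seed)
    perm_ind = _stage("permanova")(diversity.permanova)(
        dist_loc, ind_labels, n_permutations=config.n_permutations,
        seed=rng_seed + 1, strata=loc_labels)
    summary["permanova"] = {
        "location": {"pseudo_F": round(perm_loc.statistic, 4),
                     "p": perm_loc.p_value},
        "individual": {"pseudo_F": round(perm_ind.statistic, 4),
                       "p": perm_ind.p_value},
    }

    micro_dist = diversity.aitchison_distance(by_ind.loc[individuals])
    gly_dist = diversity.aitchison_distance(_imputed_gp(glycome).loc[individuals])
    mant = _stage("mantel")(diversity.mantel)(
        micro_dist, gly_dist, n_permutations=config.n_permutations,
        seed=rng_seed + 2)
    proc = _stage("procrustes")(diversity.procrustes)(
        mpc_scores.loc[individuals].iloc[:, : config.n_beta_pcs],
        gpc_scores.loc[individuals].iloc[:, : config.n_beta_pcs],
        n_permutations=config.n_permutations, seed=rng_seed + 3)
    summary["mantel"] = {"R": round(mant.statistic, 4), "p": mant.p_value}
    summary["procrustes"] = {"correlation": round(proc.statistic, 4),
                             "p": proc.p_value}

    beta_scan = _stage("beta_assoc")(diversity.beta_pc_association)(
        mpc_scores.loc[individuals].iloc[:, : config.n_beta_pcs],
        traits.loc[individuals], covariates.loc[individuals],
        m_eff_glycome=eff_gly.m_eff)
    beta_scan.to_csv(outdir / "beta_pc_associations.csv")

    # --- univariate scan ---------------------------------------------------
    results = _stage("scan")(assoc.scan)(
        by_ind.loc[individuals], traits.loc[individuals],
        covariates.loc[individuals], cov_pcs.loc[individuals])
    results.apply_sidak(m_product.m_eff)
    results.to_csv(outdir / "associations.csv")
    k, n_pairs, p_binom = assoc.enrichment_test(
        results.frame["p_nominal"].to_numpy())
    summary["scan"] = {
        "pairs": n_pairs,
        "nominal_below_0.05": k,
        "binomial_enrichment_p": float(f"{p_binom:.6g}"),
        "sidak_below_0.05": int((results.frame["p_sidak"] < 0.05).sum()),
    }
    summary["top_associations"] = [
        {"taxon": r.taxon, "trait": r.trait, "beta": round(r.beta, 4),
         "se": round(r.se, 4), "p_nominal": float(f"{r.p_nominal:.4g}"),
         "p_sidak": float(f"{r.p_sidak:.4g}")}
        for r in results.top(5).itertuples()
    ]

    # --- Mendelian randomization ------------------------------------------
    if prs is not None and len(prs.columns):
        mr_rows = []
        prs_al = prs.loc[prs.index.intersection(individuals)]
        for col in prs.columns:
            for taxon in by_ind.columns:
                r = assoc.mr_stage(
                    prs_al[col].to_numpy(),
                    by_ind.loc[prs_al.index, taxon].to_numpy(),
                    covariates.loc[prs_al.index].to_numpy(),
                    taxon=taxon, trait_name=col)
                mr_rows.append(dict(prs=col, taxon=taxon, beta=r.beta,
                                    se=r.se, p_nominal=r.p_nominal, n=r.n))
        mr = pd.DataFrame(mr_rows).sort_values("p_nominal")
        mr.to_csv(outdir / "mr_results.csv", index=False)
        best = mr.iloc[0]
        summary["mr_top"] = {"prs": best["prs"], "taxon": best["taxon"],
                             "beta": round(float(best["beta"]), 4),
                             "p_nominal": float(f"{best['p_nominal']:.4g}")}

    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    _write_report_md(outdir / "report.md", summary)
    return summary


def _imputed_gp(glycome: pd.DataFrame) -> pd.DataFrame:
    from .compositional import impute_min_fraction

    gp = glycotraits.harmonize(glycome, glycotraits.default_harmonization_map())
    return glycotraits.original_trait_clr(
        impute_min_fraction(glycotraits.total_area_normalize(gp)))


def _write_report_md(path: Path, s: dict) -> None:
    lines = ["# glycomicrobe run report", ""]
    lines += [f"- seed: {s['seed']}",
              f"- libraries in: {s['input']['libraries']} "
              f"({s['input']['taxa']} taxa, {s['input']['individuals']} individuals)",
              f"- contaminants flagged: {len(s['contaminants']['flagged'])}",
              f"- after filters: {s['after_filter']['libraries']} libraries, "
              f"{s['after_filter']['taxa']} taxa",
              f"- individuals analyzed: {s['individuals_analyzed']}",
              f"- effective tests: glycome {s['effective_tests']['glycome']}, "
              f"genus {s['effective_tests']['genus']}, product "
              f"{s['effective_tests']['product']}",
              f"- scan: {s['scan']['pairs']} pairs, "
              f"{s['scan']['nominal_below_0.05']} nominal p<0.05, "
              f"{s['scan']['sidak_below_0.05']} Sidak p<0.05", ""]
    lines.append("## Top associations\n")
    lines.append("| taxon | trait | beta | se | p nominal | p Sidak |")
    lines.append("|---|---|---|---|---|---|")
    for t in s["top_associations"]:
        lines.append(f"| {t['taxon']} | {t['trait']} | {t['beta']} | {t['se']} "
                     f"| {t['p_nominal']} | {t['p_sidak']} |")
    path.write_text("\n".join(lines) + "\n")
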