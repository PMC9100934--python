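"""Synthetic microbiome + glycome + covariate + PRS generator with ground truth.

The generator emulates the structure of a mucosal-microbiome / plasma-glycome
study: every individual is biopsied at three gut locations (ileum,
transversum, rectum) and each biopsy is sequenced with three 16S amplicons
(V1V2, V3V4, V5V6), giving up to nine libraries per individual, organised in
sequencing runs (by default nine — one per location x amplicon stratum).
A subset of individual-location combinations is sequenced twice (biological
replicates).  Genus counts are drawn multinomially from a per-library
composition ``softmax(base + location + run-batch + date + individual +
library noise)`` on the log scale, so relative abundances are logistic-normal
around a realistic rank-abundance curve.

Three contaminant mechanisms are planted disjointly, matching the abnormal
behaviours a contaminant screen should catch:

``depth_inverse``
    The taxon contributes a fixed absolute read count (individual-specific
    mean, Poisson draw) independent of library coverage, so its *relative*
    abundance falls with coverage depth.
``replicate_inconsistent``
    The taxon's log abundance is drawn independently per library, so
    biological replicates disagree.
``run_specific``
    The taxon appears only in a designated subset of sequencing runs.

The glycome is a 39-peak logistic-normal composition per individual with a
fixed chromatogram-like mean; planted (taxon, peak, beta) effects shift the
peak's latent log coordinate by ``beta x`` the individual's standardized CLR
abundance of the taxon, so downstream log-ratio analyses see (approximately)
linear effects.  Covariates are drawn to match the emulated cohort's
demographics (age 55.66 +/- 13.05, BMI 26.37 +/- 4.64, 42.3% male, 23.2%
smokers), and a polygenic score is generated with a configurable correlation
to one designated glycan peak.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SynthConfig.seed`` (stable across platforms), so a fixed seed reproduces
every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .compositional import clr_transform, impute_min_fraction

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "simulate_microbiome",
    "simulate_glycome",
    "simulate_covariates_and_prs",
    "simulate_all",
    "write_dataset",
]

LOCATIONS = ("ileum", "transversum", "rectum")
AMPLICONS = ("V1V2", "V3V4", "V5V6")
MECHANISMS = ("depth_inverse", "replicate_inconsistent", "run_specific")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset (defaults: cohort-like, desk-sized)."""

    n_individuals: int = 200
    n_taxa: int = 150
    n_contaminants_per_mechanism: int = 5
    n_replicated_pairs: int = 25
    locations: tuple[str, ...] = LOCATIONS
    amplicons: tuple[str, ...] = AMPLICONS
    n_runs: int = 9
    coverage_range: tuple[int, int] = (5_000, 50_000)
    batch_effect_sd: float = 0.5
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    n_peaks: int = 39
    n_dates: int = 12
    individual_sd: float = 1.2
    location_sd: float = 0.3
    date_sd: float = 0.2
    library_noise_sd: float = 0.3
    base_sd: float = 0.8
    glycome_noise_sd: float = 0.3
    prs_trait: str | None = None
    prs_r: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n_cont = 3 * self.n_contaminants_per_mechanism
        if self.n_taxa <= n_cont:
            raise ValueError(
                f"n_taxa={self.n_taxa} must exceed total planted contaminants {n_cont}"
            )
        lo, hi = self.coverage_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid coverage_range {self.coverage_range}")
        if self.n_runs < len(self.locations) * len(self.amplicons):
            raise ValueError("n_runs below one run per location-amplicon stratum")
        if not -1.0 <= self.prs_r <= 1.0:
            raise ValueError(f"prs_r={self.prs_r} outside [-1, 1]")
        peaks = {f"P{i + 1}" for i in range(self.n_peaks)}
        taxa = set(self.taxon_names())
        for taxon, trait, _ in self.planted_effects:
            if taxon not in taxa:
                raise ValueError(f"planted taxon {taxon!r} does not exist")
            if trait not in peaks:
                raise ValueError(f"planted trait {trait!r} is not an original peak")
        if self.prs_trait is not None and self.prs_trait not in peaks:
            raise ValueError(f"prs_trait {self.prs_trait!r} is not an original peak")

    # taxon naming: gut genera first, then the planted contaminants
    def gut_taxon_names(self) -> list[str]:
        n_gut = self.n_taxa - 3 * self.n_contaminants_per_mechanism
        return [f"genus_{i + 1:03d}" for i in range(n_gut)]

    def contaminant_names(self) -> dict[str, list[str]]:
        k = self.n_contaminants_per_mechanism
        tag = {"depth_inverse": "depth", "replicate_inconsistent": "rep",
               "run_specific": "run"}
        return {m: [f"contam_{tag[m]}_{i + 1:02d}" for i in range(k)]
                for m in MECHANISMS}

    def taxon_names(self) -> list[str]:
        names = self.gut_taxon_names()
        for m in MECHANISMS:
            names += self.contaminant_names()[m]
        return names


@dataclass
class SynthTruth:
    """Planted ground truth needed for recovery tests."""

    contaminant_taxa: dict[str, set[str]]
    true_batch_offsets: pd.DataFrame  # runs x taxa, log-abundance units
    true_effects: list[tuple[str, str, float]]
    gut_taxa: list[str]
    seed: int

    def all_contaminants(self) -> set[str]:
        out: set[str] = set()
        for s in self.contaminant_taxa.values():
            out |= s
        return out


def _run_label(loc: str, amp: str, sub: int, runs_per_stratum: int) -> str:
    if runs_per_stratum == 1:
        return f"run_{loc}_{amp}"
    return f"run_{loc}_{amp}_{sub + 1}"


def simulate_microbiome(config: SynthConfig):
    """Generate (counts, samples, truth): the 16S side of the dataset.

    Returns
    -------
    counts : DataFrame (libraries x taxa), non-negative ints, rows sum to coverage
    samples : DataFrame with per-library metadata (individual_id, location,
        amplicon, run_batch, collection_date, coverage, replicate_group,
        negative_control)
    truth : SynthTruth
    """
    rng = np.random.default_rng([config.seed, 0])
    taxa = config.taxon_names()
    gut = config.gut_taxon_names()
    contam = config.contaminant_names()
    n_taxa = len(taxa)
    individuals = [f"ind_{i + 1:04d}" for i in range(config.n_individuals)]

    # ---- library layout ---------------------------------------------------
    n_strata = len(config.locations) * len(config.amplicons)
    runs_per_stratum = config.n_runs // n_strata
    recs = []
    dates = [f"date_{d + 1:02d}" for d in range(config.n_dates)]
    ind_date = {ind: dates[rng.integers(0, config.n_dates)] for ind in individuals}
    ind_run_sub = {ind: int(rng.integers(0, runs_per_stratum)) for ind in individuals}
    for ind in individuals:
        for loc in config.locations:
            for amp in config.amplicons:
                recs.append(dict(
                    library_id=f"{ind}_{loc}_{amp}",
                    individual_id=ind, location=loc, amplicon=amp,
                    run_batch=_run_label(loc, amp, ind_run_sub[ind], runs_per_stratum),
                    collection_date=ind_date[ind],
                    replicate_group="", negative_control=False,
                ))
    # biological replicates: re-sequence chosen individual-location combos
    combos = [(ind, loc) for ind in individuals for loc in config.locations]
    if config.n_replicated_pairs > len(combos):
        raise ValueError("more replicate pairs than individual-location combos")
    rep_idx = rng.choice(len(combos), size=config.n_replicated_pairs, replace=False)
    rep_combos = [combos[i] for i in sorted(rep_idx)]
    rep_groups = {c: f"rep_{c[0]}_{c[1]}" for c in rep_combos}
    for rec in recs:
        key = (rec["individual_id"], rec["location"])
        if key in rep_groups:
            rec["replicate_group"] = rep_groups[key]
    for ind, loc in rep_combos:
        for amp in config.amplicons:
            recs.append(dict(
                library_id=f"{ind}_{loc}_{amp}_rep",
                individual_id=ind, location=loc, amplicon=amp,
                run_batch=_run_label(loc, amp, ind_run_sub[ind], runs_per_stratum),
                collection_date=ind_date[ind],
                replicate_group=rep_groups[(ind, loc)], negative_control=False,
            ))
    samples = pd.DataFrame(recs).set_index("library_id")
    samples["coverage"] = rng.integers(config.coverage_range[0],
                                       config.coverage_range[1] + 1,
                                       size=len(samples))

    # ---- log-abundance model ---------------------------------------------
    base = np.sort(rng.normal(0.0, config.base_sd, size=n_taxa))[::-1]
    base_s = pd.Series(base, index=taxa)
    # contaminant baselines: moderate, so they are observable but not dominant
    for m in MECHANISMS:
        for name in contam[m]:
            base_s[name] = rng.normal(-1.0, 0.3)

    loc_eff = pd.DataFrame(
        rng.normal(0.0, config.location_sd, size=(len(config.locations), n_taxa)),
        index=list(config.locations), columns=taxa)
    run_labels = sorted({r["run_batch"] for r in recs})
    batch = pd.DataFrame(
        rng.normal(0.0, config.batch_effect_sd, size=(len(run_labels), n_taxa)),
        index=run_labels, columns=taxa)
    date_eff = pd.DataFrame(
        rng.normal(0.0, config.date_sd, size=(len(dates), n_taxa)),
        index=dates, columns=taxa)
    ind_eff = pd.DataFrame(
        rng.normal(0.0, config.individual_sd, size=(len(individuals), n_taxa)),
        index=individuals, columns=taxa)

    # depth_inverse: individual-specific expected absolute count, coverage-free
    depth_mean = {}
    for name in contam["depth_inverse"]:
        depth_mean[name] = 30.0 * np.exp(
            rng.normal(0.0, config.individual_sd, size=len(individuals)))
    depth_mean = pd.DataFrame(depth_mean, index=individuals) if depth_mean else None

    # run_specific: each such taxon appears in a designated third of the runs
    run_sets: dict[str, set[str]] = {}
    for name in contam["run_specific"]:
        k = max(1, len(run_labels) // 3)
        chosen = rng.choice(len(run_labels), size=k, replace=False)
        run_sets[name] = {run_labels[i] for i in sorted(chosen)}

    rep_noise_sd = 2.0  # independent per-library noise of replicate_inconsistent taxa
    col_of = {t: j for j, t in enumerate(taxa)}
    depth_cols = [col_of[t] for t in contam["depth_inverse"]]
    rep_cols = [col_of[t] for t in contam["replicate_inconsistent"]]
    counts = np.zeros((len(samples), n_taxa), dtype=np.int64)

    for i, (lib, rec) in enumerate(samples.iterrows()):
        ind, loc, run, date = (rec["individual_id"], rec["location"],
                               rec["run_batch"], rec["collection_date"])
        cov = int(rec["coverage"])
        logw = (base_s.to_numpy()
                + loc_eff.loc[loc].to_numpy()
                + batch.loc[run].to_numpy()
                + date_eff.loc[date].to_numpy()
                + ind_eff.loc[ind].to_numpy()
                + rng.normal(0.0, config.library_noise_sd, size=n_taxa))
        # replicate-inconsistent taxa: fresh large noise per library
        for j in rep_cols:
            logw[j] = base_s.iloc[j] + rng.normal(0.0, rep_noise_sd)
        # run-specific taxa: absent outside their designated runs
        zero_mask = np.zeros(n_taxa, dtype=bool)
        for name, runs_ok in run_sets.items():
            if run not in runs_ok:
                zero_mask[col_of[name]] = True
        # depth-inverse taxa: fixed absolute counts first
        fixed = np.zeros(n_taxa, dtype=np.int64)
        for name, j in zip(contam["depth_inverse"], depth_cols):
            fixed[j] = rng.poisson(depth_mean.loc[ind, name])
        budget = cov - int(fixed.sum())
        if budget <= 0:  # pathological coverage; keep row sum exact regardless
            fixed = np.zeros(n_taxa, dtype=np.int64)
            budget = cov
        w = np.exp(logw - logw.max())
        w[depth_cols] = 0.0
        w[zero_mask] = 0.0
        counts[i] = fixed + rng.multinomial(budget, w / w.sum())

    counts_df = pd.DataFrame(counts, index=samples.index, columns=taxa)
    truth = SynthTruth(
        contaminant_taxa={m: set(contam[m]) for m in MECHANISMS},
        true_batch_offsets=batch,
        true_effects=list(config.planted_effects),
        gut_taxa=gut,
        seed=config.seed,
    )
    return counts_df, samples, truth


def _individual_clr(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean CLR abundance (generator-internal, for planting)."""
    cov = counts.sum(axis=1)
    rel = counts.div(cov, axis=0)
    keep = rel.columns[(rel > 0).any(axis=0)]
    clr = clr_transform(impute_min_fraction(rel[keep]))
    return clr.groupby(samples["individual_id"]).mean()


def simulate_glycome(config: SynthConfig, microbiome: pd.DataFrame,
                     samples: pd.DataFrame) -> pd.DataFrame:
    """Per-individual 39-peak composition (rows sum to 1) with planted effects."""
    rng = np.random.default_rng([config.seed, 1])
    peaks = [f"P{i + 1}" for i in range(config.n_peaks)]
    missing = [t for t, _, _ in config.planted_effects
               if t not in microbiome.columns]
    if missing:
        raise ValueError(f"planted taxon/taxa absent from count table: {missing}")
    individuals = sorted(samples["individual_id"].unique())
    n = len(individuals)

    # fixed chromatogram-like mean: a few dominant peaks, long tail
    x = np.arange(config.n_peaks)
    mu = (1.5 * np.exp(-0.5 * ((x - 3) / 2.0) ** 2)
          + 2.0 * np.exp(-0.5 * ((x - 14) / 3.0) ** 2)
          + 1.0 * np.exp(-0.5 * ((x - 27) / 4.0) ** 2) - 1.0)
    latent = mu[None, :] + rng.normal(0.0, config.glycome_noise_sd,
                                      size=(n, config.n_peaks))

    if config.planted_effects:
        ind_clr = _individual_clr(microbiome, samples).loc[individuals]
        for taxon, trait, beta in config.planted_effects:
            z = ind_clr[taxon]
            z = (z - z.mean()) / z.std(ddof=0)
            latent[:, peaks.index(trait)] += beta * z.to_numpy()

    comp = np.exp(latent - latent.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    return pd.DataFrame(comp, index=pd.Index(individuals, name="individual_id"),
                        columns=peaks)


def simulate_covariates_and_prs(config: SynthConfig, glycome: pd.DataFrame):
    """Covariates matching the emulated cohort's demographics, plus a PRS.

    Age ~ N(55.66, 13.05), BMI ~ N(26.37, 4.64), sex male with probability
    0.423, smoking with probability 0.232.  The PRS for the designated peak
    (``config.prs_trait``, default: the first planted trait or P5) is
    ``r * z + sqrt(1 - r^2) * noise`` where z is the standardized peak value.
    """
    rng = np.random.default_rng([config.seed, 2])
    individuals = glycome.index
    n = len(individuals)
    cov = pd.DataFrame(
        {
            "age": rng.normal(55.66, 13.05, size=n),
            "sex": (rng.random(n) < 0.423).astype(int),
            "bmi": rng.normal(26.37, 4.64, size=n),
            "smoking": (rng.random(n) < 0.232).astype(int),
        },
        index=individuals,
    )
    trait = config.prs_trait
    if trait is None:
        trait = config.planted_effects[0][1] if config.planted_effects else "P5"
    r = config.prs_r
    z = glycome[trait]
    z = ((z - z.mean()) / z.std(ddof=0)).to_numpy()
    noise = rng.standard_normal(n)
    prs = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
    prs_df = pd.DataFrame({f"PRS_{trait}": prs}, index=individuals)
    return cov, prs_df


def simulate_all(config: SynthConfig):
    """Full dataset: (counts, samples, glycome, covariates, prs, truth)."""
    counts, samples, truth = simulate_microbiome(config)
    glycome = simulate_glycome(config, counts, samples)
    covariates, prs = simulate_covariates_and_prs(config, glycome)
    return counts, samples, glycome, covariates, prs, truth


def write_dataset(outdir, config: SynthConfig) -> None:
    """Simulate and write the dataset as plain-text tables + truth YAML."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, samples, glycome, covariates, prs, truth = simulate_all(config)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    samples.to_csv(outdir / "samples.tsv", sep="\t")
    glycome.to_csv(outdir / "glycome.csv")
    covariates.to_csv(outdir / "covariates.csv")
    prs.to_csv(outdir / "prs.csv")
    (outdir / "allowlist.txt").write_text(
        "\n".join(truth.gut_taxa) + "\n")
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            dict(
                seed=truth.seed,
                contaminant_taxa={m: sorted(s)
                                  for m, s in truth.contaminant_taxa.items()},
                true_effects=[list(e) for e in truth.true_effects],
                gut_taxa=truth.gut_taxa,
                true_batch_offsets={r: truth.true_batch_offsets.loc[r].round(6)
                                    .to_dict()
                                    for r in truth.true_batch_offsets.index},
            ),
            fh, sort_keys=True)
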