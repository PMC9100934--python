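# Methods

This note documents the models implemented in `glycomicrobe`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Compositional framework

Both omics are compositions: only relative information is meaningful. All
inference runs on log-ratio coordinates (natural log everywhere):

- **CLR** `clr(x)_i = ln x_i − (1/D) Σ_j ln x_j`, mapping a D-part
  composition to a zero-sum vector (row sums are 0 to < 1e-12 before batch
  correction; deviations afterwards are exactly the removed batch terms).
- **Two-part ILR balance** `(1/√2)·ln(Σ numerator / Σ denominator)` — the
  orthonormal coordinate of a 1-vs-1 balance, used for ratio-type derived
  traits.
- **Zero imputation**: a zero cell is replaced by the part's minimum
  positive relative abundance over all samples, then rows are re-closed.
  The same rule is applied to glycan peaks (real peak areas are rarely zero,
  but the derived-trait transforms require strict positivity).
- **Beta diversity** is Euclidean distance on (batch-corrected) CLR
  coordinates, i.e. Aitchison distance.

## Contaminant screen

Per taxon, a linear model on CLR abundance with explanatory variables age,
sex, BMI, smoking, collection date (categorical), location, run × amplicon
nested in location, and (mean-centred) log coverage. Rule statistics:

- **R1** t-test of the coverage coefficient (flag when BH-adjusted p < 0.05
  and the coefficient is negative). A flag switches R1 to the marginal
  Spearman correlation with coverage instead; the model coefficient is the
  default because it conditions on the batch structure that itself
  correlates with coverage.
- **R2/R3** replicate consistency: Spearman correlation of CLR abundances
  across paired replicate libraries (same replicate group and amplicon),
  pooled over all pairs. Pooling was chosen over per-pair averaging for
  stability at 25 pairs; a flag exposes the alternative. Without replicates
  the rules are reported not-evaluable and never fire.
- **R4** F-test of the run term by full-vs-reduced model comparison,
  BH-adjusted across taxa.

BH correction is applied within each rule across taxa, never across rules.
"Not characteristic for human gut microbiota" is operationalized as absence
from a user-editable allowlist file of gut-resident genera; no authoritative
list is published, so the shipped file is a synthetic stand-in and rules
R3/R4 are reproducible in mechanism, not in membership. Negative-control
libraries are accepted in input and excluded from all fits. Filtering order
is fixed — contaminants, then coverage, then abundance — and is a fixed
point on its own output. The abundance rule reads "below 0.01% mean
abundance in *any* location–amplicon stratum" literally (`any`); a config
flag (`abundance_filter_mode: all`) gives the conservative alternative.

## Batch correction

Per taxon, a linear mixed model fitted by REML: fixed effects location,
amplicon, run × amplicon nested in location; random intercept for the
collection date. Corrected value = observed − fitted fixed terms − predicted
random intercept + grand mean, so between-individual biology stays in the
residual. When the random-effect variance hits the boundary or the fit does
not converge, the taxon falls back to OLS with collection date as a fixed
effect (logged; typically a handful of taxa per run). With the default
one-run-per-stratum design the fixed part removes run structure exactly;
the mixed model matters when runs are split within strata or dates carry
real technical drift.

## Derived glycan traits

The 39 → 36 harmonization map and the 81-definition registry are shipped as
CSV data files; the engine is purely definition-driven, so another panel
(e.g. a 24-peak IgG panel) is processed by supplying alternative files. The
shipped files are **synthetic stand-ins** (so labelled in their filenames):
they have the documented shape — 39 original peaks merging onto 36 GPs, 81
derived traits over three transform classes — and anchor PGP37
(FGS/(FG+FGS)), PGP43 (FG2S2/(FG2+FG2S1+FG2S2)), PGP62 (FA2[3]G1 within the
neutral subcomposition) and PGP109 (G3S2/G3S3) to their published
descriptions, but the remaining definitions are constructed from a plausible
structure annotation of the 36-peak panel, not transcribed from the original
supplementary table. Ratio-type descriptions of the form "FGS/(FG+FGS)" are
encoded as the disjoint balance FGS vs FG, which is monotone in the printed
percentage. Merged-group CLR uses the 36 harmonized GPs as the "other
traits". All derived traits are scale-invariant in the raw areas by
construction (total-area normalization first).

## Association engine

OLS of trait on one predictor plus covariates; genus abundances are
rank-inverse-normal transformed first (plotting positions `(r − a)/(n + 1 −
2a)`, `a = 3/8` for n ≤ 10 else `1/2`, ties share average ranks — the R
`qqnorm` convention). The trait is the response and the taxon the
predictor; sex and smoking are binary indicators, age and BMI enter
untransformed; missing data are handled by complete-case analysis. The
all-pairs scan residualizes traits and transformed abundances on the shared
covariates once (Frisch–Waugh–Lovell) and computes per-pair slope, SE and
t-test with the full-model degrees of freedom; the test suite asserts exact
agreement (1e-9) with per-pair OLS and with a normal-equations oracle.
Collinear designs and n ≤ p are rejected, naming the offending columns;
failed fits are errors, never silent drops.

Multiplicity: Galwey's effective number of tests per block — eigenvalues λ
of the block's pairwise-complete Pearson correlation matrix, negatives
clipped, `M_eff = ⌊(Σ√λ)²/Σλ⌋` (floored to an integer, matching the
reference implementation; a 1e-9 guard absorbs floating-point
7.999… artefacts) — multiplied across blocks, then Sidak
`1 − (1 − p)^M` computed via `expm1/log1p` so p-values of 1e-8 survive at
M ≈ 2,000. Sidak never exceeds the Bonferroni bound `min(1, M·p)`. Whether
the glycome block should use all 117 analysis-ready traits or a subset is
not settled; the default is all traits in the block.

The binomial enrichment test reports the exact one-sided tail
P(X ≥ k | N, α) for k of N nominal p-values below α. Its published value on
the real cohort is not reconstructible from the printed k and N alone, so
the implementation asserts only equivalence with an independent
cumulative-sum oracle.

**Mendelian randomization.** The PRS for a glycan trait acts as the genetic
instrument; the stage regresses quantile-normalized genus abundance on PRS
plus covariates and reports the slope. PRS construction itself (GWAS
summary statistics, LD matrices) is out of scope; values are consumed as
input.

## Permutation analyses

PERMANOVA (Anderson's pseudo-F via Gower centering), Mantel (Pearson on
off-diagonal entries, two-sided on |R|) and Procrustes (statistic
`√(1 − m²)`) all use explicit seeds and the `(1 + #extreme)/(1 + B)`
estimator, so the smallest achievable p at B = 9,999 is 1e-4. PERMANOVA
supports stratified permutation (used to test individual grouping within
location strata); the pipeline runs it on per-individual-per-location mean
profiles rather than all libraries to keep the permutation loop tractable.
How many PC axes enter Mantel/Procrustes is not prescribed; the default is
the first 10 of each omics, configurable. Ordinations are illustrative
(PCA/PCoA on Aitchison distance), not inferential.

## Synthetic-data generator

The generator emulates the study design: `n_individuals` (default 200) ×
3 locations × 3 amplicons, nine sequencing runs (one per location–amplicon
stratum; more via `n_runs`), 25 replicated individual–location combinations,
coverage uniform on 5,000–50,000 reads, 150 genera. Per-library genus
compositions are `softmax` of base + location + run-batch + date +
individual + library log-effects (sd 0.8 / 0.3 / `batch_effect_sd`=0.5 /
0.2 / 1.2 / 0.3); counts are multinomial at the library coverage, so row
sums equal coverage exactly. The three contaminant mechanisms are planted
disjointly — clean per-rule recall/precision comes at the cost of not
emulating real contaminants that mix behaviours. Batch offsets are drawn
per (run, taxon): a scalar shift shared by all taxa would be annihilated by
compositional closure and undetectable by construction.

The glycome is logistic-normal (not Dirichlet) so planted linear effects on
log-ratios are exact: `CLR(softmax(z)) = z − mean(z)`, hence a latent shift
of β × standardized taxon CLR appears on the analysis scale attenuated only
by the harmonized-panel mean term (≈ β·35/36 for a minor peak). Covariates
match the emulated cohort's demographics (age 55.66 ± 13.05,
BMI 26.37 ± 4.64, 42.3% male, 23.2% smokers); the PRS is
`r·z + √(1−r²)·noise` for a designated peak, r configurable (default 0.5).
The distribution of replicate counts per run is unknown in real data and is
left as a parameter.

Not emulated: read-level error, chimeras, taxonomy misassignment,
phylogenetic correlation among genera, covariate–microbiome confounding,
and glycome batch structure. Passing recovery tests therefore demonstrates
that the algorithms do what they claim under their own assumptions, not
that those assumptions hold in any particular real cohort.

All randomness flows through `numpy.random.default_rng` (PCG64) seeded from
the config, so fixed seeds give bit-identical outputs across platforms.

## Problem sizes used in the test and acceptance suites

Recovery suites run at the generator defaults (200 × 150, 20 seeds) for the
contaminant classifier; the null-uniformity scan uses 100 individuals × 40
taxa × 50 traits (2,000 pairs); planted-pair ranking uses 200 individuals ×
50 taxa × 117 traits over 20 seeds; CI coverage uses 100 seeds of n = 150
regressions at the engine level (the latent-scale planted β is not the
regression estimand, see the attenuation note above); batch-correction
recovery uses 80 × 40 with run offsets of sd 1.0. These sizes were chosen
as the smallest at which the binomial/Monte-Carlo bounds in the assertions
are meaningful.

## Known limitations

- The shipped registry/map/allowlist are constructed stand-ins; analyses of
  real cohorts should replace them with the cohort's own tables.
- The mixed model assumes Gaussian CLR residuals; heavy-tailed taxa fall
  back to OLS correction more often.
- MixedLM boundary fits make batch correction deterministic but only
  approximately order-invariant (1e-8 tolerance in tests).
- The MR stage is a single-instrument regression; it inherits all
  instrumental-variable assumptions (no pleiotropy, instrument relevance)
  and tests them nowhere.
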