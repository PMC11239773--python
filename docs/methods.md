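# Methods

This note documents the data-generating mechanism, the estimators, the
numerical conventions, and the design choices behind `crthte`. It states no
empirical results; all numbers quoted as defaults are inputs, and every
operating characteristic is computed at run time by the test suite or
`scripts/acceptance.py`.

## Data-generating mechanism

**Clusters.** `K` long-term care centers are split across two regions
(`region_split = 0.5` by default, so K/2 each) and are urban/suburban or
rural. In the base setting the urban composition is deterministic and
balanced: exactly `round(p_urban · K_r)` urban clusters per region
(`p_urban = 0.5`). The *urban-heterogeneity* extension instead draws each
cluster's urban flag independently as Bernoulli(`p_urban`), so arm-level
composition varies across replications. Every cluster has `n_staff = 100`
staff members.

**Individuals.** Each staff member carries a binary self-reported race
indicator. Base setting: i.i.d. Bernoulli(`p_race = 0.5`). The
*race-heterogeneity* extension draws a cluster-specific prevalence from a
Beta distribution parameterized by mean `p_race` and concentration
`beta_concentration = 10` (a+b), then draws individuals at that prevalence —
the standard beta-binomial over-dispersion device; concentration → ∞
recovers the base setting. The *baseline-boosted* extension flags each
individual independently with probability `baseline_boosted_fraction`;
flagged individuals have their outcome forced to 1.

Defaults and rationale: `p_race = 0.5` is symmetric, maximizes information
for the race-HTE contrast, and keeps the 0.5-threshold indicator encoding
non-degenerate (with 100 staff, cluster proportions straddle 0.5 with
probability ≈ 0.46 per cluster). The heterogeneity mechanisms and their
defaults are this package's own modeling choices for "composition varies
across clusters"; they are the natural over-dispersion devices but are not
uniquely determined by the problem statement, and results under the
extensions should be read as qualitative.

**Outcomes.** A linear probability model on the additive risk-difference
scale:

    p = β₀ + β_A·A + β_U·urban + β_Z·race + β_R·region
        + β_AU·A·urban + β_AZ·A·race,     Y ~ Bernoulli(p)

with β_A = 0.14 always, and β_U = 0.03, β_Z = 0.01, β_AU = 0.10,
β_AZ = 0.15 switched on per scenario. β₀ = 0.30 and β_R = 0 by default
(both configurable): the baseline probability is consistent with a trial
that enrolls centers with below-60% baseline uptake, and keeps every implied
probability inside [0, 1] for all nine scenarios (the maximum is
0.30 + 0.14 + 0.03 + 0.01 + 0.10 + 0.15 = 0.73). Construction of a
coefficient set validates the full binary covariate support and refuses any
combination whose implied probability leaves [0, 1].

**Scenarios.** Nine named scenarios toggle the four subgroup effects:

| scenario | urban main | race main | urban HTE | race HTE |
|---|---|---|---|---|
| 1 | – | – | – | – |
| 2 | ✓ | – | – | – |
| 3 | – | ✓ | – | – |
| 4 | ✓ | ✓ | – | – |
| 5 | ✓ | – | ✓ | – |
| 6 | – | ✓ | – | ✓ |
| 7 | ✓ | ✓ | ✓ | – |
| 8 | ✓ | ✓ | – | ✓ |
| 9 | ✓ | ✓ | ✓ | ✓ |

Scenario 1 is the all-null setting and scenario 6 the simplest setting with
HTE by race; an HTE flag is always paired with the corresponding main
effect, and single-effect scenarios precede combinations. The four flags
are also exposed directly (`ScenarioSpec(...)`) so any other combination can
be run as a custom scenario. Flags that are off force the corresponding
coefficients to exact zeros, so null hypotheses tested downstream are
exactly true in null scenarios.

## Constrained randomization

Within each region stratum, half the clusters go to the intervention arm
(odd strata assign the leftover cluster's arm by a fair coin). Candidate
allocations are scored by Σ over regions of |#urban in arm 1 − #urban in
arm 0|; the accepted set is every candidate achieving the minimum observed
score (default) or the best `q` fraction (`acceptance="quantile"`,
`q = 0.1`), and one accepted allocation is drawn uniformly after
de-duplication. When the total number of stratified allocations is at most
`n_candidates` (default 50,000) they are enumerated exhaustively; otherwise
candidates are sampled uniformly with replacement.

Numerical shortcut in the sampling path: the balance score depends on a
candidate only through each stratum's arm-1 urban count, whose sampling
distribution is hypergeometric. Scores for all candidates are therefore
drawn directly as hypergeometric variates, and full allocations are
materialized (uniformly, conditional on the counts) only for the accepted
candidates. This is distributionally identical to materializing every
candidate and is an order of magnitude faster.

The minimum-score acceptance rule reflects the base setting, where the
composition is balanced and exact balance (score 0) is always achievable;
under heterogeneous composition exact balance may be impossible and the
quantile rule is the natural alternative. Under balanced composition the
operating characteristics are insensitive to this choice, since both rules
accept essentially the same set.

## Estimation and inference

Sixteen analysis models (see the README table of ids). All include
intervention, urban status, and region (the randomization factors), in the
fixed column order: intercept, intervention, urban, region, [race
encoding], [intervention×urban], [intervention×race]; interaction columns
are products of the already-built main-effect columns. Individual-level
models use the raw binary race indicator; cluster-level models use either
the **mean-centered proportion** (centered at the unweighted per-dataset
mean over the K clusters, so coefficients are differences from the
study-mean composition) or the **indicator** that the proportion strictly
exceeds `t = 0.5` (a proportion exactly at the threshold counts as low —
attainable with 100 staff).

Fits are ordinary least squares. Inference uses the cluster-robust sandwich
covariance (X'X)⁻¹ [Σ_c X_c'r_c r_c'X_c] (X'X)⁻¹ — an independence working
structure; with one observation per cluster (all cluster-level models) this
is exactly HC0 — scaled by K/(K−2) because two variables are used in
constrained randomization. Wald statistics are estimate/SE with two-sided
standard-normal p-values (reject at α = 0.05); a t(K−2) reference is
available via `reference="t"` but the normal reference is the default and
the one used for all reported characteristics.

**Degenerate datasets.** A requested design column can be constant for a
particular simulated dataset (e.g. every cluster on the same side of the
0.5 threshold, or — at very small K — all urban clusters in one arm, making
the intervention×urban product constant). Such fits are refused, recorded,
excluded from that model's rejection-proportion denominator, and tallied in
`n_degenerate`; they do not abort the study. Tiny negative diagonal entries
of the sandwich (floating-point noise at near-singular small-K fits) are
clipped to zero, and a zero SE marks the coefficient as degenerate rather
than producing a spurious p-value.

## Study orchestration and reproducibility

A study is a grid of scenarios × K ∈ {30, 40, 80} × 1000 replications ×
model ids. Per-replication seeds derive deterministically from
(master_seed, scenario key, K, replication index) through a
`SeedSequence`, and each replication splits its seed into five explicit
child streams (clusters, individuals, baseline flags, randomization,
outcomes), so: any cell is reproducible in isolation; results are invariant
to the worker count (`n_jobs`); and changing one generation stage's draw
count cannot perturb the others. Child seeds use explicit spawn keys rather
than `SeedSequence.spawn()`, which mutates the parent and would tie results
to call history.

Operating characteristics per (scenario, K, model, coefficient): rejection
proportion with Monte-Carlo SE √(p̂(1−p̂)/n_eff), mean and SD of estimates,
and bias against the generating coefficient *where one exists*.
Cluster-level coefficients on aggregated race encodings have no generating
counterpart — the generating model is individual-level, and that mismatch is
precisely the ecological inference problem — so they are summarized by
mean/SD only.

## Problem sizes used by the shipped checks

The acceptance script runs 1000 replications per target cell at K = 80 with
100 staff per cluster — the study's full per-cell replication count. The
test suite runs its full-size cells (1000 replications) for the recovery,
type-I-error, and power-ordering checks, and small grids (K = 8–30, reduced
replications) for structural and determinism checks. Statistical test
tolerances are Monte-Carlo bands: 3 SEs for rejection proportions around
the nominal level and 4 SEs of the Monte-Carlo mean for estimate recovery.

## What the generator does and does not emulate

It emulates: two regions, balanced or heterogeneous urban composition,
binary race at configurable prevalence with optional between-cluster
over-dispersion, constrained randomization on region and urban status,
linear-probability outcomes, and baseline-boosted individuals. It does not
emulate: multiple follow-up timepoints, missing outcomes or survey
non-response, more than two race categories (the compositional-data
setting), unequal cluster sizes, or within-cluster outcome correlation
beyond what shared cluster covariates induce. Consequences: passing tests
show the estimators' behavior under clean conditions matching the generating
model; they do not certify performance under informative non-response,
compositional race encodings, or strong unmodeled intra-cluster correlation.

## Known limitations

- The linear probability model can, for other coefficient choices, imply
  probabilities outside [0, 1]; construction refuses such sets rather than
  truncating, so some extreme configurations are simply not simulable.
- The Wald test uses a normal reference; at K = 30 the cluster-robust
  variance is noisy and the K/(K−2) correction only partially compensates.
  The t(K−2) option exists for sensitivity analyses.
- The `race` / `trt_x_race` coefficient names are shared across levels for
  tidy summaries even though cluster-level encodings estimate different
  quantities; the `truth`/`bias` columns (NaN at the cluster level) carry
  the distinction.
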