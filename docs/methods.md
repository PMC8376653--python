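# Methods

This note documents the statistical model, the synthetic-data generator, the
estimation choices, and the limitations of `famcoaggr`.

## The design

The sibling-comparison design asks whether two disorders co-occur within
individuals because of shared genes, shared family environment, or
individual-specific factors. Full siblings share on average 50% of their
segregating genes; maternal half siblings share 25%; both are typically
reared together and are assumed to share family environment to the same
degree. A cross-disorder association that is stronger across full-sibling
pairs than across maternal half-sibling pairs therefore points at genetic
overlap.

Analysis proceeds in two arms:

* **Phenotypic arm** — logistic regressions of each physical condition on
  ADHD, within individuals and across sibling pairs, adjusted for sex and
  birth year, with a cluster-robust sandwich variance over family clusters.
* **Aetiological arm** — a bivariate liability-threshold ACE model that
  turns the 2×2 tables of the sibling pairs into liability correlations and
  decomposes the within-person cross-trait correlation.

## The bivariate liability-threshold ACE model

Each binary trait *t* ∈ {1, 2} reflects a latent standard-normal liability

    l_t = a_t·A_t + c_t·C_t + e_t·E_t,     a_t² + c_t² + e_t² = 1,

and the trait is present when `l_t > τ_t = Φ⁻¹(1 − prevalence_t)`. Across
siblings the A components correlate φ (0.5 full / 0.25 maternal half), C
correlates 1, E correlates 0. Across traits, the component pairs correlate
`rA, rC, rE` (correlated-factors parameterisation: loadings are kept
non-negative and signs live in the component correlations). The implied
liability correlations are

    cross-sibling, same trait:    φ·a_t² + c_t²
    within-person, cross trait:   r_ph = covA + covC + covE
    cross-sibling, cross trait:   φ·covA + covC

with `covA = a1·a2·rA`, `covC = c1·c2·rC`, `covE = e1·e2·rE`. The identity
`covA + covC + covE = r_ph` is exact by construction, so the reported shares
`covX / r_ph` always sum to one (they may individually be negative or exceed
one when contributions offset). With φ forced equal across groups the model
cannot separate A from C — only the aggregates `φa² + c²` and `φ·covA + covC`
are identified; the FS/HS contrast is the sole source of separation (a unit
test demonstrates the flat ridge).

## Estimation

**Tetrachoric correlations.** For each sibling group, four 2×2 tables are
formed from the double-entered pairs (same-trait cross-sibling for each
trait, within-person cross-trait over distinct members, and cross-sibling
cross-trait with the two symmetric orientations pooled). The tetrachoric
correlation of each table is the two-step MLE: thresholds fixed at the
marginal normal quantiles, then the bivariate-normal orthant-probability
multinomial likelihood maximised over ρ ∈ (−0.999, 0.999). The
bivariate-normal CDF is computed from Owen's T function
(`scipy.special.owens_t`), cross-checked in the tests against
`scipy.stats.multivariate_normal` and against a brute-force likelihood grid
at 1e-4 resolution. The SE comes from the numerical curvature of the profile
log-likelihood; threshold uncertainty is neglected, and the double-entered
tables are treated as multinomial (empirically this matches the sampling
spread at the rare margins used here to within a few percent; the bootstrap,
not these SEs, carries the final inference). A table with a zero cell is
re-fit with +0.5 added to every cell and flagged; a zero margin is an error.

**Structural fit.** The seven structural parameters `(a1, c1, a2, c2, rA,
rC, rE)` minimise the diagonally weighted least squares criterion
`Σ_k w_k (r̂_k − r_k(θ))²` over the eight observed correlations, `w_k =
1/se_k²`. `e_t` is computed as `√(1 − a_t² − c_t²)` with a smooth penalty
keeping `a_t² + c_t² ≤ 1`; loadings are box-constrained to [0, 1] and the
component correlations to [−1, 1]. Optimisation is bounded L-BFGS-B
(discrepancy tolerance 1e-9) from a closed-form Falconer-style start
(`a² ≈ 4(r_FS − r_HS)`, `c² ≈ 2·r_HS − r_FS`, clipped) plus eight random
starts from a fixed-seed generator. Thresholds are free per sibling group,
so prevalences may differ between full and half siblings; the within-person
cross-trait correlation is structurally shared across groups (only the
thresholds vary). A diagonal weight matrix was chosen over a full asymptotic
one for stability at desk scale.

**Covariates.** In the logistic arm, sex and birth year (continuous linear)
of both pair members enter directly. In the threshold model, covariates are
handled by stratifying tables (e.g. sex × birth decade), estimating the
tetrachoric per stratum and pooling by inverse variance
(`pooled_tetrachoric`); a full probit-threshold regression is a known
alternative not implemented here. The generator defaults to zero covariate
effects, so the unstratified path is the default.

**Inference.** Non-parametric bootstrap over family clusters: each replicate
resamples clusters with replacement to the original count, reassembles all
eight tables from precomputed per-cluster cell counts, re-estimates the
tetrachorics and refits the model; CIs are the 2.5/97.5 percentiles
(skew-allowing; the point estimate need not be bracketed). Replicate seeds
derive from the master seed by counter; failed replicates are counted and an
error is raised if they exceed a configurable ceiling (default 10%).

**FS vs HS odds-ratio contrast.** A two-sided Wald z on the log-OR
difference treating the two cohorts as independent, with Benjamini–Hochberg
control applied separately across the 35 conditions and the 8 disease groups
(mirroring how the two families are reported); the realized p-threshold (the
largest rejected raw p) is reported alongside the flags. CIs throughout use
the normal multiplier 1.959964, not t.

## The synthetic registry generator

`simulate_ace_families` draws, per family, family-shared and individual
component parts and mixes them as `√ρ·family + √(1−ρ)·individual` with
ρ = 0.5/0.25 for A (FS/HS), 1 for C, 0 for E, which reproduces the expected
sibling sharing exactly in O(n); the family and individual parts are drawn
jointly across traits at correlations `rA, rC, rE`. Defaults mirror the
study conditions: birth years 1932–1995, ADHD lifetime prevalence 1.29%, one
sibling pair per family (multi-sibling families supported for the cluster
bootstrap), no twins, no deaths. Present traits are emitted as outpatient
ICD-10 diagnosis records with integer ages placed (via age + birth year)
inside the 2001–2013 outpatient window, so phenotyping recovers the
simulated flags exactly; ADHD cases receive a diagnosis, a stimulant
prescription, or both (20% prescription-only, 30% both), exercising both
arms of the case definition. Covariate effects, when enabled, shift the
liability mean linearly (sex coded ±0.5; birth year per decade from the
range midpoint), which leaves the realized prevalence only approximately
equal to the nominal one.

What the generator does **not** emulate: assortative mating, dominance,
sibling interaction, diagnostic-practice drift over calendar time,
age-varying liability, register under-coverage, and within-person
comorbidity among the 35 conditions beyond the single simulated condition.
Passing tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to the ways real registers violate
them.

For odds-ratio recovery tests, `simulate_bernoulli_pairs` draws iid binary
pairs from the unique bivariate Bernoulli distribution with given margins
and odds ratio; the joint cell solves the quadratic
`(OR−1)p11² − [(OR−1)(p1+p2)+1]p11 + OR·p1·p2 = 0` on the Fréchet interval.

## Default parameter choices

| Parameter | Default | Why |
|---|---|---|
| ADHD prevalence | 1.29% | published lifetime adult register prevalence |
| Nervous-system group prevalence | 5.5% | not published; member conditions sum to ~6% with modest overlap assumed |
| Per-trait variance shares (recovery experiments) | A/C/E = 0.55/0.15/0.30 (ADHD), 0.35/0.15/0.50 (condition) | plausible for register sibling designs, and keeps the generating component correlations well inside their bounds — a recovery experiment with truth pinned to a parameterisation boundary measures clipping, not estimation |
| Recovery sample | 100,000 FS + 20,000 HS pairs, 50 replicates | desk-scale version of the published cohort's ~8:1 FS:HS ratio |
| Bootstrap replicates | 1000 (CLI default), reduced in tests | percentile CIs; reduced-rep nested simulations verify coverage |
| FDR level | 0.05 | standard; the realized threshold is reported like the study's 0.007 |

## Numerical choices

* Tetrachoric search confined to |ρ| ≤ 0.999; optimiser `minimize_scalar`
  (bounded, xatol 1e-8); profile-curvature SE with step 1e-4.
* `bvn_cdf` nudges exact-zero thresholds by 1e-12 (the Owen's-T formula is
  continuous there) and clips to [0, 1].
* Zero-cell continuity correction +0.5 per cell, flagged on the estimate.
* Degenerate inputs raise typed errors rather than returning NaN: zero-case
  outcomes, constant adjustment covariates, zero margins, missing latent
  draws, prevalences outside (0, 1), infeasible OR/margin combinations.
* Cluster ids are deterministic (components numbered by smallest member id);
  all tables are sorted on write, so fixed seed + config ⇒ byte-identical
  outputs.

## Statistical power at desk scale — an honest caveat

The A-vs-C separation rests entirely on the contrast between the FS and HS
cross-sibling cross-trait correlations. At register-realistic margins (ADHD
1.29%, condition ~5%), a 20,000-pair half-sibling group yields only ~30
doubly-affected cross-pairs, so that tetrachoric carries an SE near 0.036
and the per-replicate SD of the fitted genetic share of a 0.23 correlation
is ~0.5. Averaging 50 replicates still leaves an SE of ~7 percentage points
on the genetic share. This is an information limit of the design, not of the
implementation — the published analysis, with 23× more half-sibling pairs,
still reports a 95% CI spanning 7–49% for the genetic share of the
nervous-system correlation, which is the same noise scaled by √23. Users
decomposing modest correlations should read the bootstrap CIs, not the point
shares.

## Known limitations

* The shipped condition catalog is a provisional ICD-10 chapter-standard
  approximation; any serious analysis must supply its own curated code lists
  (the schema round-trips losslessly).
* The WLS weight matrix is diagonal; moment correlations are ignored in the
  fit (the cluster bootstrap restores valid inference).
* No dominance (ADE), sex-limitation, or >2-trait models; no paternal
  half-sibling analyses; no time-to-event phenotypes.
* Within-individual analyses cluster on the family cluster throughout
  (conservative); whether to cluster on individual instead is a judgment
  call the interface does not expose.
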