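# Methods

This note documents the statistical model behind each module, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices a maintainer should know about. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing (`tables`)

Counts are rarefied to a common depth by multivariate hypergeometric
subsampling (subsampling reads without replacement, the standard
rarefaction semantics, default depth 40,000); samples below the depth are
dropped with a warning. After closure to relative abundances, taxa are
filtered by two rules: mean relative abundance ≥ 0.1% and presence (a
strictly positive fraction) in at least ⌈1% · n⌉ samples. The abundance
screen is applied to the *mean* across samples; a max-based variant is
available via `abundance_stat="max"`. The default order is
rarefy → closure → filter; both steps are independent functions so the
order can be changed by the caller. Filtering re-closes the remaining
columns so the abundance-table invariant (rows sum to 1) always holds;
since re-closure only increases fractions, the filter is idempotent.

Residualization fits phenotype ~ intercept + sex + cage by OLS on the
indicator expansion, using a pseudo-inverse so rank-deficient designs (a
cage nested in a sex, singleton levels) are handled; a level observed once
absorbs its own residual to zero and is logged. Downstream modules operate
exclusively on the residual column.

Presence for the two-part features is defined once, on the filtered
(rarefied) table, as fraction > 0, and reused everywhere.

## Two-part association model (`twopart`)

Features per taxon: b = presence indicator; q = log relative abundance
standardized over present samples with the *population* SD convention
(ddof 0), set to 0 where absent. Taxa present in fewer than two samples,
or with zero log-variance, are degenerate and flagged.

The "binary" analysis is OLS of the residual phenotype on b with a
two-sided t-test on the slope. An OLS formulation (rather than a logistic
regression of b on the phenotype) was chosen because the additive
prediction model downstream needs β₁ on the phenotype scale; the two give
equivalent score tests under the null. The quantitative analysis restricts
to present samples (minimum 4, configurable) and regresses the residual on
q. The meta analysis is a Stouffer weighted-Z with weights √n of each
component (n for the binary part, n_present for the quantitative part);
z-scores are recovered from the component p-values so heavy-tailed t
statistics are combined on the normal scale. Inverse-variance weighting
would be an alternative; Stouffer was chosen for robustness to the very
different sample sizes of the two parts.

p_final = min of the defined component p-values. The minimum is
anti-conservative, so the scan permutes the residual phenotype B times
(default 1000), recomputes p_final per taxon under each permutation, and
reports p_perm = (1 + #{p_final,perm ≤ p_final,obs}) / (1 + B) — the +1
correction keeps p_perm ≥ 1/(B+1). The *same* permutations are reused for
every taxon, which makes the scan deterministic under a seed and preserves
the between-taxon dependence of the permutation null. Phenotype shuffling
(rather than per-taxon shuffling) was chosen because it preserves the
taxon–taxon correlation structure. BH FDR is applied across taxa to
p_perm; degenerate taxa are excluded from the family. `B=0` is a fast mode
that skips the correction (used inside cross-validation).

Because both regressions are OLS with intercepts, every reported p-value
is exactly invariant to affine transforms of the phenotype; rank-based
transforms of q are not applied by default since the permutation already
corrects residual skewness.

## Microbiability (`mve`)

Per repeat (default 100): an 80/20 random split; a two-part scan on the
discovery portion; at each threshold of the grid (10⁻⁵, 10⁻⁴, 10⁻³, 0.01,
0.05, 0.1) the taxa with discovery p ≤ threshold define

  r_m,i = Σⱼ (β₁ⱼ·b_ij + β₂ⱼ·q_ij)

on validation samples, with q standardized using the *discovery* per-taxon
log mean/SD (no leakage); taxa degenerate in discovery contribute zero.
R² is the squared Pearson correlation of r_m with the residual phenotype
on validation, defined as 0 when r_m is constant; repeats with empty
selections contribute R² = 0 rather than being dropped, so the mean
reflects predictive failure honestly. Selection uses p_final in fast mode
(B_inner = 0, the default) or the permutation-corrected p when
B_inner > 0. R² is measured against the residualized phenotype because
the association model operates on residuals.

Properties of this estimator worth knowing:

* It recovers a planted variance share only when that share is
  concentrated in individually discoverable taxa. Signal spread thinly
  below the detection threshold is invisible to a selection-based
  predictor, and each null taxon admitted at a permissive threshold
  contributes ≈ t²σ²/n_discovery of pure noise variance to r_m. The
  recovery experiments therefore use a focused panel (30 taxa, 5 causal,
  n = 500) where the planted 10% share is discoverable; with hundreds of
  candidate taxa the permissive-threshold estimate is diluted downward.
* Categorical covariates consume signal: with c cage levels,
  residualization removes an expected ≈ c/n of the microbial variance.
  The synthetic recovery cohorts keep ~20 cages (block size 25 at
  n = 500) in line with a realistic cage count, rather than letting the
  number of cage dummies grow with n.

## Co-abundance networks (`canet`)

SparCC estimates basis correlations from compositional counts. For each
pair, t_ij = var(log(x_i/x_j)) = ω_i + ω_j − 2·cov_ij is closure-free.
Assuming most covariances vanish, row sums of t give the linear system
diag(d) + A over included pairs for the basis variances ω, solved by least
squares; then ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)), clipped to [−1, 1].
The pair with the largest |ρ| above the exclusion threshold (0.1) is
iteratively removed from the system and ω re-solved, up to 10 exclusions.

Numerical safeguards (both matter in permutation nulls on small panels):

* a taxon may lose at most two partners to exclusion — the refinement is
  meant to remove a few genuinely correlated pairs, and unlimited
  per-taxon exclusions can erode a row sum until its ω collapses and the
  whole row saturates at |ρ| = 1;
* an ω that is non-positive or below 1% of the median ω marks that
  taxon's correlations as unidentifiable; they are reported as 0 rather
  than as saturated artifacts.

Zero handling: fractions are drawn from the per-sample Dirichlet posterior
with a unit prior (default; median over 20 draws), or fixed +1 pseudocount,
or plain closure (`pseudocount="none"`, requiring positive counts). Plain
closure is the only scheme exactly invariant to per-sample count rescaling
— posterior-based schemes are depth-aware by construction — and is what
the invariance tests use. Taxa with substantial zero fractions get large
negative log outliers under any pseudocount scheme, which strongly
attenuates their estimated correlations; planted-correlation experiments
therefore use fully (or nearly fully) prevalent taxa.

Pair significance: each taxon's counts are shuffled independently across
samples, ρ re-estimated, and the two-sided pseudo-p is
(1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm), BH-adjusted over the upper
triangle. Note the BH floor: with P candidate pairs and k floor-level
pairs, q_floor = P/(k·(n_perm+1)), so small panels and/or large n_perm are
needed for any edge to clear q < 0.05. Edges require |ρ| > 0.35 and
q < 0.05 by default (0.45 is the documented stricter alternative).

CAGs: Ward-linkage clustering of d = 1 − ρ (simple and monotone in ρ; the
√(2(1−ρ)) metric is available) cut into k groups (default 2), validated by
PERMANOVA on d with 999 label permutations and the +1-corrected p, so the
attainable floor is 1/1000. PERMANOVA is implemented here (pseudo-F from
sums of squared distances) for seedable determinism; the test suite
cross-checks the statistic against scikit-bio and an exhaustive label
enumeration. CAG–phenotype association is the Spearman correlation of each
CAG's summed member fractions with the residual phenotype, BH-corrected
across CAGs.

## Group contrasts (`groupstats`)

High/low groups are the top and bottom n (default 5) samples by phenotype,
ties at a boundary broken deterministically by sample id. Wilcoxon
rank-sum uses the exact null distribution for combined n ≤ 20 without ties
(the normal approximation is poor at 5v5) and the tie-corrected normal
approximation otherwise. The SCFA contrast is the classical equal-variance
two-sample t-test (Welch available), BH over the three analytes. Feature–
SCFA correlations use average-rank Spearman with exact enumeration
p-values for n ≤ 9 without ties and the t-approximation otherwise; BH runs
jointly over all feature × analyte pairs. FDR families are scoped per
operation call; correction of the species–SCFA family is applied by
default.

## Synthetic cohorts (`syndata`)

The generator emulates the study design: ~105 animals (near-balanced
sexes), cages as small blocks (default 5 — the real design housed one
animal per cage, which confounds cage with individual and makes
residualization inestimable, so blocks are a deliberate divergence),
library sizes Poisson around 40,000, finishing weight in grams around an
intercept of 2,500.

Counts: per-taxon Gaussian log means (SD 1.5 across taxa) and unit log SD
define a latent log-normal basis; designated pairs are correlated through
a Gaussian copula (the pair matrix is checked for positive definiteness —
an inconsistent set of pairs is an invalid-config error). Structural
presence uses exact per-taxon presence counts drawn inside the configured
prevalence range, so realized structural prevalences provably fall in the
range. Presence counts are assigned to taxa by abundance rank
(abundance–occupancy coupling: dominant taxa ubiquitous, rare taxa patchy,
as in real communities; disable with `abundance_prevalence_coupling=False`)
— this also keeps each sample's log-total stable, limiting spurious
closure-induced associations. Masked basis values are closed to
compositions and reads drawn multinomially, so zeros arise both
structurally and from undersampling.

Phenotype: y = intercept + sex effect + cage effect + c·Σ(β₁b + β₂q) + ε
with Gaussian ε. Effects are expressed in phenotype units (the test
scenarios set them in units of the residual noise SD, which is 1 there).
Causal taxa default to a draw among taxa of intermediate prevalence
(0.25–0.9), because an effect planted on a nearly ubiquitous taxon
degenerates to abundance-only and on a nearly absent taxon to
presence-only. When `target_microbial_variance_fraction` is set, c is
computed from the realized component variances, so the in-sample variance
share matches the target exactly. The true causal set, scaled effects, and
realized share are returned (and written as a JSON sidecar) for test
assertions. The phenotype noise is Gaussian; no claim is made of matching
any real herd's weight distribution.

SCFAs: butyrate is log-normal with log-mean shifted by the standardized
summed relative abundance of designated producer taxa (slope sign = sign
of the configured effect); acetate and propionate are independent
log-normal noise at typical fecal concentrations (~30 and ~6 mM).

What the generator does not emulate: sequencing-read artifacts (chimeras,
taxonomy errors), overdispersion beyond multinomial sampling, taxon
phylogeny, and functional profiles. Passing tests on these cohorts show
the estimators are correct under the stated generative model, not that
real data meet its assumptions.

Known limitation — compositional leakage: when planted effects are strong,
non-causal taxa are genuinely (weakly) associated with the phenotype
through the closure constraint (all fractions share the −log(total) term),
so the false-discovery rate measured among non-planted taxa is an upper
bound on the scan's intrinsic error; it is typically 1–3% at the scales
used here but can exceed 5% in cohorts where a single dominant taxon's
fluctuations propagate through closure.

## Problem sizes in the shipped experiments

Calibration: three null cohorts of 200 taxa × 300 samples, B = 1000.
Power: three cohorts with 5 planted taxa (β₁ = β₂ = 1.5 noise-SD) among
200, n = 300. Microbiability: three cohorts of 30 taxa, 5 causal, 10%
planted share, n = 500, 60 CV repeats, fast mode. SparCC: 50 fully
prevalent taxa, n = 500. CAG: two 10-taxa blocks (within-ρ 0.7, between-ρ
−0.3) among 30 taxa, n = 300. Pipeline demo: 120 taxa, n = 105, B = 1000,
4999 edge permutations. Pooling three cohorts per experiment reduces the
Monte-Carlo error of the reported rates.
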