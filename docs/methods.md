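# Methods

This note documents the models, estimators, numerical choices and known
limitations of `osmophylo`, in the order the pipeline runs them.

## Trait derivation from exposure experiments

**Inputs.** Per-individual records (species, population, medium osmolality
in mOsm/kg H2O, day-5 survival, day-5 hemolymph osmolality for survivors)
and per-level mortality counts. Practical salinity converts to osmolality
at 30 mOsm/kg H2O per permil.

**Lethal limits (LL50 / UL50).** Mortality probability is modeled as
Φ(β0 + β1·x) on the *linear* osmolality scale and fitted by binomial
maximum likelihood (IRLS via a probit GLM, with a Nelder–Mead fallback on
the raw likelihood when IRLS fails, e.g. under separation); the limit is
−β0/β1. A full salinity series is U-shaped in mortality, so before
fitting, the table is split at the plateau of minimal mortality: the
lower-limit fit uses levels from the dilute extreme through the plateau,
the upper-limit fit from the plateau upward. The linear scale is used
because dilute-side limits approach 0 mOsm, where a log scale is
undefined. If no mortality occurred on a flank the limit is *censored*:
no point estimate, bounded by the extreme tested level. Censored lower
limits propagate as missing values so the phylogenetic imputation stage
can fill them. No control-mortality (Abbott) correction is applied;
day-5 control mortality is assumed zero.

**Response curve and derived osmolalities.** Hemolymph osmolality of
survivors is regressed on medium osmolality with an ordinary
least-squares cubic, requiring ≥ 5 distinct surviving levels (positive
residual df); R² is reported. The isosmotic point is the root of
f(x) − x inside the fitted range, found in closed form (cubic roots);
with several interior roots the one nearest the mean observed medium is
taken and all candidates logged. Osm_LL50 and Osm_UL50 evaluate the curve
at the lethal limits; evaluation slightly beyond the last surviving level
is permitted with a warning, since UL50 typically exceeds it. The
species-level "hemolymph osmolality" trait is the curve evaluated at the
habitat osmolality — consistent with its meaning as hemolymph at ambient
salinity (the source tables do not state their computation).

**Indices and aggregation.** RC_Hyper and RC_Hypo apply the formulas in
the README at full precision; rounding to 2 decimals happens only at the
reporting layer. Species values are unweighted means across populations
with SE = sd/√n (population sample sizes vary, and no weighting rule is
documented for the reference data); populations with censored LL50 are
excluded from the LL50/RC_Hyper aggregation with a logged count. A
species whose every population fails derivation raises by default; the
pipeline instead drops it (as real analyses drop species without usable
data).

## Tree structures

Trees are rooted, with non-negative branch lengths in arbitrary
(e.g. genetic-divergence) units; ultrametricity is *not* assumed, and
polytomies are allowed. Newick I/O and pruning use dendropy; internally
trees are preorder parent/branch-length arrays. The Brownian covariance
is C[i,j] = depth of the MRCA of tips i,j; patristic distance follows as
d(i,j) = C[i,i] + C[j,j] − 2C[i,j]. The OU covariance uses the
*stationary* form V[i,j] = σ²/(2α)·exp(−α·d(i,j)), the appropriate
kernel on a non-ultrametric tree; for α below 1e−9 it falls back to
σ²·C for continuity at the drift limit.

## Phylogenetic correlograms

Tip pairs are split into k = 4 patristic-distance classes (equal-frequency
quantile bins by default; equal-width optional; a distance tied with a
boundary joins the lower class). Moran's I with binary weights is
computed per class; the null expectation is −1/(n−1). Significance comes
from random tip relabeling (999 permutations by default, seeded): the
two-tailed p is rank-based, (r+1)/(n_perm+1), counting permuted
|I − E[I]| at least as extreme as observed. Permutation rather than the
analytic normal approximation was chosen because species tables are small
(~24) and the weights binary. The permutation loop is vectorized over
permutations; calibration on i.i.d. traits attains nominal 5% type-I
error (tested).

## PGLS with simultaneous OU α

For each candidate α the residual correlation is exp(−α·d_ij); the scale
is profiled analytically (σ̂² = r'V⁻¹r/n) and β̂ is the GLS estimate. α̂
maximizes the profile log-likelihood over a log-spaced grid
(10⁻⁴…10² in units of 1/tree-height) plus the α = 0 Brownian endpoint,
refined by bounded scalar optimization between the best grid point's
neighbors; boundary solutions are flagged. A user-supplied grid is
honored verbatim, which also serves to pin α. The slope test is a Wald F
with (1, n−2) df using the unbiased scale r'V⁻¹r/(n−2); this convention
is reported as such and no attempt is made to mimic nonstandard df
subscripts seen in some published tables. Simulation at 100 tips with a
true slope of 0.30 and OU(α = 2) residuals recovers the slope with
|bias| ≤ 0.03 and 93% CI coverage (acceptance suite).

## Ancestral states under BM

Each internal node's state is the GLS root estimate of the tree re-rooted
at that node, computed without tree surgery via the re-rooted covariance
C_v[i,j] = (d(i,v) + d(j,v) − d(i,j))/2. The BM rate σ̂² is the ML
estimate at the original root; CI95 = estimate ± 1.96·√(σ̂²/(1'C⁻¹1)).
Singular covariances from zero-length branches are jittered
(ε = 1e−8·max C) with a warning. Estimates are invariant to tip order
and to global branch-length rescaling (tested); they match physical
re-rooting and the standard R implementation of the method (tested).

## OU imputation of missing values

A univariate stationary OU model is fitted to the observed tips by ML
(θ and the scale profiled analytically, α by bounded search on log α ∈
[log 1e−4/h, log 1e3/h]); each missing tip is then the conditional mean
of the joint normal given the observed tips, with the conditional SD
reported. If the ML solution degenerates toward α = 0 the imputation
falls back to the BM conditional expectation with a warning. Imputation
is univariate: only single-trait gaps (censored lower limits) occur in
the intended inputs; a multivariate extension is out of scope.

## Multi-optimum OU (Hansen) models and regime search

A *painting* assigns every branch a selective regime via regime origins:
a regime starts on the branch above its origin node and is inherited
until overridden. Within a trait, all regimes share α and σ²; only the
optimum θ differs (the standard restriction). Expected tip values are
W(α)·θ where W accumulates exp(−α·(T_i − t)) increments over each branch
segment of the root-to-tip path plus a root term exp(−α·T_i) credited to
the root regime (the root state is drawn from the root regime's
stationary distribution); rows of W sum to 1. Residuals follow the
stationary OU covariance. Per trait, θ is solved by GLS and the scale
profiled, with α maximized on a fixed log-spaced grid (15 points,
10^−2.5…10^1.7 per tree height); per-trait parameters count k = 2 + #regimes.
Traits are treated as independent given the shared painting, so per-trait
AICs (partial AICs) sum to the model total. AICc is available by flag
(2k(k+1)/(n−k−1) added per trait) and is the pipeline default — see
"Design choices" below.

The forward search starts from one regime and, each round, tries every
branch not already originating a regime as a new origin, accepting the
single best summed-AIC improvement; every improvement is accepted
(threshold zero) and ties break toward the earliest branch in preorder,
making the search deterministic. The optional backward phase greedily
merges regime pairs into shared (convergent) regimes while the criterion
improves. Searches share per-α Cholesky factors and per-α trait
projections across candidates, so candidate evaluation is a small GLS.

**Known limitation — spurious regime additions.** With the likelihood
refit per candidate, the best spurious candidate's gain on single-regime
data behaves like the maximum of ~2·#branches correlated χ²-type
statistics (measured 8–14 per trait at 64 tips), which exceeds the AIC
penalty of 2 (and the AICc penalty at moderate n) essentially always.
Threshold-zero stepwise AIC therefore tends to add one or more regimes
beyond the truth, and on null data does not reliably stop at one regime —
a documented property of this method family, not of this implementation
(the acceptance suite records the honest rates). Residual cross-trait
correlation compounds this, because the independent-traits
pseudo-likelihood counts correlated evidence multiply. Mitigations
provided: AICc, the `max_regimes` cap, and the backward collapse phase.

## Synthetic data

Generators are seed-deterministic and always emit their ground truth.

*Exposure experiments*: survival is binomial with probit dose-response on
each flank; survivors' hemolymph follows a double-logistic blend between
a hyper-regulated plateau (dilute media) and a hypo-regulated plateau
(concentrated media), constrained to cross the isosmotic line at the true
IC — deliberately *not* a cubic, so the downstream cubic fit is a genuine
approximation (the fitted crossing carries a few-percent systematic bias,
visible in the tests' tolerances). Measurement-plus-individual scatter is
heteroskedastic: the SD ramps from `noise_sd` (default 40 mOsm) at the IC
to (1 + 10)×`noise_sd` at the upper lethal limit, emulating the breakdown
of regulation near lethal concentrations; the ramp factor is calibrated
so cubic fits attain R² ≈ 0.6–0.85, the range reported for real salinity
series. The default design is 14 media from distilled water to 3540
mOsm/kg H2O, dense below 1500 (as real salinity ladders are), with 4
crabs per level and 2 populations per species.

*Trees and traits*: Yule trees with exponential waiting times; BM by
branchwise Gaussian increments; OU by exact per-branch transitions
honoring the painting, root drawn from the root regime's stationary
distribution. The simulators and the analytic covariance / Hansen-mean
formulas are mutually consistent (Monte-Carlo moment tests) — the central
internal-validity property of the package.

*Full studies* (`gen_study`): six latent physiological axes (isosmotic
point, lower and upper tolerance spans, habitat salinity, and two
regulation-capability axes setting the hemolymph plateaus) evolve under
the painted OU model with unit stationary variance; regime shifts are
`effect_size` (default 4) stationary SDs on the shifted axes. Shift
strengths differ by axis — regulation capability shifts strongly between
regimes, isosmotic point / lower span / habitat moderately, and the upper
tolerance span not at all — mirroring the per-trait contributions
reported for the emulated study system. Latent-to-physiology maps are
smooth (logistic spans rather than hard clips) and calibrated to the
published species table's ranges (IC ≈ 580–1080, IC−LL50 ≈ 600–1000,
UL50−IC ≈ 270–2450 mOsm/kg H2O). The default painting is a root regime,
a clade-level shift on the clade nearest one third of the tips, and a
tip-level shift on the longest terminal branch inside that clade (a shift
must have been expressed to be observable). What the generator does *not*
emulate: temporal day-1–5 dynamics, sex/size covariates, spatial
population structure, and trait-specific measurement error models —
passing tests show estimator correctness under the stated model, not
robustness to these.

## Pipeline

Stages run in order (derive → validate/prune → impute → correlogram →
PGLS → ancestral states → regimes), each reading the previous stage's
serialized artifact, so any stage is re-runnable in isolation. The PGLS
stage tests hemolymph~habitat, IC~habitat, RC_Hypo~RC_Hyper and each
index~habitat. JSON artifacts are written with sorted keys and fixed
rounding; identical config+seed gives byte-identical outputs (timestamps
live only in the manifest). Significance defaults to 0.05.

## Design choices where the design was open

- **AIC vs AICc**: the regimes-module API defaults to plain AIC with
  AICc by flag; the *pipeline* defaults to AICc plus a `max_regimes = 8`
  cap because its target is small species tables (n ≈ 24), where the
  small-sample correction is material and threshold-zero stepwise AIC is
  degenerate (see the limitation above). Both criteria are always
  reportable.
- **Curve fitting mode**: per-population curves, then aggregation
  (pooling individuals across populations is available by passing pooled
  records); SEs of derived quantities are computed across populations,
  not by error propagation.
- **Distance classes** use patristic distances (node-count distances are
  not offered; patristic is the natural metric on a branch-length tree).
- **Trait standardization**: the multi-trait regime search z-scores
  traits by default so each contributes on a comparable scale; this is an
  affine per-trait change and does not affect which painting wins for a
  single trait.
- **Root state** in Hansen fits is stationary at the root regime's
  optimum; a root-state-free parameterization is out of scope.
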