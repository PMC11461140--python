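# Methods

This note documents the statistical models implemented in `phyloallom`,
the estimation choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the problem sizes
used by the test suite and acceptance script.

## Tree handling and the phylogenetic covariance

A rooted tree with branch lengths defines the matrix C with
C_ij = shared root-to-MRCA path length of tips i and j and C_ii = the
root-to-tip distance — the covariance of a unit-rate Brownian motion
along the tree. C is assembled as B·diag(b)·Bᵀ from the tip×edge
incidence matrix, one BLAS product even for thousands of tips.

Pruning collapses unary nodes with branch lengths summed and keeps any
chain above the new root as a root stem edge, so root-to-tip distances of
retained tips are preserved exactly and `vcv∘prune = subset∘vcv` holds to
rounding. Tip labels are normalised by trimming and treating runs of
spaces/underscores as equal (case preserved), because trait tables and
Newick files habitually disagree on the separator. Non-ultrametric trees
are accepted; nothing downstream requires ultrametricity.

Pagel's transform C(λ) multiplies off-diagonals by λ and keeps the
diagonal. λ is deliberately *not* restricted to [0, 1] at this level:
small-sample fits can push the optimum outside the unit interval, and the
transform is well defined as long as C(λ) stays positive definite.
Outside that region the code flags/warns rather than errors, because the
matrix is still printable and comparable even when unusable for fitting.

## PGLS with Pagel's λ

Model: y = Xβ + ε, X = [1, x], ε ~ N(0, σ²·C(λ)). Writing D = diag(C)
and C* = D^(-1/2) C D^(-1/2) with eigendecomposition C* = U S Uᵀ,

    C(λ) = D^(1/2) U diag(1 + λ(sᵢ − 1)) Uᵀ D^(1/2),

so after one symmetric eigendecomposition every λ evaluation is a
diagonally weighted least squares problem (O(n²) instead of O(n³)). The
positive-definite λ interval is read off the spectrum:
(−1/(s_max − 1), 1/(1 − s_min)).

* **Criterion.** REML by default (ML by switch). The REML profile
  log-likelihood includes the log|XᵀC(λ)⁻¹X| term; σ² is profiled with
  divisor n − 2.
* **Optimiser.** The profile is evaluated on a deterministic 81-point
  grid over the user bounds (default [−2, 2]) intersected with the PD
  interval, then refined by bounded scalar maximisation between the
  neighbours of the best grid point. This is deterministic given the
  data, robust to the multimodality occasionally seen in λ profiles, and
  subsumes multi-start local optimisation. User bounds are widened (up to
  three doublings) when the optimum presses against them with room left
  inside the PD interval; a persistent boundary optimum is flagged on the
  fit, not raised.
* **Uncertainty.** Coefficient CIs and p-values are t-based with
  df = n − 2 (the residual df of a two-parameter model). The λ interval
  is a Wald interval from the numerically differentiated curvature of the
  profile (central second difference, h = 10⁻⁴·max(1, |λ̂|)); when the
  curvature is non-negative (flat or irregular profile) the interval is
  reported as NaN rather than invented.
* **Degenerate inputs.** On a star phylogeny the profile is flat in λ;
  the fit fixes λ = 0 by convention, flags it `unidentifiable`, and then
  coincides exactly with OLS. Non-PD λ regions evaluate to a −10³⁰⁰
  sentinel so the optimiser simply avoids them.

Invariances checked by the test suite: with C = I the fit equals OLS to
1e−8 (coefficients, SEs, p-values, against statsmodels as an independent
oracle); rescaling all branch lengths changes σ² but not b̂, λ̂, or
p-values; the profile optimum dominates λ ∈ {0, ½, 1}.

## Scaling-exponent tests

Categories map to expected exponents via: production rate → m, biological
time → 1 − m, biological rate → m − 1, biomass product → m + (1 − m) = 1.
m = 0.88 (amphibian metabolic scaling) and m = ¾ (Kleiber) are the
defaults; both are configurable. A model *supports* an expectation iff
its slope differs significantly from zero (two-sided, α = 0.05) and the
expected exponent lies inside the 95% CI, endpoints inclusive — the
published wording ("within the interval") does not specify strictness,
and the inclusive reading is the weaker, safer one.

Two fitted models are compared parameter-wise by CI overlap: parameters
significantly non-zero in both fits are "different" iff their 95% CIs
share no point (touching endpoints count as overlap). This
disjoint-interval operationalisation of the published comparison method
is an interpretation; the source describes the procedure only by citation.

The published per-trait summaries are shipped as TSVs exactly as printed.
Two cells print internal inconsistencies across tables (an incubation-time
CI bound differing by 0.01, and a salamander age-at-maturity CI upper
bound of 0.13 vs 0.10 — the latter flips the MDH verdict at expected
0.12); each file carries what its own table prints, and the replay of the
support table uses that table's values. Slope-CI lower bounds printed as
"< 0.01" are stored as the string and parsed as the bound; they enter no
computed count.

## Phylogenetic PCA

The evolutionary covariance is R = (X − 1aᵀ)ᵀ C(λ)⁻¹ (X − 1aᵀ)/(n − 1)
with a the GLS (phylogenetic) mean. λ is estimated by maximising the
multivariate Brownian profile likelihood (R profiled at its ML value),
constrained to [0, λ_max] with λ_max the positive-definiteness limit —
unlike PGLS, because reference pPCA implementations constrain λ and the
quantity feeds a correlation matrix, not a significance test. In `corr`
mode R is standardised to a correlation matrix (standardisation by the
GLS variances, not by ordinary column z-scores; a pre-standardisation
flag exists for the alternative reading) and scores are the centred,
GLS-variance-scaled raw data projected on the eigenvectors — not
C⁻¹-whitened — matching the reference tool's output convention.
Eigenvector signs are fixed so each component's largest-magnitude loading
is positive, making results deterministic across linear-algebra backends.
Axis retention uses the Kaiser–Guttman rule with strict inequality
against the mean eigenvalue (so a flat spectrum retains nothing).

## Simulation-null ANOVA/MANOVA

The observed statistic is the classical one-way F (or Wilks'
Λ = det(W)/det(W + B)). The null distribution comes from `nsim` (default
1000) Brownian datasets simulated on the tree at the REML rate (or
evolutionary rate matrix) estimated from the observed data on the
untransformed λ = 1 tree — the simulation null must match the observed
scale, and F/Λ are scale-free, so this choice only matters through the
tree structure itself. Group labels stay fixed; only trait values are
re-simulated. p = (1 + #{at least as extreme})/(nsim + 1) (for F, extreme
means ≥ observed; for Wilks, ≤), never exactly zero. Results are
deterministic given the seed. On a star tree the simulated null
reproduces the classical F-test p-value to Monte-Carlo error.

## Synthetic data

The generator mirrors the structure of a large amphibian life-history
compilation, and its defaults are the study conditions, not tuning knobs:

* **Tree.** Yule (pure-birth) process conditioned on the tip count,
  default 2069 tips — the study's species count; all tips extant, hence
  ultrametric.
* **Mass.** log10 body mass evolves by Brownian motion from a root of
  1.0 (10 g) with tip standard deviation 0.7, spanning roughly three
  orders of magnitude as amphibian masses do.
* **Traits.** Each of the 16 traits is its published all-amphibian
  allometry (slope, intercept, λ) plus a BM-with-λ residual with tip sd
  0.25 — a residual scatter typical of log-log life-history regressions;
  the study does not print residual sds, so this value was chosen once on
  that reasoning. Per-trait Bernoulli retention reproduces the published
  per-trait sample sizes (n = 22 up to 1860 of 2069); a clade-blocked
  missingness option exists to probe taxonomically biased sampling.
* **Fast–slow set.** Five traits from two latent phylogenetic factors
  (λ = 0.8): a pace factor loading positively on all five (0.9 on mass,
  0.7 on the two timing traits, 0.45 on the two fecundity traits) and a
  trade-off factor loading +0.6/−0.6 on egg volume/clutch size, plus iid
  noise (sd 0.25). Default 263 species, the study's complete-case subset.

What the generator does *not* emulate: measurement error and
within-species variation collapse into the single residual; missingness
is (optionally clade-) random rather than driven by research effort;
trait residuals are mutually independent given mass, whereas real
fecundity traits are partly derived from one another; the tree is Yule
rather than a dated supertree. Passing tests therefore demonstrate that
the estimators recover known structure under the model's own
assumptions — not that the published biological estimates are correct.

## Problem sizes and runtime

The test suite and acceptance script use: slope/λ/coverage recovery at
n = 200 tips × 100 replicates (coverage asserted in [0.90, 0.99], λ RMSE
< 0.1); fast–slow structure recovery at n = 263 × 100 replicates (≥ 90
with single-sign PC1 and egg/clutch opposition on PC2); ANOVA type-I
calibration with 300 replicates of nsim = 200 on a 50-tip tree (rate
asserted in [0.03, 0.07]); and a full 2069-tip, 16-trait end-to-end run
executed twice under one seed and compared byte-for-byte. The
eigendecomposition-based λ machinery keeps the full pipeline under a
minute on one CPU.

## Known limitations

* The λ Wald interval understates uncertainty when the profile is
  strongly asymmetric (common at small n); a profile-likelihood interval
  would be better and is not implemented.
* `gls_estimate`'s generic path is O(n³) per call; the fast eigen-path is
  used by `fit_pgls` only.
* MANOVA simulation loops in Python over `nsim` (a p×p determinant per
  draw); fine at nsim = 1000, slow if pushed far beyond.
* The length-to-mass conversion applies user-supplied power laws; no
  published coefficient sets are bundled (the example config ships
  placeholder values only).
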