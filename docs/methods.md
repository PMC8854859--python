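# Methods

`rrsemen` implements a random-regression (RR) animal model for
longitudinal boar semen traits — semen volume (VOL, ml), sperm motility
(MOT, %), sperm concentration (CON, 10^8/ml) and abnormal sperm
percentage (ABN, %) — recorded repeatedly over a boar's reproductive
life (ages 33–150 weeks, collection intervals of 1–30 days).

## Model

For a record of boar *k* taken at age *t* within AI-center×year×month
class *i* and collection-interval class *j*:

    y_ijkt = AIYS_i + Interval_j + Σ_l φ_l(w_t) β_l
           + Σ_l φ_l(w_t) a_kl + Σ_l φ_l(w_t) pe_kl + e_ijkt

where `w_t = −1 + 2(t − a_min)/(a_max − a_min)` is the standardized age
and `φ_l(w) = sqrt((2l+1)/2) P_l(w)` the normalized Legendre basis
(orthonormal on [−1, 1]). In matrix form `y = X1 b1 + X2 b2 + Z1 a +
Z2 p + e` with

    var(a) = K_a ⊗ A,   var(p) = K_p ⊗ I,   var(e) = I σ_e².

`A` is the pedigree numerator relationship matrix; `K_a` and `K_p` are
the (L_A+1)² and (L_P+1)² coefficient covariance matrices. A model is
labelled `L(a, b, c)` by the polynomial degrees of the fixed, additive
and permanent-environment (PE) regressions; degree *k* means basis
functions φ₀..φ_k. Traits are analyzed univariately. The residual
variance is homogeneous across ages. There is no explicit overall mean:
φ₀ (a constant) serves as the intercept, and one reference level per
class factor is dropped, so the fixed-effect block is full rank.

Derived quantities: σ_a²(t) = φ(t)'K_a φ(t), σ_pe²(t) = φ(t)'K_p φ(t),
h²(t) = σ_a²/(σ_a²+σ_pe²+σ_e²), repeatability(t) =
(σ_a²+σ_pe²)/(σ_a²+σ_pe²+σ_e²), between-age genetic correlation
r(t₁,t₂) = φ(t₁)'K_aφ(t₂)/√(σ_a²(t₁)σ_a²(t₂)), and the population mean
curve V(t) = φ(t)'β. The heritability/repeatability formulas are the
standard RR definitions with homogeneous σ_e². Default reporting grids:
weekly ages 36–136 for trajectories and {33, 42, …, 150} (9-week steps)
for correlation surfaces.

## Quality control

Five criteria, applied in a fixed order: (e) per-trait range filters
(VOL 100–600 ml, MOT 10–100 %, CON 0.1–8 ×10^8/ml, ABN 0.01–100 %,
closed intervals); (a) age window 33–150 weeks; (b) removal of records
with an undefined or out-of-range (1–30 d) collection interval — each
boar's chronologically first record has an undefined interval and is
removed here; (c) boars with fewer than 6 remaining ejaculates dropped;
(d) fixed-effect levels (AIYS, interval class) with fewer than 10
records dropped; (c)/(d) alternate until a fixed point. A removed row
is attributed to the first criterion that removed it (a convention —
rows removable by several criteria exist). Range filters run first
because they are record-local; the count criteria depend on survivors.
Intervals are *not* recomputed after rows are removed: a collection
interval is a property of the physical collection sequence. Traits are
filtered independently (a row failing only the MOT range still enters a
VOL analysis), because traits are modelled separately. QC is idempotent
and monotone in its bounds; both properties are tested.

## Pedigree

`A` is built by the tabular method; inbreeding coefficients F come from
the Meuwissen–Luo L-vector recursion; the sparse `A⁻¹` is assembled by
Henderson's rules with Mendelian-sampling variances
d_i = 1 − 0.25(1+F_s) − 0.25(1+F_d) (terms present per known parent).
Unknown parents are unrelated, non-inbred founders; there are no
genetic groups. Inbreeding is included in `A⁻¹` by default (a flag
disables it). log|A| = Σ log d_i is carried alongside for the
likelihood.

## REML

The restricted log-likelihood is evaluated through the mixed-model
equations with the PE and residual terms absorbed boar-by-boar into
block-diagonal covariances `R_b = Φ_b K_p Φ_b' + I σ_e²` (Φ_b = the
boar's PE covariate rows). The working system then contains only the
fixed effects and the additive coefficient block, with
`G⁻¹ = A⁻¹ ⊗ K_a⁻¹` added coefficient-blockwise; this is algebraically
identical to the full Henderson system (a test verifies agreement with
a dense multivariate-normal evaluation to 1e−6) while keeping the dense
factorization at p + m·(L_A+1) equations.

Three estimation methods are provided:

* **lbfgs** (default): quasi-Newton ascent on the Cholesky factors of
  (K_a, K_p) and log σ_e², using exact analytic REML gradients mapped
  by dL/dL_chol = 2 (dL/dK) L. The Cholesky scale makes the PSD cone
  unconstrained. This is the default because the likelihood surface of
  covariance-function models has long ridges (additive and PE
  components of the same basis function are separated only by
  relative-pair covariances) on which raw average-information updates
  were observed to oscillate or crawl.
* **ai**: damped average-information steps (AI = ½F'PF from the working
  variates F_k = V_k Py) with Levenberg–Marquardt damping escalated
  until the likelihood does not decrease, and EM fallback.
* **em**: pure EM. Monotone by construction
  (asserted per-step in the tests within 1e−10):
  K_a ← (S_a + T_a)/m with S_a = Ã'A⁻¹Ã and T_a the A⁻¹-weighted
  posterior-covariance blocks; analogous updates for K_p and σ_e².

Defaults: convergence |Δ log L| < 1e−8, 200 iterations, diagonal start
(K_a at 10 %, K_p at 20 %, σ_e² at 70 % of the OLS residual variance).
Covariance matrices are kept positive definite by clipping eigenvalues
at 1e−8 of the trace; clipping active at convergence raises a boundary
warning. Gradients were verified against finite differences and the AI
matrix against its dense definition on small instances.

## Model selection

BIC = −2 log L + P log n (natural log, n = records in the analyzed
dataset). Two parameter-count conventions are carried: the reporting
convention P = a + b + c − 2 for `L(a,b,c)` (used by published RR rank
tables of this kind, and the default for ranking and report parity) and
the conventional count (L_A+1)(L_A+2)/2 + (L_P+1)(L_P+2)/2 + 1 of free
covariance parameters, always reported alongside since the reporting
convention undercounts. Grid search fits every cell, warm-starting each
model from a neighboring smaller model's estimates (new orders padded
with a moderate diagonal — exactly zero is a saddle point of the
Cholesky parameterization). Ties break toward fewer parameters, then
lexicographically. Individual fit failures are recorded and ranked
last.

## Synthetic data

The generator emulates the structure of multi-center AI studbook data:
a three-generation random-mating pedigree (founder sires/dams,
generation-1 males and females, generation-2 males; record boars are
the generation-1 and 2 males, so sire–offspring pairs both carry
records); per-boar collection histories with entry age, record count
and i.i.d. intervals from a truncated shifted negative binomial on
1–30 d (mode ≈ 5 d; a geometric was considered but its mode is its
minimum, which is not what collection schedules look like); AIYS
effects drawn once per simulated center×year×month level; a
collection-interval effect profile rising over 1–9 d and declining
thereafter; and trait values composed exactly per the model with
additive coefficients propagated down the pedigree (parent average +
Mendelian term with variance d_i K_a) and i.i.d. PE coefficients.

Default truth is on the semen-volume scale: mean curve ≈ 240–260 ml
rising to a plateau near 80 weeks (β = (350, 25, −10)), K_a =
[[1600, 200], [200, 150]] giving σ_a²(t) ≈ 680–1370, K_p =
diag(1200, 350, 120) giving σ_pe²(t) ≈ 680–1430, σ_e² = 4000 — hence
h² ≈ 0.11–0.22 and repeatability ≈ 0.3–0.5 across the age range, the
magnitudes typical for this trait. Truth columns (`truth_*`) ride along
in the in-memory table for test assertions and are stripped from
written pipeline inputs.

What the generator does not emulate: measurement-method changes over
calendar time, culling/selection (records are missing at random),
heterogeneous residual variance, seasonality beyond the random AIYS
effects, and real interval/AIYS distributions (unpublished); passing
tests therefore demonstrate correctness of the machinery under the
model, not robustness to these real-data features.

## Validation experiment sizes

Chosen by power analysis before measuring outcomes, and fixed:

* *Trajectory recovery*: 500 record boars — 25 recorded founder sires
  plus three recorded descendant generations (158 + 158 + 159 males),
  so nearly every boar has a recorded sire (~475 parent–offspring
  record pairs), with full-brother litters and 15–25 records per boar
  at ~2-week intervals; default truth; the generating model is fitted
  to the generated records directly (range-truncating QC would censor
  trait tails and bias the components downward). The additive/PE
  separation is information-limited at this population size: with an
  h² ≈ 0.2 truth the attainable relative standard error of σ_a²(t) is
  on the order of 0.15–0.2 (parent–offspring record pairs carry an
  intercept correlation of only ≈ 0.24), so heritability trajectories
  are recovered much more precisely than the additive-variance
  trajectory itself. The corresponding test reports both error
  measures.
* *Order recovery*: the PE order is identifiable only from within-boar
  age span (a quadratic is locally linear over a short history), and
  the additive order only from relative pairs. The experiment therefore
  uses 240 record boars with long histories (entry 33–40 wk, 40–65
  records at ~2-week intervals, spanning most of the age window, as the
  study population's long-lived boars do), 20 paternal half-sib
  families, ~120 sire–offspring record pairs, and generating
  covariances with pronounced higher-order components
  (K_a = [[1600, 250], [250, 1200]], K_p = diag(1200, 250, 500)).
* *Null calibration*: with no genetic signal the additive variance
  estimate concentrates near zero only when enough relative pairs
  exist; the experiment uses 400 record boars in 15 large half-sib
  families.

## Known limitations

* The fixed-effect block is required to be full rank after
  reference-level dropping; confounded class factors (e.g. interval
  class a deterministic function of month) raise an error rather than
  being absorbed by a generalized inverse.
* Heavy grids at degree 8 on study-scale data are outside the intended
  desk scale of this implementation; the engine is dense after
  absorption and scales with (animals × (L_A+1))³ per iteration.
* Standard errors are provided for fixed-effect contrasts only, not for
  variance components or heritability curves.
* Age standardization defaults to the 33–150-week design window;
  evaluating the basis outside the fitted window raises an error by
  default because polynomial extrapolation at extreme ages is
  unreliable.
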