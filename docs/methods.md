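# Methods

This note documents the models implemented in `hydroniche`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## 1. Isotope conventions

All isotope values are δ notation in ‰ against VSMOW:
δ = (R_sample/R_standard − 1) × 1000. The ×1000 factor is always applied,
so stored and reported values are on the familiar per-mil scale.
Deuterium excess is d = δD − 8·δ¹⁸O; points on the global meteoric water
line (δD = 8·δ¹⁸O + 10) have d = 10 ‰ exactly. The local meteoric water
line is fitted by ordinary least squares of δD on δ¹⁸O — not
reduced-major-axis — because an OLS slope below 8 is the quantity
interpreted as sub-cloud evaporation in this literature, and R² then
equals the squared Pearson correlation (asserted in tests by computing
both ways). Fits require ≥ 3 samples with non-zero δ¹⁸O variance.

Soil depth intervals are half-open `[top, bottom)` cm. Nine intervals
are sampled (0–5, 5–10, 10–20, 20–40, 40–60, 60–80, 80–100, 100–120,
120–150); the eight shallowest serve as mixing sources by default. The
deepest interval is generated but excluded from the source set, matching
the eight-source configuration of the emulated analysis; the scheme is a
plain list of (top, bottom) pairs and can be overridden. Layer SDs use
the n−1 denominator; a single-replicate layer reports SD 0 with a
data-quality warning instead of failing, because the mixing model floors
source SDs anyway.

## 2. Bayesian mixing model

The mixing model apportions a xylem-water signature among K soil-layer
sources on the simplex. Assumptions, chosen to mirror the standard
configuration for root-water-uptake studies:

* **Zero discrimination.** Root water uptake does not fractionate, so
  the mixture mean is Σ_k p_k μ_jk with μ the source mean signatures.
* **Residual-only error.** All mismatch is absorbed by per-isotope
  residual SDs σ_j with half-normal priors; source variances are *not*
  propagated into the likelihood. This matches the "residual error"
  setting of the common tooling and is a deliberate fidelity choice, not
  an oversight; it makes source SDs diagnostic only (SD floor 0.1 ‰
  guards collinearity warnings, not the likelihood).
* **Dirichlet(α = 1) prior** on proportions — the conventional
  "uninformative" choice. Its consequences are real and documented
  below (shrinkage toward 1/K).
* Multiple replicates of one mixture are i.i.d. observations (three
  stems per species in the emulated design).

Sampling: random-walk Metropolis on additive-log-ratio coordinates
z = log(p_k/p_K) plus log σ_j, proposing all coordinates jointly. The
ALR Jacobian is ∏_k p_k, giving the convenient α·Σ log p_k prior term.
Step sizes adapt per chain during burn-in (×1.2 above 40 % acceptance,
×0.8 below 20 %, in blocks of 200). Defaults: 3 chains × 20 000
iterations, 10 000 burn-in, thin 10 (3 000 retained draws); the
pipeline's `reduced()` plan (8 000/4 000/thin 4) is used where dozens of
runs are composed. Convergence is monitored with rank-normalized
split-R̂ (arviz); exceeding 1.05 warns rather than fails, since the
short-plan warnings are expected and harmless for posterior means.
Correctness is pinned by two oracle tests: a prior-predictive run must
reproduce Dirichlet moments, and a two-source problem must match a dense
grid evaluation of prior × likelihood within total-variation 0.05.

Aggregation to depth groups (0–20 / 20–40 / 40–100 / 100–120 cm) sums
member-layer proportions *per draw*, preserving posterior correlations.

**Known behaviour, not a defect:** with eight sources whose δ²H and δ¹⁸O
are nearly collinear (both derive from the same evaporation-line
structure), three replicates supply roughly two linear constraints on a
seven-dimensional simplex. The posterior is then a prior-weighted
average over a polytope slice, and group means shrink toward the prior
(37.5 % for three-layer groups, 12.5 % for single layers). In the
recovery experiments this appears as a −2 to −6 point bias for the
single-layer 20–40 cm block (truth 19.8 %, typical posterior mean ≈ 14 %)
while three-layer blocks recover within a few points. Any mixing tool
with this prior and data volume behaves the same way; credible intervals
remain honest (empirical coverage near nominal in
`recovery_experiment`).

## 3. Herb-to-shrub ratio and classification

C_h and C_s are species-averaged posterior-mean contributions of the
herb shallow block (0–20 cm) and shrub deep block (40–100 cm); the ratio
R_h/s = C_h/C_s is dimensionless and scale-invariant. Class boundaries:
stable below 0.9, semi-stable on the **closed** interval [0.9, 1.4],
unstable above 1.4. The closed convention was chosen because the upper
boundary is treated as a critical (bifurcation) state rather than an
unstable one; both thresholds are exposed as arguments. Ratios are kept
at full precision internally and rounded only in report tables.

The restoration-age trend is a Pearson correlation with a two-sided
t-test over dated sites only — the natural-vegetation control has no
restoration age and is excluded from all trend statistics (it keeps a
synthetic ordering age, maximum + 1, purely for sorting). Niche overlap
is the proportional similarity index Σ_k min(p_k, q_k). ANOVA/Tukey are
thin wrappers over scipy and statsmodels, present for pipeline parity
and cross-checked against textbook arithmetic in tests.

## 4. Shrub–herb dynamics

The coupled model and its stability analysis are implemented exactly as
printed in the source formulation, including its rough edges:

* ∅(R) = exp(−k·max(R − R₀, 0)) is continuous with a kink at R₀; the
  analytic Jacobian uses the right-hand derivative there, and
  finite-difference validation excludes a 10⁻³ neighbourhood of the
  kink.
* The printed Jacobian entries (J11 = r_s∅ − r_sR∂∅ − u_s,
  J12 = r_s∂∅, J21 = −r_hR²∂φ, J22 = r_hφ + r_hR∂φ − u_h) follow from
  the chain rule only when k_h = k_s; that is the default, and the
  printed form refuses k_h ≠ k_s. A general form carrying the k_h/k_s
  factors is available and reduces to the printed form when they match.
  Either way the matrix depends on the state only through R, so per-site
  evaluation "at equilibrium with the site's R imposed" is well defined.
* The equilibrium expressions W_s* = r_s∅/u_s, W_h* = r_hφ/u_h are rate
  ratios, not biomasses with consistent units; they are evaluated
  verbatim and the inconsistency is documented rather than repaired.
* Eigenvalues come from λ = tr/2 ± √((tr/2)² − det) with complex square
  root, checked against a generic eigensolver to 10⁻⁹. Regimes use a
  zero tolerance of 0.02 on max Re(λ) (stable / marginal / unstable);
  0.02 was chosen so that a dominant real part of about ±0.01 — the
  magnitude reported for the critical site — classifies as marginal.
* R₀ = 0.9 and Rc = 1.4 by default, identifying the modulation
  breakpoints with the empirical ratio thresholds; the source
  formulation never states them.
* Integration is classical fixed-step RK4 (default step 0.01). The test
  suite exploits a structural property as a strong oracle: with
  k_h = k_s the ratio obeys its own autonomous equation
  dR/dt = R[(r_hφ − u_h) − (r_s∅ − u_s)], which simulated trajectories
  must satisfy pointwise.

**Attainability of the reported regime pattern.** Under the printed
model, J11 = r_s∅(1 + kR) − u_s is positive at small R (∅ = 1 gives
r_s − u_s > 0 for the default rates) and decays toward −u_s at large R,
so the dominant real part *decreases* with R. The reported pattern —
stable at low ratios, unstable above 1.4 — has the opposite sign
structure and cannot be produced by any choice of (R₀, Rc, k, b) with
the stated rates. `calibrate_regimes` performs a deterministic grid
search (misclassification count, margin tie-break) and reports this
explicitly: the best achievable pattern reproduces the six
stable sites and the critical site but leaves the two high-ratio sites
marginal instead of unstable. The reported per-site eigenvalue
magnitudes are therefore treated as non-reproducible, and validation of
this module rests on the structural oracles above (finite-difference
Jacobian, eigensolver agreement, ratio closure) instead.

## 5. Synthetic generator: what it emulates and what it does not

Defaults encode the emulated study conditions:

* **Precipitation:** 26 events, δ¹⁸O ~ U(−15, 5) ‰ (the reported range;
  no distribution is reported, uniform is the least-informed choice),
  δD on the line 7.8·δ¹⁸O + 12.2 plus Gaussian noise. The noise SD
  (≈ 8.83 ‰) is derived in closed form from
  R² = s²v/(s²v + σ²) with v = 400/12, so the *expected* fit statistics
  match the reported slope/intercept/R² — it is a derived quantity, not
  a reported one.
* **Soil profiles:** layer-mean δD = deep + (surface − deep)·e^(−d/λ)
  at interval midpoints, three replicates per layer (SD 2 ‰ δD), δ¹⁸O
  tied to δD by a soil evaporation line (slope 5.5, intercept −20 ‰ —
  typical arid-zone values, configurable) plus 0.4 ‰ noise. Site
  parameters follow the reported profile descriptions: natural site
  −75 → −110 ‰ (≈ 30 ‰ contrast), old stands −85 → −105 ‰ with a gentler
  e-folding (60 cm), younger stands −70 → −112 ‰ (λ = 40 cm).
* **Xylem:** per species, expected isotopes are the proportion-weighted
  means of the *summarized* sources (so recovery is well posed), plus
  residuals of 1.5/0.3 ‰. Within-layer and xylem SDs are plausible
  placeholders — the emulated study reports none — and are flagged as
  such in the settings docstring.
* **True proportions:** the group's main depth block (shrub 40–100,
  semi-shrub 20–40, herb 0–20 cm) carries the site target mass split
  equally over block layers; the remainder decays geometrically (ratio
  0.5) with layer distance from the block. Only main-block totals are
  reported in the emulated analysis; the decay scheme is the package's
  documented choice.
* **Chronosequence:** the two oldest stands carry their reported deep
  shares (55.6, 57.6 %); the six younger stands follow a saturating age
  curve with fixed site scatter solved once so that the true-mean age
  correlation is r = 0.862, the reported value. The correlation is a
  property of the deterministic site constants, hence identical across
  seeds. Herb shallow means are set so the expected site ratio
  reproduces the reported per-site ratio sequence. Semi-shrubs occur in
  the four youngest stands and the natural site, reflecting their
  decline during succession.

What passing the synthetic suite shows: the estimators recover what was
injected, at the noise levels and sample sizes stated, with calibrated
uncertainty. What it does not show: robustness to features of real
field data absent from the generator — seasonal source dynamics,
groundwater access, species-level rooting differences within a group,
spatially correlated soil moisture, fractionation during cryogenic
extraction, or non-Gaussian measurement error.

## 6. Reproducibility and problem sizes

Every random stream descends from one integer seed through
`numpy.random.SeedSequence` spawn keys fixed per stage (precipitation 0,
soil 1, xylem 2, MCMC 3, recovery 4, pipeline mixing 5), so whole-run
determinism and stage-wise re-runs coincide. Problem sizes in the
shipped analyses were chosen to keep a full desk run in minutes: the
meteoric-line experiment uses 200 repeats of n = 26; mixing recoveries
average 8 generated datasets at the reduced chain plan; the trend check
generates 50 chronosequences; property oracles use 300–1 000 random
draws. All were picked as comfortable Monte-Carlo sizes for the
quantities' tolerances.
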