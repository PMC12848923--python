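# hydroniche

Water-source partitioning and stability analysis for dryland revegetation
chronosequences, built around dual stable isotopes of water (δ²H, δ¹⁸O).

In arid shrub-planting systems, deep-rooted shrubs, semi-shrubs and
shallow-rooted herbs coexist by drawing soil water from different depths.
`hydroniche` is for ecohydrologists who want to quantify that vertical
niche partitioning from isotope data and turn it into a stability
diagnostic:

1. **Isotope core** — δ-notation arithmetic, deuterium excess
   (d = δD − 8·δ¹⁸O), and OLS fitting of the local meteoric water line
   (LMWL) from precipitation samples.
2. **Bayesian mixing model** — a from-scratch MCMC implementation of the
   standard stable-isotope mixing setup for root water uptake: for
   mixture replicate *i* and isotope *j*,

   ```
   x_ij ~ Normal( Σ_k p_k μ_jk , σ_j² ),    p ~ Dirichlet(α),
   ```

   with zero discrimination at uptake and a "residual" error structure
   (σ_j estimated, source variances not propagated). Sampling is
   random-walk Metropolis on additive-log-ratio coordinates with
   multiple chains, burn-in step adaptation and split-R̂ diagnostics;
   layer proportions are aggregated to depth groups (0–20, 20–40,
   40–100, 100–120 cm) after sampling.
3. **Herb-to-shrub ratio** — the site statistic R_h/s = C_h / C_s,
   where C_h is the mean herbaceous contribution from 0–20 cm and C_s
   the mean shrub contribution from 40–100 cm, classified as stable
   (R < 0.9), semi-stable (0.9 ≤ R ≤ 1.4) or unstable (R > 1.4);
   plus restoration-age trends (Pearson), proportional-similarity niche
   overlap, and one-way ANOVA with Tukey HSD.
4. **Shrub–herb dynamics** — the coupled biomass model
   dW_s/dt = r_s ∅(R) W_s − u_s W_s, dW_h/dt = r_h φ(R) W_h − u_h W_h
   with ∅(R) = exp(−k·max(R − R₀, 0)) and φ(R) = 2/(1 + e^{b(R−Rc)}),
   analytic Jacobian, trace/determinant eigenvalues, per-site regime
   classification, bifurcation scan and a regime-pattern calibration
   routine.
5. **Synthetic data** — a seeded generator that emulates the study
   conditions (26 precipitation events on the LMWL δD = 7.8·δ¹⁸O + 12.2
   with R² = 0.963; exponentially depth-depleted soil profiles; xylem
   mixtures with group-specific true proportions that strengthen with
   stand age), with a truth table for exact recovery scoring.

No public dataset accompanies the study design this emulates, so every
analysis here runs against the synthetic generator or against user CSVs
in the documented sample schema.

## Worked example

```python
import warnings
from hydroniche import (
    GeneratorSettings, MixingConfig, default_chronosequence,
    fit_meteoric_line, summarize_sources, run_mixing, aggregate_layers,
    summarize, herb_shrub_ratio, classify_stability, site_stability,
)
from hydroniche.synthetic import (
    generate_precipitation, generate_soil_profile, generate_xylem,
)
from hydroniche.isotopes import DEFAULT_DEPTH_GROUPS

settings = GeneratorSettings(seed=42)

# 1. local meteoric water line from synthetic event precipitation
fit = fit_meteoric_line(generate_precipitation(settings))
print(f"LMWL: dD = {fit.slope:.2f} d18O + {fit.intercept:.2f}  "
      f"(R2 = {fit.r_squared:.3f}, n = {fit.n})")

# 2. mix shrub xylem water over 8 soil-layer sources at the natural site
ck = default_chronosequence()[-1]
sources = summarize_sources(generate_soil_profile(ck, settings))
xylem, truth = generate_xylem(ck, "shrub", sources, settings)
post = run_mixing(xylem, sources, MixingConfig(seed=1))
table = summarize(aggregate_layers(post, DEFAULT_DEPTH_GROUPS))
print(table.round(1).to_string(index=False))

# 3. stability ratio and dynamical regime
r = herb_shrub_ratio(36.7, 26.3)
print(f"R_h/s = {r:.2f} -> {classify_stability(round(r, 1))}")
res = site_stability(1.61)
print(f"R = 1.61: max Re(lambda) = {res.max_re:.3f} -> {res.regime}")
```

Output:

```
LMWL: dD = 7.81 d18O + 13.00  (R2 = 0.976, n = 26)
    source  mean_pct  sd_pct  ci_low_pct  ci_high_pct
   0-20 cm      15.0     4.7         5.2         23.4
  20-40 cm       9.9     8.0         0.6         29.9
 40-100 cm      48.3    17.1        14.4         77.2
100-120 cm      26.9    15.3         3.2         56.5
R_h/s = 1.40 -> semi-stable
R = 1.61: max Re(lambda) = 0.011 -> marginal
```

Reading it: the single-seed meteoric line scatters around the regional
slope 7.8 and intercept 12.2; the shrub posterior puts its largest mass
on the 40–100 cm group (the injected truth for this site is 52.3 %),
with a wide credible interval because only three stems of each species
are observed; the warning pair C_h = 36.7 %, C_s = 26.3 % lands exactly
on the critical ratio 1.4; and the dynamical model's dominant eigenvalue
at the highest observed site ratio sits at the margin of instability.

## Command line

```bash
hydroniche generate --seed 0 --outdir data        # synthetic dataset + truth
hydroniche mixing --sources soil.csv --mixture xylem.csv
hydroniche partition --contributions contributions.csv
hydroniche dynamics                                # regime table + bifurcation scan
hydroniche all --seed 0 --outdir run               # full pipeline
```

## Layout

```
src/hydroniche/
  isotopes.py    δ arithmetic, d-excess, LMWL, source summaries
  synthetic.py   seeded chronosequence generator + truth tables
  mixing.py      Bayesian mixing model (ALR Metropolis, R-hat, aggregation)
  partition.py   R_h/s, classification, trends, overlap, ANOVA/Tukey
  dynamics.py    biomass ODE, Jacobian, eigenvalues, bifurcation, calibration
  pipeline.py    end-to-end orchestration, validation, manifests
  cli.py         click command line
docs/methods.md  model assumptions, defaults, numerical choices, limitations
```
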