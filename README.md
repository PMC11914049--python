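# reefkit

Statistics for long-term benthic cover surveys on artificial and natural reef
substrates: harbor breakwaters, wave-dissipating blocks, and artificial tide
pools colonized by hard corals.

Decades-long monitoring programs of this kind leave behind messy,
semi-quantitative records — per-taxon percent cover written as numbers,
ranges ("20–30"), or the symbols "R" (rare, < 1%) and "+" (1–5%), with blank
cells meaning *no survey* rather than zero — collected by different methods
at different sites and depths, before and after mass-bleaching disturbance.
`reefkit` turns such tables into effect-size inferences and community
trajectories, and adds a carbonate-budget view of tide-pool ecosystems.

## What it computes

**Record resolution.** Ranges resolve to their midpoint; in the total-cover
column "R" → 0.5% and "+" → 3.0%; per-taxon symbols are resolved jointly by
the R-unit allocation rule ("+" counts as six Rs; the gap between the
recorded total and the numerically recorded taxa is split evenly over the
units, and symbols get 0 when the gap is not positive).

**Compositional transforms.** Covers of the 7 taxon groups (*Acropora*,
*Pocillopora*, *Montipora*, *Porites*, Faviidae, *Millepora*, other hard
corals) plus the coral-free base form a closed composition. Zeros are
replaced multiplicatively by 0.0025 (half the 0.5% recording resolution);
analyses run on the additive log-ratio alr(x_j) = ln(x_j / x_other), and
community distances use the robust Aitchison metric (Euclidean distance on
row-centered log ratios).

**Hierarchical Bayesian effect sizes.** For alr cover y (normal, identity
link) on the harbor design:

    y_i = b1 + b2 f_substrate + b3 X_depth + b4 X_year
        + b5 f_substrate*X_depth + b6 f_substrate*X_year
        + r_site[site(i)] + r_method[method(i)] + e_i

with 11 site and 5 method random intercepts; the block design drops the
random effects and uses a surface-processing indicator, with colony counts
modelled as Gamma(mean mu, variance eps^2) under a log link. Covariates are
standardized by (x − mean)/(2 SD), priors are Uniform(±10) (cover) /
Uniform(±20) (counts) on coefficients and Half-Cauchy(1e-2) on scales, and
sampling is five independent No-U-Turn runs of 1000 tuning + 2000 retained
draws (10,000 pooled). An effect is *credible* when its 80% highest-density
interval excludes zero; convergence is the classical Gelman-Rubin statistic
across the five runs, and fit is Bayesian R².

**Ordination and permutation tests.** nMDS (Kruskal stress-1) on robust
Aitchison distances with environmental vector overlays, plus multi-factor
PERMANOVA with sequential sums of squares (substrate, year, depth and
interactions) and Bonferroni-corrected pairwise tests.

**Response curves.** Thin-plate regression spline smooths of alr cover
against depth, slope or light, penalty chosen by GCV, back-transformed to
percent cover (normalized to 100%, values under 0.25% reported as 0).

**Net ecosystem calcification.** In a stagnant tide pool,
NEC = −½ · (ΔTA/Δt) · Z̄ · ρ_water (mmol CaCO₃ m⁻² h⁻¹) from the
least-squares TA slope over short sampling windows; NEC is regressed against
photon flux (tanh or linear, AICc-selected) and integrated over a 24-h light
curve with a delta-method SD.

Every stage has a seeded synthetic-data generator with a machine-readable
truth sidecar, so calibration and parameter recovery are testable end to end.

## Worked example

Simulate the block-survey design (processed vs unprocessed block faces,
three depths, 18 quadrats per year over 18 years) and fit the cover model
under the full five-run protocol:

```python
from reefkit.hbm import ModelSpec, fit_hbm
from reefkit.synthetic_data import BlockSimConfig, simulate_block_survey

frame, truth = simulate_block_survey(BlockSimConfig(seed=7))
fit = fit_hbm(ModelSpec("eq2_block_cover"), frame, "alr_cover", seed=1)
print(fit.table[["median", "hdi80_low", "hdi80_high", "rhat", "credible"]].round(3))
```

```
                          median  hdi80_low  hdi80_high  rhat           credible
parameter
intercept                 -1.060     -1.093      -1.027   1.0  credible_negative
surface_processing         0.555      0.489       0.618   1.0  credible_positive
depth                     -0.484     -0.550      -0.418   1.0  credible_negative
years                      0.966      0.899       1.031   1.0  credible_positive
surface_processing:depth  -0.028     -0.168       0.093   1.0       not_credible
surface_processing:years   0.264      0.135       0.401   1.0  credible_positive
eps2                       0.460      0.435       0.482   1.0
```

The generating effect sizes were (−1.0, 0.6, −0.5, 0.9, 0.0, 0.3): every
median sits near its truth, the two real interactions are classified
credible while the null one is not, all Gelman-Rubin values round to 1.00,
and the Bayesian R² is 0.64 (95% HDI 0.59–0.69) against a residual SD of
0.5 used in the simulation.

The same workflow is scriptable from the shell:

```sh
reefkit simulate --kind survey --seed 3 --outdir out
reefkit resolve out/survey.csv --outdir out
reefkit ordinate out/resolved.csv --outdir out --perms 999
reefkit nec out/tidepool.csv --outdir out
```

Each stage writes a manifest (inputs, digests, seed, outputs) so a run can
be reproduced exactly.

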