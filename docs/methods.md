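# Methods

This note documents the models, parameter choices and numerical decisions
behind `rankcast`, and what the synthetic-data tests do and do not
demonstrate.

## Growth-curve model

Curves are fitted with the modified (Zwietering) Gompertz form

    y(t) = A * exp(-exp(mu_max * e / A * (lam - t) + 1))

with yield `A` (OD), maximum growth rate `mu_max` (OD h⁻¹) and lag `lam` (h).
This is the standard microbiology parameterization in which the fitted
coefficients *are* the biological quantities of interest; other sigmoids
(logistic, Baranyi) are deliberately out of scope.

Numerical choices:

* **Blank handling.** The minimum of the first three OD readings is
  subtracted per well and the signal floored at 1e-4. Plate blanks vary by
  instrument; this rule is deterministic and does not assume a blank row.
* **Initialization and bounds.** `A₀ = max(od)`, `mu₀` = largest
  finite-difference slope, `lam₀` = first time OD reaches 10% of `A₀`;
  bounds A, mu ∈ (0, 10], lam ∈ [0, 36]. Least squares via
  `scipy.optimize.curve_fit` (trust-region reflective).
* **Non-growing wells.** Fits that fail, or converge with A < 0.05 OD, are
  flagged and excluded from parameter tables rather than propagated.
* **AUC** is the integral of the *fitted* curve over the observation window
  (default 0–36 h) by adaptive quadrature. Integrating the fit rather than
  the raw trace keeps the three growth parameters internally consistent (all
  derive from one curve fit); trapezoid integration of the raw data is
  available behind `on_raw=True`.
* **1/T_mid** = 1 / (A/(2 mu_max) + lam) combines lag, rate and yield so
  that larger always means better growth.

## Supernatant scoring

Relative growth is the ratio of a growth parameter in conditioned medium
(30% supernatant + 70% fresh medium) to the salt control (30% NaCl + 70%
fresh); per-replicate treated values are divided by the receiver's mean
control, then averaged per producer → receiver cell.

The integrative supernatant score sums each producer's ratios over its three
receivers, centers the sums, **negates** them (a low sum means strong
inhibition, and the score convention is positive = inhibitory), and scales
the two sides separately — positive residuals by the largest positive
residual, negative by the magnitude of the most negative — so the most
inhibitory producer scores exactly +1 and the most stimulatory exactly −1.
Scores are therefore invariant to adding a constant to all sums, but not to
rescaling individual ratios; they are a ranking device, not an effect size.

Strong inhibition means the ratio is at most 0.8 (growth reduced by ≥ 20%,
boundary inclusive). These edges drive rank adjustment and toxin
parameterization.

## The three ranking rules

* **Rule 1** sorts species ascending by one growth parameter; adjacent
  values within a relative tie tolerance (default 5%) merge into a tied
  group. Integrative parameters (1/T_mid, AUC) are recommended over bare
  mu_max, which ignores lag and yield.
* **Rule 2** removes each strong-inhibition producer from that order and
  re-inserts it immediately above the highest-ranked species it strongly
  inhibits, never below its Rule-1 position. When a producer's anchor is
  itself a promoted producer, both share the insertion slot; producers in
  one slot are stacked by how many species they inhibit, and equal counts
  merge into a tied group. Cyclic promotion constraints (A inhibits B, B
  inhibits A, nothing else) collapse into one tied group with a warning —
  the data cannot order such species.
* **Rule 3** discards edges produced by slow growers — the weakest Rule-1
  group, generalized to the bottom quartile of groups for communities with
  more than four groups — because low biomass limits inhibitory compound
  production.

This operationalization reproduces both reference four-species scenarios:
a single dominant inhibitor of intermediate growth rises to the top
(B < P < C < K), and two colliding promotions produce a two-tier clustering
(B ≈ C < K ≈ P, where the B ≈ C tie comes from Rule 1's tolerance — AUC
dampens differences between weak growers — and the K ≈ P tie from the
collision rule).

## Competitiveness from co-cultures

Wrightian relative fitness is computed from start/end CFU per pair and
log₁₀-transformed. The per-species integrative score walks species from
weakest (mean pairwise log-fitness) to strongest; each unordered pair's mean
log₁₀ fitness is estimated **once** and reused with opposite sign for the
partner, avoiding double counting of the reciprocal perspectives. With exact
reciprocity the scores sum to zero, so opposing effects can cancel and a
species can occupy a neutral rank. Detection-limit end counts must be
imputed at the plating limit (configurable) before fitness computation;
censored records carry flags. Community (3-/4-species) tables are summarized
by median log₁₀ CFU with replicate-paired Wilcoxon signed-rank tests, FDR
(Benjamini–Hochberg) correction and compact-letter significance groups —
routine statistics delegated to scipy/statsmodels.

## Agent-based model

Cells are discs (radius 0.5–1 μm) on a 100 × 100 μm torus. Per step, in
fixed order: toxin production, toxin diffusion, cell diffusion, toxin
uptake, toxin-induced death, growth, division, chemostat removal. Growth
follows G_t = g (1 − (ΣT/θ_T)^κ) G₀ with κ = 2 and G₀ = 0.5/1200 μm per
step; a cell targeted by several toxins multiplies the inhibition factors.
Division at 1 μm produces two 0.5 μm daughters placed tangently at a random
angle inside the mother's footprint, splitting the toxin load as evenly as
integers allow (the odd molecule assigned by coin flip). Once the population
first reaches 500, uniformly random cells are removed down to 500 at the end
of every step. Resources are unlimited and cells exert no mechanical forces
(overlap permitted): competition acts only through growth rates, toxins and
the chemostat.

**Toxins.** Each producer species secretes one molecular species;
susceptibility is a property of the receiver, so one K-toxin can kill C at
θ = 1750 molecules but B and P only at 2500. Molecules are point particles
emitted at producer centers, displaced per axis by Normal(0, √(2∂)) per step
(one step ≡ 1 s, so diffusion coefficients in μm² s⁻¹ apply per step), and
absorbed by a uniformly random overlapping **susceptible** cell;
non-targets — including the producer itself — neither suffer from nor soak
up the molecule. Absorption removes the molecule from the free pool; loads
of dying or chemostat-removed cells leave the system without re-release.
Accumulation beyond the receiver-specific θ_T kills. Integer bookkeeping
(produced = free + held by living cells + removed with dead) is verified
every step as an exact identity.

This uptake architecture is what produces the **toxin-absorption effect**:
susceptible slow growers (B, P) accumulate high per-cell loads, soaking up
molecules that would otherwise reach the fast-dividing reference species C,
which dilutes its own load below threshold through division. Per-capita
toxin uptake is reported as the time-average of (molecules held by living
cells of a species / number of those cells), directly expressing the
dilution mechanism; cumulative molecules absorbed per cell-ever is also
available.

**Parameters and defaults.**

| parameter | default | meaning |
|---|---|---|
| arena side | 100 μm | torus edge (10 000 μm² surface) |
| G₀ | 0.5/1200 μm | radius gain per step at g = 1 (division every 1200 steps) |
| κ | 2 | latency of toxin growth inhibition |
| r_init, r_div | 0.5, 1.0 μm | birth and division radii |
| founders | 32 per species | initial random placement |
| chemostat cap | 500 cells | population held after activation |
| D, ∂ (high diffusion) | 5, 10 μm² s⁻¹ | shaken liquid culture |
| D, ∂ (low diffusion) | 0, 0.1 μm² s⁻¹ | surface-attached growth |
| production rate | 0.75 molecules cell⁻¹ step⁻¹ | see below |
| steps | 30 000 (full), 5000 (desk scale) | simulation length |

The **toxin production rate** is a free parameter of the simulation platform
with no published value. It was fixed once, by a pilot sweep, at 0.75
molecules per producer cell per step — the regime in which kill thresholds
in the 750–4500 molecule range are *marginally* lethal over a 5000-step run:
well below it toxins are inert; well above it the producer sweeps the
community outright and the absorption effect cannot operate. All potency
(θ_T) calibration results are conditional on this rate: a platform emitting
toxin faster would calibrate to proportionally larger θ values.

**Potency calibration** simulates pairwise producer-vs-target competitions
across a θ_T sweep (750–4500 in steps of 250 by default, high diffusion) and
returns the *largest* θ — the weakest toxin, hence minimal potency — at
which the producer wins a majority of replicates (winner = larger mean
fraction over time). Sentinels: `none-needed` when the producer wins without
any toxin, `unachievable` when it loses even at the most potent setting.

**Scales used in the shipped tests.** Desk-scale runs use 5000 steps and
10 seeds for the four-species community (the competitive order
B < P < K < C and the B, P > C uptake signature are established well before
step 5000), 2000 steps for neutral-drift checks, and small arenas
(40 μm, cap 100) for calibration toys. These sizes were chosen as the
smallest at which the qualitative outcomes are stable across seeds.

## Synthetic data generator

The generator emulates the study's data shapes with known ground truth:

* **Plates**: 15-min OD grid over 36 h; per-species Gompertz truths chosen so
  the 1/T_mid order is B < K < P < C with T_mid ratios matching growth
  multipliers {C: 1, P: 0.84, K: 0.81, B: 0.68} (P fast but long-lagged, B
  slow throughout); i.i.d. Gaussian OD noise (σ = 0.01 by default — typical
  plate-reader scatter); 3 blocks × 3 replicates.
* **Supernatant treatments** multiply the receiver's effective mu_max by a
  producer-specific factor (K → everyone 0.5; B → P 0.6), the simplest
  mechanism consistent with suppressed curves; a lag-extension mode exists
  behind `lag_mode=True`. Note a mu_max factor attenuates on the 1/T_mid
  scale (a 0.5 factor on mu_max gives a ~0.66–0.82 ratio in 1/T_mid
  depending on the receiver's lag/yield balance), which is why the weaker
  B → P inhibition sits below the 20% edge threshold on 1/T_mid — exactly
  the kind of borderline effect Rule 3 renders irrelevant.
* **CFU tables**: end counts log-normal (σ = 0.15 log₁₀ units) around
  rank-consistent expectations, ~10-fold per rank step from 10⁷ CFU, start
  counts 5 × 10⁴ per species, detection-limit censoring at 10³ CFU.

What passing tests show: the pipeline's estimators and rules recover a
ground truth of the assumed structure under realistic noise. What they do
not show: robustness to non-Gompertz growth (diauxie, death phases),
supernatant effects acting on yield or through pH, plate position effects,
or CFU overdispersion beyond log-normal — real data can violate all of
these.

## Pipeline and reproducibility

One config drives fit → score → rank (→ simulate); per-stage seeds derive
from a root seed by fixed offsets; outputs and a manifest (config hash,
input digests, package version, per-stage timings) land in a run directory.
Reruns with the same config are byte-identical. Simulations are bit-identical
given a seed (single NumPy generator, fixed event order).

## Known limitations

* The ranking rules are calibrated on batch, well-mixed, four-species
  communities; promotion collisions among many inhibitors and communities
  with rich cyclic inhibition are resolved by documented conventions, not by
  data.
* The ABM has no nutrient field, no mechanical cell interactions, no toxin
  decay, and models only inhibitory molecules; 24-h snapshot experiments are
  compared against long-run simulated frequencies, so magnitudes (not
  orders) are expected to differ.
* Fitness scores assume detection-limit imputation when a species is
  uncountable; the resulting values are bounded, not measured.
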