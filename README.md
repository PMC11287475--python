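# rankcast

Predicting competitive rank orders in small bacterial communities from
culture-free assays, with an agent-based simulator of toxin-mediated
interference competition.

Co-culture competition experiments directly reveal winners and losers, but
they are labor-intensive and require distinguishable species. `rankcast`
implements an alternative: combine **monoculture growth curves** with
**supernatant assays** (growth in cell-free conditioned medium) to predict
which species will dominate a mixed community, and explore higher-order
community dynamics with an individual-based model. The reference system is a
four-species consortium of opportunistic pathogens, abbreviated B
(*Burkholderia*), C (*Cronobacter*), K (*Klebsiella*) and P (*Pseudomonas*).

## What it computes

**Growth parameters.** OD600 trajectories are fitted with the modified
(Zwietering) Gompertz model — yield *A*, maximum growth rate *μ*<sub>max</sub>,
lag *λ* — from which three integrative readouts are derived: *μ*<sub>max</sub>,
the area under the fitted curve (AUC), and the inverse time to
mid-exponential phase

&nbsp;&nbsp;&nbsp;&nbsp;1/*T*<sub>mid</sub> = 1 / (*A* / (2 *μ*<sub>max</sub>) + *λ*).

**Supernatant interactions.** Growth of a receiver in 30% producer
supernatant relative to a salt control, (a)/(b), classifies each directed
pair as inhibitory (< 1) or stimulatory (> 1); per-producer sums are centered
and scaled to [−1, +1] into an integrative supernatant score, and ratios
≤ 0.8 define strong-inhibition edges.

**Rank prediction (three rules).** Rule 1: rank species by a monoculture
growth parameter. Rule 2: move species that strongly inhibit others up the
ranking (immediately above the highest-ranked species they inhibit). Rule 3:
ignore inhibitory edges exerted by slow growers, whose low biomass limits
compound production.

**Validation metrics.** Pairwise co-cultures are scored with Wrightian
relative fitness, *w*₁ = (end CFU₁ × start CFU₂)/(end CFU₂ × start CFU₁),
log₁₀-transformed and folded into a stepwise per-species competitiveness
score; 3- and 4-species outcomes are compared by end-point CFU with paired
Wilcoxon tests and FDR correction.

**Agent-based model.** Disc-shaped cells on a 100 × 100 μm torus grow by
radius increments *G*<sub>t</sub> = *g* (1 − (ΣT/θ<sub>T</sub>)^κ) *G*₀ with
κ = 2 and *G*₀ = 0.5/1200 μm, divide at 1 μm, and share accumulated toxin
between daughters. Producers secrete point-like toxin molecules that diffuse,
are absorbed by susceptible cells, and kill at the receiver-specific
threshold θ<sub>T</sub>; a chemostat caps the population at ~500 cells.
Species growth multipliers come from scaled monoculture
1/*T*<sub>mid</sub> values, *g* = 0.5 + 0.5 *T*<sub>mid,ref</sub>/*T*<sub>mid,i</sub>.

## Worked example

No external data are needed — the built-in generator emulates a full study
(plate curves + CFU tables) with a known ground-truth rank:

```sh
rankcast synth --seed 1 --out fixtures
# wrote fixtures/plate.csv and fixtures/cfu_pairwise.csv (true rank: B < P < C < K)

rankcast fit-growth --input fixtures/plate.csv --out fixtures/params.csv
# wrote fixtures/params.csv (180 wells, 180 converged)

rankcast supernatant-score --params fixtures/params.csv --out-prefix fixtures/supernatant
# strong inhibition: K -> B (ratio 0.787)
# strong inhibition: K -> C (ratio 0.661)

rankcast predict --params fixtures/params.csv
```

prints (abridged)

```json
{
  "mono_rank": [["B"], ["K"], ["P"], ["C"]],
  "slow_growers": ["B"],
  "edges": [["K", "B"], ["K", "C"]],
  "predicted_rank_str": "B < P < C < K"
}
```

Read: by monoculture growth alone K is second-weakest (Rule 1), but its
supernatant strongly suppresses other species, so Rule 2 promotes it above
everything it inhibits — the predicted competitive order is B < P < C < K,
matching the generator's ground truth. The pairwise CFU table confirms it:

```sh
rankcast fitness --counts fixtures/cfu_pairwise.csv --out fixtures/fitness.csv
# B: -5.947
# P: -1.860
# C: +2.000
# K: +5.807
```

(summed log₁₀ relative fitness per species, weakest to strongest).

Community simulation from a YAML config:

```sh
rankcast simulate --config sim.yaml --seed 7 --out run1/
rankcast calibrate --config sim.yaml --producer K --target C --sweep 750:4500:250
rankcast run --seed 1 --out study/        # full pipeline with manifest
```

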