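# straitpop

Closed-population assessment toolkit for adult tri-spine horseshoe crabs
(*Tachypleus tridentatus*) in the Taiwan Strait.

The package rebuilds, as a tested and reusable pipeline, the analysis chain
of a multiyear mark-recapture monitoring program spanning three subregions
(Kinmen, Penghu, and the Taiwan main island) with monthly sampling
occasions:

* **Records** — a capture-event data model (tag id, date, subregion, WGS84
  coordinates, event kind, release flag, sex, prosomal width), CSV
  round-trip with row-level validation, and aggregation into per-occasion
  mark-recapture statistics (C_t, M_t, R_t, U_t) with optional cross-year
  tag carryover.
* **Schnabel estimation** — the multi-occasion closed-population estimator

  N̂ = Σ_t C_t·M_t / (Σ_t R_t + 1),   Var(1/N̂) = Σ_t R_t / (Σ_t C_t·M_t)²

  with exact-Poisson or reciprocal-normal 95% intervals and a Monte Carlo
  cross-subregion comparison (pairwise P(N_A > N_B)).
* **Bayesian N-mixture estimation** — the constant-p closed-population
  (M0) capture likelihood with a log-normal prior on latent abundance N
  and a Beta prior on detection probability p, fitted by MCMC (slice
  sampling on logit p with N marginalized, exact conditional draws of N),
  with split-R̂/bulk-ESS diagnostics and an exhaustive grid-posterior
  oracle for validation.
* **Field summaries** — recapture rates and catch-per-unit-effort with the
  half-up 2-decimal rounding convention of the program's annual tables.
* **Movement** — great-circle release-to-recapture displacement and exact
  days at liberty.
* **Connectivity** — Q4 (top-quartile) core-area extraction from a
  habitat-quality raster, a [1,100] resistance surface, and least-cost
  corridors between core patches (multi-source Dijkstra, average-node move
  costs), with ESRI ASCII grid interchange.
* **Synthetic data** — a generator for every input the pipeline consumes
  (capture histories with known ground truth, effort logs, displacement
  pairs, habitat rasters), so the full chain is testable without field
  data.

## Worked example

```python
from straitpop import (build_occasions, schnabel_estimate, fit_nmixture,
                       nmixture_data_from_events)
from straitpop.synthetic import SimulationScenario, simulate_capture_history

scenario = SimulationScenario(subregion="Kinmen", year=2024, true_N=1000,
                              p=0.1, T=6, tagging_prob=0.9, seed=42)
events, truth = simulate_capture_history(scenario)

series = build_occasions(events)[("Kinmen", 2024)]
res = schnabel_estimate(series)
print(f"Schnabel: {res.n_hat:.0f} ({res.ci_low:.0f}-{res.ci_high:.0f})")

post = fit_nmixture(nmixture_data_from_events(events, "Kinmen", 2024))
print(post.summary.loc["N"])
```

prints (for this seed)

```
Schnabel: 917 (782-1109)
mean         948.652500
median       945.000000
ci_low       834.000000
ci_high     1084.000000
r_hat          1.000025
ess_bulk    8075.199366
Name: N, dtype: float64
```

Both estimators bracket the simulated truth of 1000 animals: the Schnabel
point estimate is 917 with a 95% interval of 782–1109, and the N-mixture
posterior has median 945 with a 95% credible interval of 834–1084 and
clean convergence diagnostics (R̂ ≈ 1.00, bulk ESS ≈ 8000 of 8000 draws).

The numbered scripts under `analysis/` run the same stages as a narrative
pipeline over a six-stratum synthetic survey (simulate → summarize →
Schnabel → N-mixture → movement → connectivity) and write their tables
under `results/`.

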