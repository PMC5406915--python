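# ramarkov

Markov disease-state transition modelling for rheumatoid arthritis (RA)
registries.

RA disease activity in treated patients fluctuates: visits months apart find
the same patient in low, moderate, or severe disease activity, and clinicians
managing to treat-to-target goals need to know how likely each move is and how
long patients linger in each state. `ramarkov` implements the complete
analysis for longitudinal registry data scored with the Clinical Disease
Activity Index (CDAI = TJC28 + SJC28 + PtGA + PGA, range 0–76; states:
remission ≤ 2.8 < low ≤ 10 < moderate ≤ 22 < severe):

- **Empirical transition matrices** — the per-visit MLE
  π̂ᵢⱼ = nᵢⱼ / Σⱼ nᵢⱼ over consecutive-visit pairs, for the full cohort and
  for a *regular-visit sub-cohort* (every inter-visit gap in 3–9 months).
- **Continuous-time multi-state model** — panel MLE of the intensity matrix Q
  (ℓ(Q) = Σ log [exp(Q·Δt)]\_{prior,current}), giving interval-standardized
  matrices P(t) = exp(Qt) (e.g. a 6-month horizon comparable across visit
  schedules) and mean sojourn times −1/qᵢᵢ with delta-method intervals.
- **Markov logistic regression** — current state on prior state, visit-interval
  bin, and calendar-year / disease-duration / age categories, with
  covariate-by-prior-state interactions, patient-clustered sandwich variance,
  odds-ratio contrasts, and marginally standardized transition matrices.
  Multinomial logit for the 3-state scheme, binary logit for low vs
  moderate/severe.
- **A synthetic registry generator** — latent state dynamics from a
  configurable per-visit matrix or CTMC generator, irregular visit schedules
  matching published interval moments, covariate effects on transition
  log-odds, and CDAI component decomposition — so every estimator is validated
  by parameter recovery against known truth. Real registries of this kind are
  proprietary; the generator is the package's test bed, not a data substitute.

## Worked example

```python
import ramarkov as rm

# simulate a registry whose truth is the published full-cohort matrix
cfg = rm.SimulationConfig(n_patients=2000, seed=42, visits_mean=6.0)
sim = rm.simulate_cohort(cfg)

visits = rm.derive_states(sim.visits)          # CDAI -> low/moderate/severe
trans  = rm.pair_consecutive_visits(visits)    # consecutive-visit pairs
m = rm.mle_transition_matrix(rm.count_transitions(trans))
print(m.to_frame().round(2))
```

```
           low  moderate  severe
low       0.81      0.15    0.03
moderate  0.46      0.35    0.19
severe    0.13      0.38    0.50
```

Each row is a prior state, each column the state at the next visit: a patient
seen in moderate disease has a 46% chance of being low at the next visit and a
19% chance of being severe (generator truth: 0.47 / 0.18 — the simulation
recovers it to sampling error). The continuous-time route adds sojourn times;
here on a cohort simulated in jump-chain mode with generator sojourns
19.38 / 4.25 / 5.30 months:

```python
ctmc_cfg = rm.SimulationConfig(n_patients=2000, seed=7, mode="ctmc",
                               intensity=rm.reference_intensity(), visits_mean=6.0)
ctmc_sim = rm.simulate_cohort(ctmc_cfg)
ctmc_trans = rm.pair_consecutive_visits(rm.derive_states(ctmc_sim.visits))
fit = rm.fit_ctmc(ctmc_trans)
for e in rm.mean_sojourn_ctmc(fit):
    print(f"{e.state:9s} {e.mean:5.2f} months  (95% CI {e.ci_lo:.2f}-{e.ci_hi:.2f})")
```

```
low       19.70 months  (95% CI 18.35-21.15)
moderate   4.22 months  (95% CI 3.93-4.53)
severe     5.41 months  (95% CI 5.00-5.87)
```

Each fitted interval covers its generator truth. The full pipeline —
cohort filters, empirical and
6-month matrices, sojourn tables, OR tables — runs in one call or from the
shell:

```bash
ramarkov simulate --config sim.yaml --out cohort/
ramarkov fit --registry cohort/registry.csv --out report/
ramarkov recover --replicates 100 --out recovery/
```

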