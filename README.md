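# microflux

Longitudinal gut-microbiome colonization dynamics: who stays, who passes
through, and what that turnover does to the community and the host.

`microflux` is for microbiome researchers with species-by-sample
abundance tables from repeated stool sampling of the same subjects
(e.g. quarterly visits over a year). It models each species' occupancy
as a two-state Markov chain and classifies species as **persistent
colonizing species (PCS)** — once they appear, they stay — or
**transient colonizing species (TCS)** — they appear briefly and are
lost. Downstream it quantifies species retention, community
destabilization and host-phenotype associations of the two classes.

## The model

Presence is called against a data-driven detection limit: all nonzero
abundances (per-million scale, log2-transformed) are pooled and fitted
with a maximum-likelihood gamma distribution; a species is present in a
sample only when its log2 per-million abundance exceeds the fitted 1%
quantile.

For each species, transition pairs over consecutive same-subject visits
are pooled into a two-state Markov chain with maximum-likelihood
transition probabilities

```
inflow  = P(absent  -> present) = n_ap / (n_aa + n_ap)
outflow = P(present -> absent)  = n_pa / (n_pp + n_pa)
```

Species with inflow > 0.3 and outflow < 0.3 are PCS; outflow > 0.3 and
inflow < 0.3 are TCS (strict inequalities; species at 0% or 100%
prevalence are excluded). Retention is the Kaplan–Meier survival of a
species' stay, with loss as the event and the visit interval as the
clock.

Per-species abundances standardize to z_ij = (A_ij − μ_i)/σ_i over all
samples, and a class aggregates as Z_class(j) = Σ_i z_ij / √n, which is
standard normal under an iid null for any class size n. Consecutive
visits give μ = (Z_t + Z_{t+1})/2 and Δ = Z_{t+1} − Z_t; individuals
with μ_TCS > 2 are TCS-enriched, μ_TCS < −2 TCS-depleted. Host
phenotypes are tested with a random-intercept mixed model
Y = Z_PCS·β_PCS + Z_TCS·β_TCS + u_subject + ε.

A synthetic cohort generator with known ground-truth inflow/outflow,
log-normal abundances, multinomial sequencing noise and score-linked
phenotypes makes the whole pipeline testable without cohort data.

## Worked example

```python
import microflux as mf

cfg = mf.SimulationConfig(n_subjects=86, n_visits=4, n_species=300, seed=1)
presence, truth = mf.simulate_presence_paths(cfg)
abundance, _ = mf.simulate_abundances(presence, cfg)

model = mf.fit_detection_model(abundance)        # pooled gamma fit
called = mf.call_presence(abundance, model)      # presence/absence
est = mf.MarkovFluxEstimator().fit(called)       # inflow/outflow + labels

print(f"detection threshold: {model.threshold_:.3f} log2 per-million")
print(est.labels_.value_counts().to_dict())

events = mf.build_retention_events(called)
curve = mf.km_curve(events)
print(f"retention at 3 visit-intervals: {mf.retention_probability(curve, 3):.3f}")
```

prints

```
detection threshold: 2.754 log2 per-million
{'UNCLASSIFIED': 177, 'TCS': 66, 'PCS': 57}
retention at 3 visit-intervals: 0.255
```

The threshold is the fitted 1% gamma quantile on the log2 per-million
scale: anything below it is treated as undetected. Of the 300 simulated
species, 57 show persistent-colonizer dynamics and 66 transient ones
(the rest sit between the thresholds or lack defined transitions), and a
species episode that has started has a 25.5% probability of surviving
all three following visit intervals.

The same stages run from a shell via the `microflux` CLI
(`simulate`, `quantify`, `detect`, `flux`, `retention`, `scores`,
`associate`, `run-all`), each writing plain TSV/JSON outputs.

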