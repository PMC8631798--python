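# divtrace

Quantitative analysis for **dual-colour monosynaptic rabies tracing** of
premotor spinal circuits.

When two glycoprotein-deleted rabies viruses carrying different fluorophores
(e.g. eGFP and mCherry) are injected into two muscles, premotor interneurons
synapsing onto both motor pools — *divergent* neurons — can end up double
labelled. But each trans-synaptic jump succeeds only with some efficiency
*e*, so the observed double-labelled fraction *r* among labelled cells
systematically understates the true divergent fraction *d*. `divtrace` is
for anatomists and circuit modellers who need to go from raw labelled-cell
tables to corrected divergence estimates with honest uncertainty.

## The model

Each premotor→motoneuron synapse transmits its virus independently with
per-jump efficiency *e*. A single-pool neuron is labelled with probability
*e*; a divergent neuron is double labelled with probability *e²* and
labelled at all with probability *2e − e²*. For a population with divergent
fraction *d*,

```
r = d·e / (1 + d·(1 − e)),        d = r / (e − r·(1 − e)),
```

with maximum observable rate `r_max = e/(2 − e)` (all neurons divergent).
At *e* = 0.25, an observed *r* = 4% corresponds to a true *d* = 18%. An
observed rate at or above `r_max` is inconsistent with the assumed
efficiency; the package then reports the smallest consistent efficiency,
`e_min = 2r/(1 + r)`, instead of an estimate.

Around this core the package provides:

- **`synthetic`** — virtual spinal-cord cohorts (per-region population
  sizes, quadrant-structured positions, log-normal soma areas, marker
  fractions) and a per-neuron Bernoulli labelling simulator with optional
  viral interference ρ;
- **`quantify`** — central-canal coordinate normalisation, DI/DC/VI/VC
  quadrant assignment, 1-in-k section subsampling, divergence summaries
  (pooled and per-animal), Kruskal–Wallis/Dunn/Mann–Whitney soma-area
  statistics, spatial density profiles;
- **`DivergenceModel` / `DivergenceResults`** — fit the correction to
  counts or cell tables, with a parametric-bootstrap confidence interval;
- **`divtrace`** CLI — `simulate`, `summarize`, `correct`, `curve`, `run`.

## Worked example

Correct a count of 206 double-labelled cells among 4341 labelled premotor
interneurons, assuming a 25% jump efficiency:

```sh
divtrace correct --double 206 --total 4341 --efficiency 0.25 --seed 1
```

```
Divergence-rate correction (binomial double-infection model)
============================================================
counts:              206 double / 4341 labelled
observed rate r:     0.047455  (4.7%)
assumed efficiency:  e = 0.25  (assumption, not estimated)
corrected rate d:    0.221327  (22.1%)
95% bootstrap CI:    [0.1882, 0.2559]  (n_boot = 10000)
```

Reading: 4.7% of labelled cells carried both colours, but at 25% jump
efficiency most divergent neurons receive only one (or neither) virus, so
the model attributes the counts to a population in which ~22% of premotor
neurons contact both pools, with a binomial-resampling CI of [0.19, 0.26].

The same loop works from simulation. A virtual cord (lumbar: 7000 premotor
neurons per animal with true d = 0.18) pushed through infection at e = 0.25
and the standard counting rules (motoneurons excluded, lumbar counted on one
of every three sections) gives

```python
import divtrace as dt
cfg = dt.default_cord_config(n_animals=4, seed=1)
cells = dt.simulate_infection(dt.generate_cohort(cfg), dt.VirusParams(), seed=2)
print(dt.divergence_summary(cells))
```

```
  region  n_double  n_total  rate_pooled
cervical        24      175     0.137143
  lumbar       108     2640     0.040909
  sacral         1       16     0.062500
thoracic       115      784     0.146684
```

— the lumbar block shows the expected ≈4% observed rate, and fitting
`DivergenceModel.from_summary_row(...)` recovers d ≈ 0.18. The cervical and
thoracic rates sit near or above `r_max` = 14.3% for e = 0.25, exactly the
regime where the model reports an implied minimum efficiency rather than a
corrected rate.

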