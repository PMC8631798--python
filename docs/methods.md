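# Methods

## The double-infection model

`divtrace` models dual-colour retrograde rabies tracing as independent
Bernoulli transmission across premotor→motoneuron synapses. Writing *e* for
the per-jump transfer efficiency and *d* for the fraction of premotor
neurons contacting both injected motor pools:

- a non-divergent neuron is labelled with probability *e*;
- a divergent neuron receives each colour independently with probability
  *e*: double labelled with probability *e²*, labelled at all with
  probability *2e − e²*.

The observed double-labelled fraction among labelled cells is therefore

    r(d, e) = d·e² / (d·(2e − e²) + (1 − d)·e) = d·e / (1 + d·(1 − e)),

which is strictly increasing in both arguments, bounded by
`min(d, e/(2 − e))`, and algebraically invertible:

    d(r, e) = r / (e − r·(1 − e)).

Assumptions, stated plainly: transfer efficiencies are equal and
independent across synapses and regions; the two viruses do not interfere
(the inversion is only defined for ρ = 0); every labelled cell is counted
once; primary-infected motoneurons are excluded from denominators. The
forward simulator can relax the no-interference assumption; the inversion
deliberately cannot, because interference has no identifiable closed form
in a two-count experiment — an interference-affected count therefore yields
an *underestimate* of d, which is the conservative direction.

### Feasibility

`r_max = e/(2 − e)` is the rate a population of exclusively divergent
neurons would show. `true_rate` raises an `InfeasibleRateError` for any
r within 1e-9 of or above that bound (the error carries the bound and the
implied minimum efficiency `e_min = 2r/(1 + r)`). The margin means the
exact point d = 1 is also refused — inverting a rate on the boundary
cannot distinguish d = 1 from an efficiency misspecification, so the
package reports the feasibility diagnosis instead. Pipelines do not stop:
an infeasible group is reported with its `e_min` and the run continues.

### Uncertainty

`correct_estimate` / `DivergenceModel.fit` attach a parametric-bootstrap
CI: resample `n_double* ~ Binomial(n_total, r̂)`, map each resample through
the inversion, take percentile bounds (default 10 000 resamples, 95%
level, seeded). Resamples at or above the feasibility bound are mapped to
d = 1 and counted in `n_infeasible_resamples`; the upper bound is capped
at 1. Near the bound this yields honest, strongly asymmetric intervals.

## Tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `e` (efficiency) | per-jump transfer probability | 0.25 | upper bound suggested for the SAD-B19 strain by strain-comparison data; always echoed in output as an assumption |
| `ρ` (interference) | reduction of the second virus's efficiency after a first infection | 0 | matches the simplifying independence assumption; forward-simulation only |
| `n_boot` | bootstrap resamples | 10 000 | percentile-CI stability at the 2.5% tails |
| sampling | 1-in-k sections per region | lumbar k = 3, others k = 1; motoneurons k = 2 | the counting convention for dense lumbar labelling (avoids counting a cell split across consecutive 30 µm sections twice); all overridable |
| bins | spatial-profile bins over [−1, 1] | 40 | ≈0.05 of a hemisection per bin |

## The synthetic cohort generator

`generate_cohort` emulates the population the tracing experiment samples
from. Defaults (per animal): lumbar 7000 premotor neurons with true
d = 0.18; thoracic 500 with d = 0.85; cervical 100 long descending
propriospinal neurons with d = 0.9; sacral 15 with d = 0.25. Quadrant
weights, soma-area moments (log-normal, e.g. cervical 774 ± 231 µm² vs
lumbar 320 ± 114 µm²) and marker fractions are matched to the printed
per-region counts; lumbar cohort size and d follow the corrected lumbar
estimate, and the thoracic/cervical divergent fractions are set so that
their *observed* rates land in the printed 13–45% range — which puts them
near or beyond the e = 0.25 feasibility bound, reproducing the real
analysis situation where those regions admit only an implied-minimum-`e`
statement. Animals are homogeneous by construction: neurons are split
evenly across animals (remainder to the first), the single-pool A/B split
is 50/50 (configurable), positions are uniform within the sampled
quadrant, and one neuron occupies exactly one section (an optional
spillover flag duplicates labelled cells onto an adjacent section to let
tests exercise the subsampling rationale). Optional motoneuron rows are
primary-infected, cholinergic, and never enter premotor denominators.

What the generator does *not* emulate: within-quadrant spatial structure
(laminae, nuclei), per-synapse efficiency heterogeneity, secondary
motoneuron-to-motoneuron jumps, section-boundary geometry, or animal-level
biological variability in d. Passing tests therefore demonstrate the
correctness of the counting and correction machinery under the stated
stochastic model, not robustness to those real-data features.

Forward-simulation defaults where the source analysis states none:
population 10⁶, 100 replicates, ρ = 0. `mc_observed_rate` uses binomial
draws that are distribution-identical to per-neuron Bernoulli labelling;
the per-neuron path is exercised independently by `simulate_infection`,
and the two routes are cross-checked against each other and against the
closed form in the test suite.

## Quantification conventions

- Coordinates: central canal at (0, 0); each half-axis normalised by its
  own canal-to-grey-matter-border distance, per region; x > 0 ipsilateral
  to the hindlimb injection, y > 0 dorsal. Out-of-bounds points are
  flagged and excluded from summaries rather than clipped.
- Quadrants: ties (coordinate exactly 0) go to ipsilateral/dorsal —
  deterministic and measure-zero under continuous positions.
- Rates: the pooled rate (summed double / summed total) and the unweighted
  per-animal mean ± SD are both always reported. They agree for
  homogeneous animals; `mean_pooled_discrepancy` flags a group when
  |mean − pooled| > max(0.01, 0.1·pooled), which catches cohorts where
  animal size correlates with animal-level divergence.
- Percentages are rendered at one decimal, rounding half away from zero;
  machine-readable outputs keep full-precision fractions.
- Soma-area comparisons are two-sided rank tests on raw areas:
  Kruskal–Wallis (tie-corrected) across ≥3 groups with Dunn's pairwise
  z-tests under Bonferroni adjustment (the adjustment family is a package
  choice, recorded in output), Mann–Whitney for two groups. Dunn's
  statistic is computed from pooled ranks with the tie term
  Σ(t³ − t)/(12(N − 1)); for two groups it satisfies z² = H exactly, which
  the tests use as an independent check. Groups with fewer than two values
  are excluded with a warning.

## Pipeline determinism

Every run is driven by one config and one seed; config hash and seed are
stamped into each artifact's comment-line metadata, stage timings and row
counts go only to the logging stream, and re-running an identical config
produces byte-identical files.

## Problem sizes used in validation

The shipped test-suite and acceptance computations use: 10⁶ neurons for
the forward-simulation anchor; 100×100 grids for the round-trip identity
(to 1e-12, d up to 1 − 1e-6; d = 1 is the feasibility boundary, asserted
as such); 10⁵ neurons × 100 replicates for Monte-Carlo/closed-form
agreement (3 SE); 100 seeded cohorts of 7000 lumbar neurons with 2000
bootstrap resamples for CI coverage (≥90/100); and 200 replicates at the
printed group sizes (38/135/61) for the soma-area power check. These sizes
make every statistical check's sampling error small relative to the
tolerance it asserts.

## Known limitations

- `e` is assumed, not estimated; corrected rates inherit its error and the
  package deliberately refuses to estimate `e` from a two-count design.
- The inversion ignores interference and so underestimates d when ρ > 0.
- No lamina-level mapping (quadrants and raw normalized coordinates only);
  no multi-pool (>2 colour) generalisation; no modelling of secondary
  motoneuron-mediated jumps beyond optional cosmetic rows.
- Printed per-animal mean ± SD values from the original per-animal source
  tables cannot be reproduced from pooled counts alone; only pooled ratios
  are treated as exact reproduction targets.
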