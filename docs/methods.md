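# Methods

## Scope and data model

The package analyzes flow-cytometry event tables (scatter plus fluorescence
channels) and time-stamped bulk culture measurements (viable cell density,
viability, glucose, glutamine, lactate, ammonium, antibody titer). Two
experiment designs are supported end to end, each with a synthetic
counterpart so the full chain can be validated without instrument data:

1. **Clonal outgrowth under repeated-batch passaging.** Cells co-transduced
   with three fluorescent-protein vectors fall into eight intensity octants.
   Flasks are re-seeded to 0.3·10⁶ cells ml⁻¹ every 5 days for 130 days; a
   faster-growing variant clone present at a small initial share overgrows
   the culture.
2. **Mixed cultures of differently aged precultures.** Four singly-marked
   populations, each harvested from a different growth phase, are pooled at
   0.25·10⁶ cells ml⁻¹ each. Each population resumes growth after a
   phase-specific lag (3/13/15/18 h) at a common specific growth rate
   (0.037 h⁻¹), sampled twice daily (shake flask) or hourly for 48 h
   (bioreactor with automated flow cytometry).

## Event preprocessing

Processing order is debris exclusion → doublet exclusion → compensation →
normalization. Debris is a rectangle gate on FSC-A and SSC-A (defaults
FSC-A ∈ [10⁵, 4·10⁶], SSC-A ∈ [10⁴, 4·10⁶]); doublets are events whose
FSC-H/FSC-A ratio leaves [0.8, 1.2] (a doublet roughly doubles the area
signal at unchanged height). Population sizes are always computed on the
retained singlet events.

Compensation subtracts ordered spillover terms sequentially: the second
term uses the already-compensated source channel, i.e. the ordered list is
treated as a triangular spillover system (a `sequential=False` switch uses
raw sources throughout). Compensated intensities are floored at 1 raw unit
so logarithms stay defined; the floor sits far below every positivity
threshold, so classification is unaffected. Provenance flags on the sample
prevent double compensation.

The bounded log normalization maps raw intensity onto [0, 1] between
per-channel boundaries (lower 10³ for all channels; upper 2·10⁵ for mCherry
and Cerulean, 10⁷ for Venus). The package defaults to the **ascending**
orientation (*I*\_lower → 0, *I*\_upper → 1), which makes a high-intensity
population sit near 1 on its axis — matching how the cube coordinates of
the dominant high-Venus/intermediate-Cerulean population (≈ 0.2/0.7/0.4 on
R/G/B) are described. The descending complement is available via
`ascending=False` for literal compatibility with the alternative
convention. The value is algebraically independent of the log base.

## Gating

Positivity is *strict* inequality against the per-channel threshold (equal
to the lower normalization bound, 10³): an event exactly at the threshold
is negative. The choice at exact equality is arbitrary; it is documented
and covered by a test. The octant label is exactly the set of positive
colors, giving eight exhaustive, mutually exclusive labels. Marginal
per-channel positive percentages equal the sum of the containing octant
fractions by construction.

Four-color classification uses nearest centroids in log₁₀-intensity space;
the within-cluster spread and centroid spacing of the synthetic populations
keep neighboring clusters ≥ 3 SD apart, so misassignment stays below 0.5 %.
Exact distance ties (to numerical precision) are labelled `unassigned`.
Rectangular gates on raw intensity are available as an alternative for real
data where centroids are unknown.

## Population dynamics

Change statistics compare a baseline window against a final window of the
fraction series. The bioreactor (hourly) mode defaults to the first three
vs last three samples; the shake-flask mode to single first/last samples
(window sizes are parameters). *Total* change is reported in percentage
points of all gated cells, *individual* change relative to the population's
own baseline share. Both are linear in the fractions.

The lag/growth fit is a broken-stick model on log density: a horizontal
segment at the inoculation level followed by a straight line of slope *μ*.
For each candidate breakpoint on the observed time grid the model is linear
in its two parameters (level and slope) and solved by least squares; the
breakpoint minimizing the residual sum of squares wins. The discrete search
matches the hourly sampling grid of the automated-cytometry data;
continuous breakpoint refinement is deliberately not attempted. Candidates
leave at least two points after the breakpoint; fits with fewer than three
post-lag points warn, and a non-positive fitted slope raises a no-growth
flag. On noiseless synthetic data the fit recovers (lag, *μ*) to machine
precision when the true lag lies on the grid.

## Kinetics

Cell-specific rates are two-point differences normalized by the trapezoidal
mean viable density, attached to interval midpoints. Internally time is in
hours, *X*_v in cells l⁻¹ and concentrations in mmol l⁻¹ (mg l⁻¹ for the
antibody), which puts rates on the 10⁻¹⁰–10⁻¹¹ per-cell-per-hour scale.
Intervals spanning a passage are excluded automatically (the medium
exchange resets concentrations); further intervals can be excluded
explicitly. In repeated-batch mode, where every measurement sits at a cycle
endpoint, each passage contributes one interval from its *calculated*
post-transfer state (seed density, fresh medium) to the measured endpoint.
No smoothing or regression-based rate estimation is applied — the two-point
estimator is the method. Its finite-difference character means a rate
estimated over an interval of exponentially growing density is biased low
by a factor ≈ 1 − (μΔt)²/12; tests assert the error shrinks monotonically
under grid refinement rather than pretending the estimator is exact.

Relative changes support two conventions: `delta` (100·(end−start)/start)
and `ratio` (100·end/start), because published summaries use both ("−15 %"
for a productivity decline, "220 %" for a titer that nearly doubled).

## Synthetic generator

**Copy numbers and intensities.** Each vector integrates with copy count ~
Poisson(effective MOI), independently across vectors; a cell's channel
intensity is autofluorescence plus the sum of one log-normal per copy
(additive on the linear scale). The effective MOI is the functional titer —
deliberately *not* forced to equal the nominal MOI, because measured
cluster fractions (e.g. 13.8 % unstained at nominal MOI 3, against the
Poisson prediction e⁻³ ≈ 5 %) show the functional titer was lower.
Compositions can therefore also be specified directly as cluster fractions.

**Intensity levels.** Autofluorescence is log-normal at log₁₀ mean 2.0,
SD 0.3 (well below the 10³ threshold). Day-0 positive peaks are broad and
polyclonal (log₁₀ means 4.5/5.3/4.2 for mCherry/Venus/Cerulean, SDs
0.35–0.45); the variant clone has narrow peaks at Venus ≈ 1.5·10⁶ and
Cerulean ≈ 10⁴ (SD 0.15). With these choices the per-event probability of
a threshold-crossing tail misclassification is a few 10⁻⁴ — negligible
against the three-binomial-SE tolerances used in recovery tests.

**End-of-study composition.** Only the day-130 *marginal* positives
(mCherry 4.01 %, Venus 84.3 %, Cerulean 84.8 %) and the qualitative picture
(one dominant Venus+Cerulean population; unstained share unchanged) are
known. The generator reconstructs a consistent joint composition by placing
the whole mCherry-positive share in the triple-positive octant, keeping the
unstained share at its day-0 value (13.8 %), letting the GB octant carry
the dominant population and the single-positive G/B octants absorb the
marginal excess (R, RG, BR empty). The construction reproduces all three
marginals exactly and sums to 100.

**Growth model.** Pure exponential growth with a hard lag and an optional
proportional carrying-capacity cap; no death phase (viabilities stay above
95 %, and log-linear slope fitting is the target analysis). Composition
under repeated-batch passaging follows the exact replicator form
f_p(t) = f_p(0)·e^{μ_p t} / Σ_q f_q(0)·e^{μ_q t}, since passaging preserves
fractions. The variant clone defaults: initial share 0.1 %, μ 0.0315 h⁻¹ vs
0.028 h⁻¹ base (the outgrowth reaches ~50 % around day 85 and > 95 % by day
130, matching the observed trajectory shape). The variant's initial
abundance and growth advantage are free simulation parameters, not
estimates — the study does not report them.

**Bulk metabolites.** Forward model dc/dt = ±Σ_p q_p·X_p(t) (minus for
glucose/glutamine, plus for lactate/ammonium/antibody), integrated by
trapezoidal quadrature on a 0.05 h grid and floored at zero; exact for
constant density, and within the 2 % round-trip tolerance otherwise.
Metabolites reset to fresh-medium values at each passage (fresh medium:
35 mmol l⁻¹ glucose, 5 mmol l⁻¹ glutamine, zero lactate/ammonium/antibody).
Default rates (q_Glc 5·10⁻¹¹ mmol cell⁻¹ h⁻¹, q_Lac 6.8·10⁻¹¹, q_Ab
2·10⁻¹⁰ mg cell⁻¹ h⁻¹, variant q_Ab 4.5·10⁻¹⁰) reproduce the observed
per-passage endpoints (glucose not below ≈ 20 mmol l⁻¹, lactate ≈ 20
mmol l⁻¹, early titers near 84 mg l⁻¹ rising as the productive variant
takes over). No Monod terms, no ammonium inhibition, no cell-cycle
structure. The late-study productivity *decline* is not emulated — it has
no mechanistic counterpart in a growth-selection model.

**Measurement noise.** Multiplicative log-normal noise with configurable CV
(default 5 %, mean-unbiased) on densities and concentrations, applied at
sampling times only. Event-level composition noise arises naturally from
multinomial sampling. Debris and doublet events are injected at
configurable rates with aberrant scatter values.

What the synthetic data does *not* emulate: instrument-specific spectral
overlap beyond the configured linear spillover, autofluorescence drift,
density-dependent growth-rate changes, apoptosis, or peak shape beyond
log-normal. Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated statistical structure, not robustness
to every artifact of real acquisitions.

## Numerical and interface choices

* CSV is the canonical event interchange (columns `event_id`, `FSC-A`,
  `FSC-H`, `SSC-A`, then one column per fluorescence channel named by its
  filter, e.g. `FL_525_40`); FCS input is not implemented and raises
  cleanly. Numbers serialize with 9 significant digits; two runs with the
  same seed produce byte-identical outputs, and a run manifest (config
  hash, seed, version) accompanies every pipeline run.
* Replicator weights are computed with growth-rate exponents centred on
  their maximum before exponentiation, so century-long horizons do not
  overflow.
* Problem sizes used by the verification runs: 10⁵-event samples for
  composition recovery (binomial SE ≈ 0.13 points at a 22.7 % fraction),
  20 replicate bioreactor simulations for growth/lag recovery, 20 000
  events per sample in pipeline runs.

## Known limitations

* The broken-stick lag is resolved only to the sampling grid; a lag between
  sample times biases the breakpoint to a neighboring grid point.
* The two-point rate estimator inherits the coarse-grid bias described
  above; it is reported as-is, not corrected.
* Centroid gating assumes roughly isotropic clusters in log space; heavily
  skewed or overlapping clusters would need the (supported) rectangular
  gates or an external clustering step.
* Octant gating cannot see heterogeneity *within* an octant; the variant
  clone is only distinguishable from its host octant through intensity
  histograms or the normalized cube coordinates, not through the octant
  fraction table alone.
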