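# chromapop

Quantification of cell-population heterogeneity dynamics in CHO cultures
whose sub-populations carry stably integrated fluorescent-protein markers
(lentiviral "RGB" barcoding). The package is aimed at bioprocess engineers
and cytometry analysts who track how marked sub-populations shift during
long-term passaging or in mixed cultures, and who relate those shifts to
bulk culture kinetics.

## What it computes

**Event-level cytometry processing.** Debris is excluded on SSC-A vs FSC-A,
doublets on the FSC-H/FSC-A ratio. Spillover is removed by ordered linear
compensation (e.g. Venus′ = Venus − 0.15·mCherry, then Cerulean′ =
Cerulean − 0.039·Venus′). Intensities are mapped onto the unit cube with a
bounded log normalization between per-channel boundaries *I*\_lower and
*I*\_upper:

&nbsp;&nbsp;&nbsp;&nbsp;*I*\_norm = (log *I* − log *I*\_lower) / (log *I*\_upper − log *I*\_lower)

clipped to [0, 1] (the descending complement is available behind a flag).

**Gating.** Three-color panels are gated into 2³ = 8 octants (none, R, G, B,
RG, GB, BR, RGB) by strict positivity thresholds per channel; four
singly-marked populations on a two-filter panel are assigned by nearest
centroid in log₁₀-intensity space. Population sizes are fractions of
retained (singlet, debris-free) events; marginal per-channel positive
percentages are also reported.

**Population dynamics.** For a fraction time series the *total* change of a
population is mean(final window) − mean(baseline window) in percentage
points; the *individual* change is 100 · total / baseline. The sum of
absolute total changes summarizes a composition shift in one number.
Per-population viable densities (total *X*_v × fraction) are fitted with a
broken-stick model on log density — a flat lag segment followed by a line of
slope *μ*, with the breakpoint searched over the sampling grid — yielding
(lag, *μ*) per population.

**Kinetics.** Cell-specific rates from two-point differences, e.g.

&nbsp;&nbsp;&nbsp;&nbsp;*q*\_Glc(*t*ᵢ, *t*ᵢ₊₁) = (*c*\_Glc,ᵢ − *c*\_Glc,ᵢ₊₁)/(*t*ᵢ₊₁ − *t*ᵢ) · 2/(*X*\_v,ᵢ + *X*\_v,ᵢ₊₁)

with the mirrored sign for production (lactate, antibody), passage-aware
interval handling, and relative-change summaries in both the delta and the
percent-of-start convention.

**Synthetic data.** A generator reproduces the statistical structure of both
experiment designs — Poisson per-vector copy numbers with additive
log-normal per-copy intensities, multinomial event sampling at a configured
composition (with debris/doublet contamination), exact replicator
composition dynamics under repeated-batch passaging, delayed-exponential
growth with population-specific lags, and trapezoidal forward integration
of bulk metabolites — so every analysis stage can be tested against known
ground truth.

## Worked example

Simulate the mixed-growth-phase bioreactor design (four populations pooled
at 0.25·10⁶ cells ml⁻¹ each, lags 3/13/15/18 h, common *μ* = 0.037 h⁻¹,
hourly sampling for 48 h, 5 % measurement noise, 20 000 events per sample)
and analyze it end to end:

```python
from chromapop.presets import case2_config
from chromapop.pipeline import run_case2

res = run_case2(case2_config("afc", seed=1), mode="afc")
print(res["growth_fits"].to_string(index=False))
```

```
population  lag_h  mu_per_h      rss
  Cerulean    3.0  0.038559 0.168124
     Venus   19.0  0.041770 0.170641
  mOrange2   12.0  0.036939 0.200239
   mTagBFP   15.0  0.037670 0.232361
```

The fitted lags recover the configured 3/13/15/18 h pattern to within the
hourly grid and the slopes scatter around the common 0.037 h⁻¹. The change
table from the same run:

```
population  baseline_pct  total_change_pts  individual_change_pct  sum_abs_changes_pts
  Cerulean     25.583333          9.751667              38.117264            19.503333
     Venus     24.638333         -4.713333             -19.130082            19.503333
  mOrange2     25.266667         -2.313333              -9.155673            19.503333
   mTagBFP     24.511667         -2.725000             -11.117155            19.503333
```

i.e. the population with the shortest lag gains ~10 percentage points of
the culture within 48 h while the stationary-phase-derived population loses
~5 points (−19 % of its own starting share); the composition shift sums to
~20 points.

The same machinery runs from the shell:

```
chromapop simulate-case2 --mode afc --seed 1 --out runs/afc
chromapop simulate-case1 --seed 1 --out runs/case1
chromapop gate events.csv --panel case1 --out populations.csv
chromapop rates culture.csv --analyte c_Glc --out rates.csv
```

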