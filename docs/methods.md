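# Methods

## Scope and model

`deqsyn` quantifies drug-drug interaction in cell-viability assays against
the two classical additivity references. Loewe additivity treats a
combination as a dilution problem — a drug mixed with itself is exactly
additive — and is operationalized through dose-equivalent (DEQ) mixture
designs and the Combination Index. Bliss independence treats each drug's
effect as an independent probabilistic event and is operationalized
through full-dose checkerboard (or band) designs and the Bliss Index /
excess over Bliss. The two references answer different questions and
disagree in general (see "Loewe vs Bliss" below); both are implemented so
a pair can be scored by whichever its curves support.

## Dose-response model

Viability v as a function of log10 molar dose x follows the
variable-slope four-parameter logistic

    v(x) = bottom + (top - bottom) / (1 + 10^((x - log_ec50) * hill)),

with hill > 0 meaning viability falls with dose and
v(log_ec50) = (top + bottom)/2 identically. Fitting is nonlinear least
squares on all replicate wells jointly (unweighted), with five optimizer
starts spreading the initial log EC50 across the dose range and the
lowest-RSS solution kept. Box constraints: top in [0.5, 1.5], bottom in
[-0.1, 1.0], hill in [0.05, 10], log EC50 within 2 log units of the
ladder. A fit is flagged non-converged — never silently dropped — when
the optimizer fails or the fitted log EC50 leaves the window
[min dose - 1, max dose + 1], where the estimate is no longer supported
by data. Near-flat data can still converge to a shallow low-amplitude
curve; downstream code therefore also gates on maximal effect, not only
on the convergence flag.

### Parallelism gate

Linear isobologram analysis assumes approximately parallel curves with
comparable maximal effects. The gate requires, in order: each drug's
maximal effect (top - bottom) >= 0.5; Hill-slope ratio within [1/2, 2];
maximal-effect gap <= 0.2. These numerical cutoffs implement a
qualitative requirement and are configurable; a failing pair raises with
advice to use Bliss independence instead (overridable).

## Normalization

Viability = luminescence / max(luminescence of untreated wells in the
same plate x experiment group). The maximum (not mean) follows the
assay's stated rule; grouping per plate x experiment prevents scale
leakage across plates. Viability is deliberately not clipped here — wells
brighter than the reference keep values > 1, preserving information for
fitting; clipping to effects in [0, 1] happens only in the Bliss module.

A consequence worth knowing: the maximum of n noisy untreated wells is
biased above the true scale (about +4% for n = 3 at 5% CV), so all
viabilities are slightly deflated and weak effects slightly inflated.
This barely moves EC50s (a common multiplicative factor is absorbed by
top/bottom) but visibly skews the Bliss Index upward at weak-effect dose
pairs, where BI is a ratio of two small numbers. The test suite
demonstrates both facts: Bliss statistics are exactly calibrated given
correctly scaled viabilities, while the max-rule reference shifts per-run
grid-median BI by a few percent.

## DEQ design

- Grid: integer multiples of 1/3 log10 (which include the integer
  decades). Snapping minimizes |grid - log EC50|, ties toward the lower
  (more negative) dose — conservative, keeping more of the curve top.
- Ladder: 10 points from anchor - 7/3 to anchor + 2/3, i.e. the anchor is
  the 8th point. The asymmetric placement matches the reference dosing
  tables this design emulates; offsets are configurable. Doses are
  computed from integer thirds so band shifts never accumulate float
  drift, and render at two decimals (-8.67 style).
- Mixture fractions follow the integer-microliter pipetting volumes
  (0.80/0.20, 0.66/0.34, 0.50/0.50, ...), not exact thirds, because the
  physical experiment pipettes integer volumes.
- Bliss bands: drug B's ladder held constant, drug A's shifted one grid
  step up (2:1) or down (1:2); full doses, no volume reduction.

## Combination Index

Mixture curves are fitted on each drug's *nominal* ladder axis (the full
ladder dose, as plated), and the fitted EC50 is multiplied by the drug's
volume fraction afterwards; this is mathematically identical to fitting
on delivered dose and matches how the corrected-contribution tables are
produced. CI = sum of fraction-corrected contributions over single-agent
EC50s. Classification: synergy < 0.8, additive 0.8-1.2 (boundaries
inclusive), antagonism > 1.2. Per-ratio CI is reported along with mean
+/- sd across ratios; per-experiment CIs are available on request
(`per_experiment=True`).

For three drugs, the 1:1 pair is a pseudo-drug. It has no molar
concentration, so its dose axis is position-indexed and reported on the
first pair member's nominal molar axis; both CI terms involving the pair
use that same axis, so the arbitrary choice cancels exactly. The
independent three-term CI uses single-agent alone EC50s for all three
denominators; a variant using the first pair member's 50:50-pair EC50 as
its denominator is exposed behind `use_pair_context_denominator` for
comparability with analyses that define it that way (the two coincide on
additive surfaces).

## Bliss scoring

Effects are clipped to [0, 1] before any Bliss arithmetic (viability
above the reference becomes effect 0, never negative), replicate
viabilities are averaged per condition across technical replicates and
experiments before effect conversion, and BI at zero actual effect is an
NaN sentinel excluded from masks and summaries. The synergy call
threshold defaults to 0.85 (the operational heatmap cutoff), with BI < 1
being nominal synergy; both are configurable.

### Loewe vs Bliss

For a drug paired with its own twin (exact Loewe additivity), the
combination viability equals the single-agent curve at the summed dose.
Scored against Bliss, that surface yields at the EC50/EC50 cell
BI = 0.75 / (2^h / (1 + 2^h)): above 1 for Hill slope h < log2(3) ≈ 1.585
(Loewe-additive looks Bliss-antagonistic) and below 1 for steeper curves.
The sign of the disagreement between references is slope-dependent; tests
pin the closed form at h = 1 and h = 2.

## Synthetic data

The generator emulates the target assay: inner 60 wells of 96-well
plates, 10-point 1/3-log ladders, 3 technical replicates, 3 independent
experiments, untreated controls on every plate, CellTiter-Glo-like
luminescence.

- Surfaces: Loewe viability solves sum_i d_i / D_i(v) = 1 by bisection
  (tolerance 1e-12; D_i(v) from the inverse 4PL). When a partner pushes
  the effect below another drug's floor the well is clamped to the
  boundary effect with a warning. Bliss viability is the survival product
  1 - (1 - prod_i (1 - E_i)) with clipped effects.
- Synergy injection: delivered doses multiplied by (1 + alpha), applied
  only in wells containing >= 2 drugs (so marginals are untouched and the
  interaction is invisible except to combination analysis), optionally
  confined to a per-drug log-dose window to emulate regional synergy.
  This is one simple monotone mechanism among many possible ones.
- Noise: multiplicative lognormal with unit mean, parameterized by CV
  (default 10% per well) — luminescence is positive and heteroscedastic —
  plus a lognormal per-experiment scale factor (default 5% CV) emulating
  independent experiments; per-plate normalization absorbs it.
- Layout: all wells of one dose-response arm are placed on a single plate
  whenever the arm fits, as in real experiments, so plate-scale error
  shifts whole curves (absorbed by top/bottom) rather than distorting
  their shape.
- Determinism: a single seeded generator; outputs are bit-reproducible
  given (config, seed).

### Default drug panel in tests

The standard two-drug test panel uses anchors -8.67 / -5.67 (nM- and
uM-scale inhibitors) with Hill slopes 1.8 and 1.5. Slopes >= ~1.5 are the
regime in which the 7-below/2-above ladder actually represents both
plateaus, which the emulated assay design requires of its drugs; with
slopes near 1 the bottom plateau falls outside the ladder, EC50 variance
grows markedly, and per-ratio CI dispersion under 10% noise widens beyond
the additive call band more often. Simulated viabilities use top = 1,
bottom = 0 unless a test exercises partial-efficacy behavior.

## What passing tests do and do not show

The simulator shares the 4PL functional form with the fitter, so
parameter-recovery results show correctness of the estimation machinery,
not robustness to model misspecification (biphasic curves, edge effects,
drift, pipetting error are not simulated). Loewe/Bliss oracle surfaces
validate the analysis pipelines against independent closed forms or
root-finding, end to end through plate generation, normalization and
fitting. Conclusions about real plates depend additionally on assay
behavior the generator does not emulate.

## Known limitations

- No 5PL/biphasic models, no bootstrap or profile confidence intervals on
  EC50 or CI.
- No Chou-Talalay Fa-CI curves, no ZIP/HSA scores, no curved isoboles for
  non-constant potency ratios.
- Bliss analysis assumes marginal wells exist at every combination dose
  (matched within 1e-6 log units); it does not interpolate marginals.
- The three-drug analysis reproduces the fixed (1+1):k volume designs; it
  does not search ratio space.
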