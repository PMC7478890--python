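# deqsyn

Dose-equivalent drug-combination synergy analysis for plate-reader
viability assays.

`deqsyn` is for scientists quantifying whether two (or three) inhibitors
kill cells better together than expected — the workflow behind
isobologram and Bliss-independence panels in combination-therapy papers:
CellTiter-Glo-style luminescence plates, 10-point 1/3-log dose ladders,
fixed-volume-ratio drug mixtures, three technical replicates across three
independent experiments.

## What it computes

**Dose-response fitting.** Viability is normalized to the maximum
luminescence of untreated wells (per plate × experiment) and fitted with
the variable-slope four-parameter logistic

v(x) = bottom + (top − bottom) / (1 + 10^((x − log EC50) · h))

where x is log10 molar dose and h the Hill slope (h > 0: viability
decreases with dose).

**DEQ design.** Each drug's fitted log EC50 is snapped to the nearest
1/3-log grid point (ties toward the lower dose) and a 10-point ladder is
placed 7 steps below to 2 steps above the anchor. Ladder position i then
delivers an equipotent dose of every drug, so mixtures at fixed volume
ratios (4:1 → 0.80/0.20, 2:1 → 0.66/0.34, 1:1, 1:2, 1:4) have a
predictable composite potency under additivity.

**Isobologram / Combination Index (Loewe additivity).** Each mixture's
curve is fitted on each drug's nominal dose axis; the fitted EC50 times
the drug's volume fraction is that drug's contribution to the mixture
EC50. Then

CI = EC50_A,mix / EC50_A,alone + EC50_B,mix / EC50_B,alone

with CI < 0.8 synergy, 0.8–1.2 additive, > 1.2 antagonism. Isobole points
(one per ratio) sum to CI, so synergy falls below the x + y = 1 line.

**Bliss independence.** With effect E = clip(1 − viability, 0, 1), the
expected effect of independent drugs is E_A + E_B − E_A·E_B. The Bliss
Index BI = expected/actual (< 1 nominal synergy; heatmaps call synergy at
BI < 0.85) and excess over Bliss = 100·(actual − expected) percentage
points. Bliss designs deliver full doses of both drugs, either a 10 × 10
matrix or three dose-equivalent bands (one drug shifted ±1/3 log).

**Three-drug extension.** A 1:1 DEQ pair is treated as a pseudo-drug and
combined with a third inhibitor at (1+1):1, (1+1):2, (1+1):4 volume
ratios (33/33/34, 25/25/50, 17/17/66 µL per 100 µL). Two CI families are
reported: the third drug against the pair-as-single-agent, and the fully
independent three-term CI.

**Synthetic plates.** A generator produces well-level plate tables with
known ground truth — 4PL single agents combined under Loewe or Bliss
reference surfaces, optional synergy injection (dose potentiation in
combination wells only, optionally confined to a dose window),
multiplicative lognormal well noise and per-experiment scale factors — so
every analysis stage is testable end to end without any lab data.

## Worked example

`examples/03_isobologram.py` simulates a DEQ experiment for an exactly
additive pair and for the same pair with a 60% synergy boost, then runs
the full analysis:

```
additive surface
  alone EC50s: 2.16 nM, 2.13 uM
  4:1: CI = 1.01  (additive)
  2:1: CI = 0.98  (additive)
  1:1: CI = 1.01  (additive)
  1:2: CI = 0.98  (additive)
  1:4: CI = 1.01  (additive)
  mean +/- sd across ratios: 1.00 +/- 0.02

synergistic (alpha=0.6) surface
  4:1: CI = 0.64  (synergy)
  ...
  mean +/- sd across ratios: 0.62 +/- 0.01
```

On the additive surface every ratio's CI is within noise of 1; the
boosted surface drops CI to ≈ 1/1.6, well below the 0.8 synergy cutoff.
The other examples cover single-agent fitting, DEQ design construction,
Bliss matrices with a localized synergy window, and the three-drug CI
families.

A thin CLI mirrors the library (`deqsyn fit | design | isobologram |
bliss | threedrug | simulate`); run `deqsyn --help`.

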