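"""Three-drug vertical-inhibition analysis.

A 1:1 DEQ pair is treated as a pseudo-drug and a third inhibitor is mixed
with it at (1+1):1, (1+1):2 and (1+1):4 volume ratios. On an exactly
additive Loewe surface both CI families (vs the pair, and fully
independent) should be ~1; lower values would indicate that the third drug
deepens synergy beyond the pair.
"""

from deqsyn import (
    DrugParams, SimulationConfig, ThreeDrugDesign, analyze_three_drug,
    build_ladder, normalize_viability, simulate_combination,
)

drugs = {"osi-like": DrugParams("osi-like", log_ec50=-8.67, hill=1.8),
         "bay-like": DrugParams("bay-like", log_ec50=-5.67, hill=1.5),
         "rmc-like": DrugParams("rmc-like", log_ec50=-6.67, hill=1.6)}
ladders = {n: build_ladder(p.log_ec50, drug=n) for n, p in drugs.items()}
design = ThreeDrugDesign(pair=("osi-like", "bay-like"), third="rmc-like",
                         ladders=ladders)

config = SimulationConfig(drugs=drugs, reference_model="loewe",
                          noise_cv=0.05, seed=3)
table = normalize_viability(simulate_combination(config, design))
result = analyze_three_drug(table, design)

print("pair baseline EC50 on osi-like axis:",
      f"{result.baseline_pair_ec50 * 1e9:.2f} nM")
print(f"{'mix':>8}  {'CI vs pair':>10}  {'CI independent':>14}")
for label, m in result.mixes.items():
    print(f"{label:>8}  {m.ci_vs_pair:>10.2f}  {m.ci_independent:>14.2f}")
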