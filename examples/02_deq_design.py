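"""Build a dose-equivalent (DEQ) mixture design from two fitted EC50s.

Starting from fitted log EC50s of -8.57 and -5.73 (log10 molar), each value
is snapped to the nearest 1/3-log grid point, a 10-point ladder is placed
around each anchor (7 points below, 2 above), and the five standard
volume-ratio mixtures are planned. Position i of each ladder delivers an
equipotent dose of either drug, so mixing by volume preserves expected
potency under additivity.
"""

from deqsyn import make_deq_design, snap_to_grid

print("snap -8.57 ->", round(snap_to_grid(-8.57), 2))
print("snap -5.73 ->", round(snap_to_grid(-5.73), 2))

design = make_deq_design("osimertinib", -8.57, "BAY-293", -5.73)
print("\nladder A (osimertinib):", " ".join(design.ladder_a.formatted()))
print("ladder B (BAY-293)    :", " ".join(design.ladder_b.formatted()))
print("\nmixture volume fractions (drug A, drug B):")
for spec in design.mixtures:
    print(f"  {spec.ratio_label:>3}: ({spec.fraction_a:.2f}, {spec.fraction_b:.2f})")
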