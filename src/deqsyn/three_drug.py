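"""Three-drug vertical-inhibition isobologram analysis.

A 1:1 DEQ mixture of two drugs is treated as a single pseudo-drug and the
third drug is combined with it at (1+1):1, (1+1):2 and (1+1):4 volume
ratios (33/33/34, 25/25/50, 17/17/66 uL per 100 uL). Two CI families are
computed per mix:

* CI vs the pair — the pair's fraction-corrected contribution relative to
  the EC50 of the 50:50 pair treated as a single agent, plus the third
  drug's contribution relative to its alone EC50. Values below the
  two-drug CI indicate that adding the third drug deepens synergy.
* independent CI — three terms, one per drug, each drug's fraction-
  corrected nominal-axis EC50 over its own single-agent EC50.

The pseudo-drug has no molar concentration of its own; its dose axis is
ladder-position-indexed and reported on the first pair member's nominal
molar axis. Both CI terms involving the pair use that same axis, so the
arbitrary choice cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .deq_design import DoseLadder
from .isobologram import classify_ci, combination_index, fit_axis, fractional_ec50
from .plate_io import PlateTable

#: Volume triples (pair member, pair member, third drug) in uL per 100 uL.
THREE_DRUG_VOLUMES: dict[str, tuple[int, int, int]] = {
    "(1+1):1": (33, 33, 34),
    "(1+1):2": (25, 25, 50),
    "(1+1):4": (17, 17, 66),
}


@dataclass(frozen=True)
class ThreeDrugDesign:
    """Dosing plan for one pair-plus-third-drug experiment."""

    pair: tuple[str, str]
    third: str
    ladders: dict[str, DoseLadder]
    mixes: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(THREE_DRUG_VOLUMES)
    )

    def __post_init__(self):
        for name in (*self.pair, self.third):
            if name not in self.ladders:
                raise ValueError(f"missing ladder for drug {name!r}")
        for label, (va, vb, vc) in self.mixes.items():
            if va + vb + vc != 100:
                raise ValueError(f"mix {label!r} volumes must sum to 100")
            if va != vb:
                raise ValueError(f"mix {label!r} pair components must be equal")


def three_drug_ci_vs_pair(
    pair_contrib: float,
    pair_ec50_5050: float,
    third_contrib: float,
    third_ec50_alone: float,
) -> float:
    """CI of the third drug against the 1:1 pair treated as one agent."""
    if pair_ec50_5050 <= 0 or third_ec50_alone <= 0:
        raise ValueError("denominator EC50s must be positive")
    return pair_contrib / pair_ec50_5050 + third_contrib / third_ec50_alone


def three_drug_ci_independent(contribs, alone_ec50s) -> float:
    """Three-term CI with each drug considered independently."""
    contribs = list(contribs)
    alones = list(alone_ec50s)
    if len(contribs) != 3 or len(alones) != 3:
        raise ValueError("need exactly three contributions and three alone EC50s")
    if any(a <= 0 for a in alones):
        raise ValueError("alone EC50s must be positive")
    return sum(c / a for c, a in zip(contribs, alones))


@dataclass
class MixResult:
    """Per-mix fitted quantities (all EC50s molar on nominal axes)."""

    label: str
    pair_fraction: float
    third_fraction: float
    pair_contrib: float
    third_contrib: float
    contribs: tuple[float, float, float]
    ci_vs_pair: float
    ci_independent: float
    class_vs_pair: str
    class_independent: str
    isobole_point: tuple[float, float]


@dataclass
class ThreeDrugResult:
    pair: tuple[str, str]
    third: str
    baseline_pair_ec50: float
    alone_ec50s: dict[str, float]
    mixes: dict[str, MixResult]

    @property
    def ci_vs_pair(self) -> dict[str, float]:
        return {k: m.ci_vs_pair for k, m in self.mixes.items()}

    @property
    def ci_independent(self) -> dict[str, float]:
        return {k: m.ci_independent for k, m in self.mixes.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mix": m.label,
                    "ci_vs_pair": m.ci_vs_pair,
                    "ci_independent": m.ci_independent,
                    "class_vs_pair": m.class_vs_pair,
                    "class_independent": m.class_independent,
                }
                for m in self.mixes.values()
            ]
        )


def _alone_fit(df, drug: str, axis: str):
    col, dose = f"drug_{axis}", f"log_dose_{axis}"
    others = [c for c in ("log_dose_a", "log_dose_b", "log_dose_c") if c != dose]
    mask = (df["ratio_label"] == "alone") & (df[col] == drug) & df[dose].notna()
    for o in others:
        mask &= df[o].isna()
    fit = fit_axis(df.loc[mask], dose, f"{drug} alone")
    if not fit.converged:
        raise ValueError(
            f"single-agent fit for {drug!r} did not converge (flat or "
            "out-of-range curve); cannot report a CI against it"
        )
    return fit


def analyze_three_drug(
    table: PlateTable,
    design: ThreeDrugDesign,
    use_pair_context_denominator: bool = False,
) -> ThreeDrugResult:
    """Fit all arms of a three-drug plan and compute both CI families.

    ``use_pair_context_denominator`` switches the first term of the
    independent CI to use the first pair member's EC50 as fitted within the
    50:50 pair (instead of its single-agent EC50); the default uses
    single-agent EC50s for all three denominators.

    Raises
    ------
    ValueError
        Table not normalized, a missing arm (named), or a non-converging
        single-agent fit (e.g. an inert drug), which would make the CI
        meaningless.
    """
    if not table.normalized:
        raise ValueError("table must be normalized before analysis")
    df = table.df
    a, b = design.pair
    c = design.third

    fit_a = _alone_fit(df, a, "a")
    fit_b = _alone_fit(df, b, "b")
    fit_c = _alone_fit(df, c, "c")
    alone = {a: fit_a.ec50_molar, b: fit_b.ec50_molar, c: fit_c.ec50_molar}

    pair_rows = df[
        (df["ratio_label"] == "1:1") & (df["drug_a"] == a) & (df["drug_b"] == b)
        & df["log_dose_c"].isna()
    ]
    if pair_rows.empty:
        raise ValueError(f"missing 1:1 pair baseline arm for ({a}, {b})")
    pair_fit_a = fit_axis(pair_rows, "log_dose_a", f"{a}+{b} 50:50|{a}-axis")
    pair_ec50_5050 = pair_fit_a.ec50_molar

    mixes: dict[str, MixResult] = {}
    for label, (va, vb, vc) in design.mixes.items():
        rows = df[
            (df["ratio_label"] == label) & (df["drug_a"] == a)
            & (df["drug_b"] == b) & (df["drug_c"] == c)
        ]
        if rows.empty:
            raise ValueError(f"missing three-drug arm {label!r}")
        f_pair = (va + vb) / 100.0
        f_third = vc / 100.0
        mix_on_a = fit_axis(rows, "log_dose_a", f"{label}|{a}-axis").ec50_molar
        mix_on_b = fit_axis(rows, "log_dose_b", f"{label}|{b}-axis").ec50_molar
        mix_on_c = fit_axis(rows, "log_dose_c", f"{label}|{c}-axis").ec50_molar

        pair_contrib = fractional_ec50(mix_on_a, f_pair)
        third_contrib = fractional_ec50(mix_on_c, f_third)
        ci_pair = three_drug_ci_vs_pair(
            pair_contrib, pair_ec50_5050, third_contrib, alone[c]
        )

        contribs = (
            fractional_ec50(mix_on_a, va / 100.0),
            fractional_ec50(mix_on_b, vb / 100.0),
            third_contrib,
        )
        denom_a = pair_ec50_5050 if use_pair_context_denominator else alone[a]
        ci_ind = three_drug_ci_independent(contribs, (denom_a, alone[b], alone[c]))

        mixes[label] = MixResult(
            label=label,
            pair_fraction=f_pair,
            third_fraction=f_third,
            pair_contrib=pair_contrib,
            third_contrib=third_contrib,
            contribs=contribs,
            ci_vs_pair=ci_pair,
            ci_independent=ci_ind,
            class_vs_pair=classify_ci(ci_pair),
            class_independent=classify_ci(ci_ind),
            isobole_point=(pair_contrib / pair_ec50_5050, third_contrib / alone[c]),
        )

    return ThreeDrugResult(
        pair=design.pair,
        third=c,
        baseline_pair_ec50=pair_ec50_5050,
        alone_ec50s=alone,
        mixes=mixes,
    )
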