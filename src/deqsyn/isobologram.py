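"""Loewe-additivity isobologram analysis of DEQ mixture plates.

Each fixed-ratio mixture's dose-response is fitted twice, once on each
drug's nominal ladder axis. The fitted EC50 is then multiplied by that
drug's volume fraction in the mixture to give its contribution to the
mixture EC50 (the "fractional EC50"). The Combination Index is

    CI = EC50_A,mix / EC50_A,alone + EC50_B,mix / EC50_B,alone

where the numerators are the fraction-corrected contributions. CI < 0.8
calls synergy, 0.8-1.2 additivity, > 1.2 antagonism. Isobole points
(contrib_A / alone_A, contrib_B / alone_B) sum to CI, so synergistic
mixtures fall below the line x + y = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deq_design import DeqDesign
from .dose_response import DoseResponseFit, ParallelismVerdict, fit_4pl, parallelism_gate
from .plate_io import PlateTable

SYNERGY_CI = 0.8
ANTAGONISM_CI = 1.2


def fractional_ec50(mixture_fit_ec50: float, fraction: float) -> float:
    """Correct a nominal-axis mixture EC50 by the drug's volume fraction.

    A 4:1 mixture is 80% drug A by volume, so drug A's contribution to the
    mixture EC50 is 0.8 x the EC50 fitted on A's nominal dose axis.
    """
    if mixture_fit_ec50 <= 0:
        raise ValueError("EC50 must be positive")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * mixture_fit_ec50


def combination_index(
    contrib_a: float, contrib_b: float, ec50_a_alone: float, ec50_b_alone: float
) -> float:
    """Loewe Combination Index from fraction-corrected contributions."""
    if ec50_a_alone <= 0 or ec50_b_alone <= 0:
        raise ValueError("single-agent EC50s must be positive")
    if contrib_a < 0 or contrib_b < 0:
        raise ValueError("contributions must be nonnegative")
    return contrib_a / ec50_a_alone + contrib_b / ec50_b_alone


def classify_ci(
    ci: float, synergy_below: float = SYNERGY_CI, antagonism_above: float = ANTAGONISM_CI
) -> str:
    """Classify a CI: synergy (< 0.8), additive (0.8-1.2), antagonism (> 1.2).

    Boundaries are inclusive to the additive band.
    """
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < synergy_below:
        return "synergy"
    if ci > antagonism_above:
        return "antagonism"
    return "additive"


@dataclass
class RatioResult:
    """Per-mixture-ratio isobologram quantities (EC50s in molar)."""

    ratio_label: str
    fraction_a: float
    fraction_b: float
    mixture_ec50_a: float
    mixture_ec50_b: float
    contrib_a: float
    contrib_b: float
    ci: float
    synergy_class: str
    isobole_point: tuple[float, float]
    ci_by_experiment: dict[int, float] | None = None


@dataclass
class IsobologramResult:
    drug_a: str
    drug_b: str
    ec50_a_alone: float
    ec50_b_alone: float
    fit_a: DoseResponseFit
    fit_b: DoseResponseFit
    gate: ParallelismVerdict
    ratios: dict[str, RatioResult]
    ci_mean: float
    ci_sd: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ratio": r.ratio_label,
                "mixture_ec50_a": r.mixture_ec50_a,
                "mixture_ec50_b": r.mixture_ec50_b,
                "contrib_a": r.contrib_a,
                "contrib_b": r.contrib_b,
                "ci": r.ci,
                "synergy_class": r.synergy_class,
            }
            for r in self.ratios.values()
        ]
        return pd.DataFrame(rows)


def _single_agent_rows(df: pd.DataFrame, drug: str, axis: str) -> pd.DataFrame:
    col = f"drug_{axis}"
    dose = f"log_dose_{axis}"
    others = [c for c in ("log_dose_a", "log_dose_b", "log_dose_c") if c != dose]
    mask = (df["ratio_label"] == "alone") & (df[col] == drug) & df[dose].notna()
    for o in others:
        mask &= df[o].isna()
    return df.loc[mask]


def fit_axis(rows: pd.DataFrame, dose_col: str, label: str) -> DoseResponseFit:
    """Fit a 4PL to the viability of ``rows`` against one nominal dose axis."""
    if rows.empty:
        raise ValueError(f"no wells found for arm {label!r}")
    return fit_4pl(rows[dose_col].to_numpy(), rows["viability"].to_numpy(), drug=label)


def analyze_isobologram(
    table: PlateTable,
    design: DeqDesign,
    override_gate: bool = False,
    per_experiment: bool = False,
    synergy_below: float = SYNERGY_CI,
    antagonism_above: float = ANTAGONISM_CI,
) -> IsobologramResult:
    """Run the full isobologram analysis on a normalized DEQ plate table.

    Fits both single agents, checks the parallelism gate (similar Hill
    slopes and maximal effects), then per mixture ratio fits the composite
    curve on each drug's nominal axis, applies the volume-fraction
    correction, and computes CI, class, and isobole point. Set
    ``per_experiment`` to additionally compute a CI per independent
    experiment (reported per ratio alongside the pooled fit).

    Raises
    ------
    ValueError
        Table not normalized; a missing arm (named); or a failed
        parallelism gate without ``override_gate`` — in that case the pair
        should be scored by Bliss independence analysis instead.
    """
    if not table.normalized:
        raise ValueError("table must be normalized before analysis")
    df = table.df
    drug_a = design.ladder_a.drug
    drug_b = design.ladder_b.drug

    fit_a = fit_axis(_single_agent_rows(df, drug_a, "a"), "log_dose_a", drug_a)
    fit_b = fit_axis(_single_agent_rows(df, drug_b, "b"), "log_dose_b", drug_b)
    gate = parallelism_gate(fit_a, fit_b)
    if not gate.suitable_for_isobologram and not override_gate:
        raise ValueError(
            f"pair ({drug_a}, {drug_b}) failed the parallelism gate "
            f"({gate.reason}); use Bliss independence analysis instead, "
            "or pass override_gate=True"
        )

    ec50_a = fit_a.ec50_molar
    ec50_b = fit_b.ec50_molar

    ratios: dict[str, RatioResult] = {}
    for spec in design.mixtures:
        rows = df[
            (df["ratio_label"] == spec.ratio_label)
            & (df["drug_a"] == drug_a)
            & (df["drug_b"] == drug_b)
        ]
        if rows.empty:
            raise ValueError(f"missing mixture arm for ratio {spec.ratio_label!r}")
        mix_a = fit_axis(rows, "log_dose_a", f"{spec.ratio_label}|{drug_a}-axis")
        mix_b = fit_axis(rows, "log_dose_b", f"{spec.ratio_label}|{drug_b}-axis")
        m_a, m_b = mix_a.ec50_molar, mix_b.ec50_molar
        c_a = fractional_ec50(m_a, spec.fraction_a)
        c_b = fractional_ec50(m_b, spec.fraction_b)
        ci = combination_index(c_a, c_b, ec50_a, ec50_b)

        by_exp = None
        if per_experiment:
            by_exp = {}
            for exp, sub in rows.groupby("experiment"):
                try:
                    ea = fit_axis(sub, "log_dose_a", "").ec50_molar
                    eb = fit_axis(sub, "log_dose_b", "").ec50_molar
                except ValueError:
                    continue
                by_exp[int(exp)] = combination_index(
                    fractional_ec50(ea, spec.fraction_a),
                    fractional_ec50(eb, spec.fraction_b),
                    ec50_a,
                    ec50_b,
                )

        ratios[spec.ratio_label] = RatioResult(
            ratio_label=spec.ratio_label,
            fraction_a=spec.fraction_a,
            fraction_b=spec.fraction_b,
            mixture_ec50_a=m_a,
            mixture_ec50_b=m_b,
            contrib_a=c_a,
            contrib_b=c_b,
            ci=ci,
            synergy_class=classify_ci(ci, synergy_below, antagonism_above),
            isobole_point=(c_a / ec50_a, c_b / ec50_b),
            ci_by_experiment=by_exp,
        )

    cis = np.array([r.ci for r in ratios.values()])
    return IsobologramResult(
        drug_a=drug_a,
        drug_b=drug_b,
        ec50_a_alone=ec50_a,
        ec50_b_alone=ec50_b,
        fit_a=fit_a,
        fit_b=fit_b,
        gate=gate,
        ratios=ratios,
        ci_mean=float(cis.mean()),
        ci_sd=float(cis.std(ddof=1)) if len(cis) > 1 else 0.0,
    )
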