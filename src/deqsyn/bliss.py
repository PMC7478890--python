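"""Bliss independence analysis over dose matrices and DEQ bands.

Viability is converted to effect (E = 1 - viability, clipped to [0, 1]).
For two drugs acting as independent probabilistic events the expected
combined effect is E_A + E_B - E_A*E_B. The Bliss Index is
expected / actual (BI < 1 nominal synergy; heatmaps call synergy at
BI < 0.85), and excess over Bliss is 100 * (actual - expected) percentage
points (> 0 synergy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateTable

#: Operational synergy-call threshold used for heatmap masks. The nominal
#: criterion is BI < 1; calls use the stricter 0.85 cutoff.
SYNERGY_BI = 0.85


def effect_from_viability(viability):
    """Convert viability to effect: clip(1 - v, 0, 1).

    Viability above 1 (wells brighter than the untreated reference through
    noise) becomes effect 0, never negative.
    """
    v = np.asarray(viability, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("viability must be finite and nonnegative")
    e = np.clip(1.0 - v, 0.0, 1.0)
    return float(e) if np.isscalar(viability) else e


def _check_effects(*effects):
    for e in effects:
        arr = np.asarray(e, dtype=float)
        valid = np.isnan(arr) | ((arr >= 0) & (arr <= 1))
        if not np.all(valid):
            raise ValueError("effects must lie in [0, 1]")


def expected_bliss(e_a, e_b):
    """Expected effect of two independently acting drugs: EA + EB - EA*EB."""
    _check_effects(e_a, e_b)
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    out = e_a + e_b - e_a * e_b
    return float(out) if out.ndim == 0 else out


def bliss_index(e_a, e_b, e_mix):
    """Bliss Index: expected effect / actual effect; NaN where actual is 0.

    A BI of 1 means the combination did exactly what independence predicts;
    below 1 the combination overperformed (synergy). Wells with zero actual
    effect yield NaN and are excluded from summaries.
    """
    _check_effects(e_a, e_b, e_mix)
    expected = expected_bliss(e_a, e_b)
    e_mix = np.asarray(e_mix, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(e_mix > 0, np.asarray(expected) / e_mix, np.nan)
    return float(out) if out.ndim == 0 else out


def excess_over_bliss(e_a, e_b, e_mix):
    """Excess over Bliss in percentage points: 100 * (actual - expected)."""
    _check_effects(e_a, e_b, e_mix)
    out = 100.0 * (np.asarray(e_mix, dtype=float) - np.asarray(expected_bliss(e_a, e_b)))
    return float(out) if out.ndim == 0 else out


@dataclass
class BlissGrid:
    """Dose-combination grid of Bliss quantities.

    Matrices are indexed [i, j] = (doses_a[i], doses_b[j]); NaN marks
    combinations absent from the design (band layouts fill 3 diagonals of
    the full matrix).
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    effect_a: np.ndarray
    effect_b: np.ndarray
    effect_mix: np.ndarray
    expected: np.ndarray
    bliss_index: np.ndarray
    excess_over_bliss: np.ndarray
    synergy_mask: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.where(~np.isnan(self.effect_mix))
        return pd.DataFrame({
            "log_dose_a": self.doses_a[ii],
            "log_dose_b": self.doses_b[jj],
            "viability": self.viability[ii, jj],
            "effect_mix": self.effect_mix[ii, jj],
            "expected": self.expected[ii, jj],
            "bliss_index": self.bliss_index[ii, jj],
            "excess_over_bliss": self.excess_over_bliss[ii, jj],
            "synergy": self.synergy_mask[ii, jj],
        })


def _mean_by_dose(rows: pd.DataFrame, dose_col: str) -> dict[float, float]:
    return rows.groupby(dose_col)["viability"].mean().to_dict()


def _match_dose(dose: float, table: dict[float, float], drug: str, tol: float = 1e-6):
    for d, v in table.items():
        if abs(d - dose) <= tol:
            return v
    raise ValueError(
        f"grid point at log dose {dose:g} has no single-agent wells for {drug}"
    )


def analyze_bliss_matrix(
    table: PlateTable,
    drug_a: str,
    drug_b: str,
    threshold: float = SYNERGY_BI,
) -> BlissGrid:
    """Compute Bliss quantities over all (dose_a, dose_b) combinations.

    Replicate viabilities are averaged per condition (across technical
    replicates and experiments) before effect conversion. Every
    combination must have matching single-agent wells at both of its
    component doses. Works for full factorial matrices and for 3x10 band
    designs alike; absent combinations stay NaN.
    """
    if not table.normalized:
        raise ValueError("table must be normalized before analysis")
    df = table.df
    alone_a = df[
        (df["ratio_label"] == "alone") & (df["drug_a"] == drug_a)
        & df["log_dose_a"].notna() & df["log_dose_b"].isna() & df["log_dose_c"].isna()
    ]
    alone_b = df[
        (df["ratio_label"] == "alone") & (df["drug_b"] == drug_b)
        & df["log_dose_b"].notna() & df["log_dose_a"].isna() & df["log_dose_c"].isna()
    ]
    combos = df[
        (df["drug_a"] == drug_a) & (df["drug_b"] == drug_b)
        & df["log_dose_a"].notna() & df["log_dose_b"].notna() & df["log_dose_c"].isna()
    ]
    if combos.empty:
        raise ValueError(f"no combination wells for ({drug_a}, {drug_b})")

    v_a = _mean_by_dose(alone_a, "log_dose_a")
    v_b = _mean_by_dose(alone_b, "log_dose_b")
    v_mix = combos.groupby(["log_dose_a", "log_dose_b"])["viability"].mean()

    doses_a = np.array(sorted({da for da, _ in v_mix.index}))
    doses_b = np.array(sorted({db for _, db in v_mix.index}))
    shape = (len(doses_a), len(doses_b))
    viability = np.full(shape, np.nan)
    e_a_grid = np.full(shape, np.nan)
    e_b_grid = np.full(shape, np.nan)

    eff_a = np.array([effect_from_viability(_match_dose(d, v_a, drug_a)) for d in doses_a])
    eff_b = np.array([effect_from_viability(_match_dose(d, v_b, drug_b)) for d in doses_b])

    idx_a = {d: i for i, d in enumerate(doses_a)}
    idx_b = {d: j for j, d in enumerate(doses_b)}
    for (da, db), v in v_mix.items():
        i, j = idx_a[da], idx_b[db]
        viability[i, j] = v
        e_a_grid[i, j] = eff_a[i]
        e_b_grid[i, j] = eff_b[j]

    present = ~np.isnan(viability)
    effect_mix = np.full(shape, np.nan)
    effect_mix[present] = np.clip(1.0 - viability[present], 0.0, 1.0)
    expected = np.full(shape, np.nan)
    expected[present] = expected_bliss(e_a_grid[present], e_b_grid[present])
    with np.errstate(divide="ignore", invalid="ignore"):
        bi = np.where(effect_mix > 0, expected / effect_mix, np.nan)
    excess = 100.0 * (effect_mix - expected)
    mask = np.zeros(shape, dtype=bool)
    ok = ~np.isnan(bi)
    mask[ok] = bi[ok] < threshold

    return BlissGrid(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=doses_a,
        doses_b=doses_b,
        viability=viability,
        effect_a=eff_a,
        effect_b=eff_b,
        effect_mix=effect_mix,
        expected=expected,
        bliss_index=bi,
        excess_over_bliss=excess,
        synergy_mask=mask,
        threshold=threshold,
    )
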