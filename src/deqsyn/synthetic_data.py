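"""Synthetic viability-plate generator with known ground truth.

Emulates a CellTiter-Glo-style 96-well assay: the inner 60 wells of each
plate hold untreated controls plus treated conditions, three technical
replicates per condition, repeated across three independent experiments.
Expected viability comes from single-agent 4PL curves combined under a
chosen reference model (Loewe additivity or Bliss independence), with an
optional synergy boost; readings get multiplicative lognormal noise and a
per-experiment scale factor.

Under Loewe additivity the combined viability v solves

    sum_i d_i / D_i(v) = 1

where D_i(v) is the dose at which drug i alone yields viability v
(root-found by bisection). Under Bliss independence the combined effect is
1 - prod_i (1 - E_i) with E_i the clipped single-agent effects. Synergy is
injected by potentiating every delivered dose by (1 + alpha) in wells
containing two or more drugs — single-agent wells are never potentiated,
so the injected interaction is invisible to the marginals and must be
found by the synergy analysis itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deq_design import BlissMatrixDesign, DeqDesign, DoseLadder
from .dose_response import four_pl, inverse_four_pl
from .plate_io import REQUIRED_COLUMNS, PlateTable

_ROWS = "BCDEFG"
_COLS = range(2, 12)
INNER_WELLS = tuple(f"{r}{c}" for r in _ROWS for c in _COLS)

_UNTREATED_PER_PLATE = 3


@dataclass(frozen=True)
class DrugParams:
    """Ground-truth 4PL parameters of one simulated drug."""

    name: str
    log_ec50: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0

    def viability(self, log_dose: float) -> float:
        return float(four_pl(log_dose, self.top, self.bottom, self.log_ec50, self.hill))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment set.

    Defaults mirror the assay being emulated: three technical replicates,
    three independent experiments, 10% multiplicative noise on readings and
    a 5% experiment-to-experiment scale wobble.
    """

    drugs: dict[str, DrugParams]
    reference_model: str = "loewe"
    synergy_alpha: float = 0.0
    synergy_window: dict[str, tuple[float, float]] | None = None
    noise_cv: float = 0.1
    n_technical: int = 3
    n_experiments: int = 3
    experiment_cv: float = 0.05
    untreated_lum_mean: float = 1.0e6
    seed: int = 0

    def __post_init__(self):
        if self.reference_model not in ("loewe", "bliss"):
            raise ValueError("reference_model must be 'loewe' or 'bliss'")
        if self.synergy_alpha < 0 or self.noise_cv < 0 or self.experiment_cv < 0:
            raise ValueError("synergy_alpha, noise_cv, experiment_cv must be >= 0")


def loewe_viability(
    delivered: dict[str, float], drugs: dict[str, DrugParams], tol: float = 1e-12
) -> float:
    """Expected viability under Loewe additivity for molar doses ``delivered``.

    Solves sum_i d_i / D_i(v) = 1 by bisection on v. If the dose total lies
    outside the effect range both agents can reach (possible when bottoms
    differ from 0), the nearer boundary viability is returned with a
    warning rather than raising.
    """
    doses = {k: d for k, d in delivered.items() if d > 0}
    if not doses:
        return 1.0
    params = [drugs[k] for k in doses]
    if len(doses) == 1:
        (name, d), = doses.items()
        return float(four_pl(np.log10(d), params[0].top, params[0].bottom,
                             params[0].log_ec50, params[0].hill))

    v_hi = min(p.top for p in params)
    v_lo = max(p.bottom for p in params)

    def total(v: float) -> float:
        s = 0.0
        for (name, d), p in zip(doses.items(), params):
            iso = 10.0 ** inverse_four_pl(v, p.top, p.bottom, p.log_ec50, p.hill)
            s += d / iso
        return s

    eps = 1e-12 * max(1.0, v_hi - v_lo)
    lo, hi = v_lo + eps, v_hi - eps
    # total(v) increases toward v_hi (iso-effective doses shrink to 0)
    if total(hi) < 1.0:
        warnings.warn("Loewe root outside effect range; clamping to weakest effect")
        return hi
    if total(lo) > 1.0:
        warnings.warn("Loewe root outside effect range; clamping to maximal effect")
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if total(mid) > 1.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bliss_viability(delivered: dict[str, float], drugs: dict[str, DrugParams]) -> float:
    """Expected viability under Bliss independence (inclusion-exclusion)."""
    survive = 1.0
    for name, d in delivered.items():
        if d <= 0:
            continue
        p = drugs[name]
        v = p.viability(np.log10(d))
        effect = min(max(1.0 - v, 0.0), 1.0)
        survive *= 1.0 - effect
    return survive


def expected_viability(config: SimulationConfig, delivered: dict[str, float]) -> float:
    """Ground-truth expected viability of one well, synergy boost included."""
    doses = {k: d for k, d in delivered.items() if d > 0}
    if len(doses) >= 2 and config.synergy_alpha > 0 and _in_window(config, doses):
        doses = {k: d * (1.0 + config.synergy_alpha) for k, d in doses.items()}
    if config.reference_model == "loewe":
        return loewe_viability(doses, config.drugs)
    return bliss_viability(doses, config.drugs)


def _in_window(config: SimulationConfig, doses: dict[str, float]) -> bool:
    if config.synergy_window is None:
        return True
    for name, d in doses.items():
        win = config.synergy_window.get(name)
        if win is not None and not (win[0] <= np.log10(d) <= win[1]):
            return False
    return True


def _noise_draws(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _arm_key(cond: dict) -> tuple:
    return (cond["ratio_label"], cond.get("drug_a"), cond.get("drug_b"),
            cond.get("drug_c"))


def _pack_plates(conditions: list[dict], n_technical: int, capacity: int) -> list[list[dict]]:
    """Group wells into plates without splitting a dose-response arm.

    All wells of one arm (one curve: same drugs and ratio label) go on the
    same plate whenever the arm fits, so per-plate scale differences shift
    whole curves rather than distorting their shape — mirroring how plates
    are laid out in practice. Oversized arms spill over.
    """
    arms: dict[tuple, list[dict]] = {}
    for cond in conditions:
        arms.setdefault(_arm_key(cond), []).append(cond)
    plates: list[list[dict]] = []
    for members in arms.values():
        wells = [c for c in members for _ in range(n_technical)]
        placed = False
        for plate in plates:
            if len(plate) + len(wells) <= capacity:
                plate.extend(wells)
                placed = True
                break
        if not placed:
            while len(wells) > capacity:
                plates.append(wells[:capacity])
                wells = wells[capacity:]
            plates.append(wells)
    return plates


def _assemble(config: SimulationConfig, conditions: list[dict]) -> PlateTable:
    """Lay conditions out on inner-60-well plates and add noise.

    Each condition dict carries the drug/dose/label columns plus
    ``delivered`` (name -> molar). Every plate gets its own untreated
    wells so per-plate normalization is always possible.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    capacity = len(INNER_WELLS) - _UNTREATED_PER_PLATE
    chunks_template = _pack_plates(conditions, config.n_technical, capacity)
    for exp in range(1, config.n_experiments + 1):
        scale = config.untreated_lum_mean * _noise_draws(rng, config.experiment_cv, 1)[0]
        for p, chunk in enumerate(chunks_template, start=1):
            plate_id = f"E{exp}-P{p}"
            well_iter = iter(INNER_WELLS)
            for u in range(_UNTREATED_PER_PLATE):
                lum = scale * _noise_draws(rng, config.noise_cv, 1)[0]
                rows.append({
                    "plate_id": plate_id, "well": next(well_iter),
                    "drug_a": None, "log_dose_a": np.nan,
                    "drug_b": None, "log_dose_b": np.nan,
                    "drug_c": None, "log_dose_c": np.nan,
                    "ratio_label": "untreated", "technical_rep": u + 1,
                    "experiment": exp, "luminescence": lum,
                })
            rep_counter: dict[int, int] = {}
            for cond in chunk:
                v = expected_viability(config, cond["delivered"])
                lum = scale * v * _noise_draws(rng, config.noise_cv, 1)[0]
                key = id(cond)
                rep_counter[key] = rep_counter.get(key, 0) + 1
                rows.append({
                    "plate_id": plate_id, "well": next(well_iter),
                    "drug_a": cond.get("drug_a"), "log_dose_a": cond.get("log_dose_a", np.nan),
                    "drug_b": cond.get("drug_b"), "log_dose_b": cond.get("log_dose_b", np.nan),
                    "drug_c": cond.get("drug_c"), "log_dose_c": cond.get("log_dose_c", np.nan),
                    "ratio_label": cond["ratio_label"],
                    "technical_rep": rep_counter[key],
                    "experiment": exp, "luminescence": lum,
                })
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    return PlateTable(df)


def _alone_conditions(drug: str, ladder: DoseLadder) -> list[dict]:
    return [
        {
            "drug_a": drug, "log_dose_a": d, "ratio_label": "alone",
            "delivered": {drug: 10.0 ** d},
        }
        for d in ladder.doses
    ]


def simulate_single_agent(config: SimulationConfig, ladder: DoseLadder,
                          drug: str | None = None) -> PlateTable:
    """Simulate one drug's 10-point ladder plus untreated controls."""
    drug = drug or ladder.drug
    if drug not in config.drugs:
        raise ValueError(f"no parameters for drug {drug!r}")
    return _assemble(config, _alone_conditions(drug, ladder))


def _deq_conditions(design: DeqDesign) -> list[dict]:
    a, b = design.ladder_a.drug, design.ladder_b.drug
    conds = _alone_conditions(a, design.ladder_a)
    conds += [
        dict(c, drug_a=None, log_dose_a=np.nan, drug_b=b,
             log_dose_b=c["log_dose_a"], delivered={b: 10.0 ** c["log_dose_a"]})
        for c in _alone_conditions(b, design.ladder_b)
    ]
    for spec in design.mixtures:
        for da, db in spec.component_doses:
            conds.append({
                "drug_a": a, "log_dose_a": da, "drug_b": b, "log_dose_b": db,
                "ratio_label": spec.ratio_label,
                "delivered": {
                    a: spec.fraction_a * 10.0 ** da,
                    b: spec.fraction_b * 10.0 ** db,
                },
            })
    return conds


def _bliss_conditions(design: BlissMatrixDesign) -> list[dict]:
    a, b = design.ladder_a.drug, design.ladder_b.drug
    conds = _alone_conditions(a, design.ladder_a)
    conds += [
        dict(c, drug_a=None, log_dose_a=np.nan, drug_b=b,
             log_dose_b=c["log_dose_a"], delivered={b: 10.0 ** c["log_dose_a"]})
        for c in _alone_conditions(b, design.ladder_b)
    ]
    # margins for shifted band doses that fall outside the base ladder
    have_a = set(design.ladder_a.doses)
    extra_a = sorted({da for da, _, _ in design.pairs} - have_a)
    conds += [
        {"drug_a": a, "log_dose_a": d, "ratio_label": "alone",
         "delivered": {a: 10.0 ** d}}
        for d in extra_a
    ]
    # full doses for combinations: no volume reduction in Bliss designs
    for da, db, label in design.pairs:
        conds.append({
            "drug_a": a, "log_dose_a": da, "drug_b": b, "log_dose_b": db,
            "ratio_label": label,
            "delivered": {a: 10.0 ** da, b: 10.0 ** db},
        })
    return conds


def simulate_combination(config: SimulationConfig, design) -> PlateTable:
    """Simulate a combination plate plan with ground-truth surfaces.

    ``design`` may be a :class:`~deqsyn.deq_design.DeqDesign`, a
    :class:`~deqsyn.deq_design.BlissMatrixDesign`, or a
    :class:`~deqsyn.three_drug.ThreeDrugDesign`.
    """
    from .three_drug import ThreeDrugDesign

    if isinstance(design, DeqDesign):
        conds = _deq_conditions(design)
    elif isinstance(design, BlissMatrixDesign):
        conds = _bliss_conditions(design)
    elif isinstance(design, ThreeDrugDesign):
        conds = _three_drug_conditions(design)
    else:
        raise TypeError(f"unsupported design type: {type(design).__name__}")
    for cond in conds:
        for name in cond["delivered"]:
            if name not in config.drugs:
                raise ValueError(f"no parameters for drug {name!r}")
    return _assemble(config, conds)


def _three_drug_conditions(design) -> list[dict]:
    a, b = design.pair
    c = design.third
    conds = []
    for name, col in ((a, "a"), (b, "b"), (c, "c")):
        for d in design.ladders[name].doses:
            conds.append({
                f"drug_{col}": name, f"log_dose_{col}": d,
                "ratio_label": "alone", "delivered": {name: 10.0 ** d},
            })
    # the 1:1 pair baseline: the pseudo-drug's own DEQ curve
    for da, db in zip(design.ladders[a].doses, design.ladders[b].doses):
        conds.append({
            "drug_a": a, "log_dose_a": da, "drug_b": b, "log_dose_b": db,
            "ratio_label": "1:1",
            "delivered": {a: 0.5 * 10.0 ** da, b: 0.5 * 10.0 ** db},
        })
    for label, (va, vb, vc) in design.mixes.items():
        for da, db, dc in zip(design.ladders[a].doses, design.ladders[b].doses,
                              design.ladders[c].doses):
            conds.append({
                "drug_a": a, "log_dose_a": da, "drug_b": b, "log_dose_b": db,
                "drug_c": c, "log_dose_c": dc, "ratio_label": label,
                "delivered": {
                    a: (va / 100.0) * 10.0 ** da,
                    b: (vb / 100.0) * 10.0 ** db,
                    c: (vc / 100.0) * 10.0 ** dc,
                },
            })
    return conds
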