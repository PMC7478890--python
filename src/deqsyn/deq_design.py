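"""Dose-equivalent (DEQ) design construction.

A DEQ design anchors every drug's dose ladder at the 1/3-log grid point
nearest its fitted EC50, so that ladder position i delivers an equi-potent
dose of each drug. Mixing equipotent doses at fixed volume ratios then
produces composite curves whose EC50 shift (or lack of it) quantifies
synergy under Loewe additivity.

Doses are log10 molar throughout. Ladder values are computed from integer
multiples of the grid step so that shifting a band by one step never
accumulates floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GRID_STEP = 1.0 / 3.0

#: Volume fractions for the standard two-drug mixture ratios. These follow
#: the integer-microliter pipetting volumes (80/66/50/34/20 uL per 100 uL),
#: so the 2:1 mix is 0.66/0.34, not exact thirds.
MIXTURE_FRACTIONS: dict[str, tuple[float, float]] = {
    "4:1": (0.80, 0.20),
    "2:1": (0.66, 0.34),
    "1:1": (0.50, 0.50),
    "1:2": (0.34, 0.66),
    "1:4": (0.20, 0.80),
}


def snap_to_grid(log_ec50: float, step: float = GRID_STEP) -> float:
    """Snap a log10-molar EC50 to the nearest point of the ``k * step`` grid.

    The grid is anchored at integer log10 doses (which are themselves
    multiples of ``step`` for step = 1/3). Exact ties break toward the
    lower (more negative) dose.

    Parameters
    ----------
    log_ec50 : float
        Fitted log10 molar EC50.
    step : float
        Grid spacing in log10 units; default 1/3.

    Returns
    -------
    float
        The grid point minimizing ``|grid - log_ec50|``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not _finite(log_ec50):
        raise ValueError("log_ec50 must be finite")
    import math

    k_lo = math.floor(log_ec50 / step)
    k_hi = k_lo + 1
    d_lo = log_ec50 - k_lo * step
    d_hi = k_hi * step - log_ec50
    # tie -> lower dose (more negative), i.e. k_lo
    k = k_lo if d_lo <= d_hi else k_hi
    return k * step


def _finite(x: float) -> bool:
    import math

    return isinstance(x, (int, float)) and math.isfinite(x)


def format_log_dose(x: float) -> str:
    """Render a log10 dose the way dosing tables print it.

    Integers print bare (``-11``), thirds print at two decimals
    (``-10.67``, ``-10.33``).
    """
    r = round(x)
    if abs(x - r) < 1e-9:
        return str(int(r))
    return f"{x:.2f}"


@dataclass(frozen=True)
class DoseLadder:
    """A 10-point 1/3-log dose ladder anchored at a grid-snapped EC50.

    The anchor sits at the 8th of 10 points (7 doses below, 2 above) so the
    ladder covers the full top of the curve down past maximal effect.
    """

    drug: str
    anchor: float
    step: float = GRID_STEP
    doses: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not self.doses:
            object.__setattr__(self, "doses", _ladder_doses(self.anchor, self.step))
        if len(self.doses) < 2 or any(
            b <= a for a, b in zip(self.doses, self.doses[1:])
        ):
            raise ValueError("ladder doses must be strictly increasing")

    def formatted(self) -> list[str]:
        return [format_log_dose(d) for d in self.doses]

    def shifted(self, n_steps: int) -> tuple[float, ...]:
        """The ladder's doses shifted by ``n_steps`` grid steps (exact)."""
        k = round(self.anchor / self.step)
        return tuple(
            (k + i - 7 + n_steps) * self.step for i in range(len(self.doses))
        )


def _ladder_doses(
    anchor: float, step: float, n_below: int = 7, n_above: int = 2
) -> tuple[float, ...]:
    k = round(anchor / step)
    # accept anchors given at printed 2-decimal precision (e.g. -8.67)
    if abs(anchor - k * step) > 5e-3:
        raise ValueError(f"anchor {anchor} is not on the step-{step} grid")
    return tuple((k + i) * step for i in range(-n_below, n_above + 1))


def build_ladder(
    anchor: float,
    step: float = GRID_STEP,
    drug: str = "",
    n_below: int = 7,
    n_above: int = 2,
) -> DoseLadder:
    """Build the DEQ ladder around a grid anchor.

    Default placement is 7 points below and 2 above the anchor, i.e. the
    anchor is the 8th of 10 points.
    """
    doses = _ladder_doses(anchor, step, n_below, n_above)
    return DoseLadder(drug=drug, anchor=anchor, step=step, doses=doses)


@dataclass(frozen=True)
class MixtureSpec:
    """One fixed-ratio DEQ mixture of two drugs.

    At ladder position i the mixture's nominal per-drug dose axes carry the
    full ladder doses; the delivered amount of each drug is
    ``fraction * 10**ladder_dose`` molar.
    """

    ratio_label: str
    fraction_a: float
    fraction_b: float
    component_doses: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not (0 < self.fraction_a < 1 and 0 < self.fraction_b < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if abs(self.fraction_a + self.fraction_b - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def two_drug_mixture_plan(
    ladder_a: DoseLadder,
    ladder_b: DoseLadder,
    ratios: tuple[str, ...] = ("4:1", "2:1", "1:1", "1:2", "1:4"),
) -> list[MixtureSpec]:
    """Build MixtureSpecs for the requested volume-ratio labels."""
    if len(ladder_a.doses) != len(ladder_b.doses):
        raise ValueError("ladders must have the same length")
    specs = []
    for label in ratios:
        if label not in MIXTURE_FRACTIONS:
            raise ValueError(
                f"unknown ratio label {label!r}; valid labels: "
                f"{sorted(MIXTURE_FRACTIONS)}"
            )
        fa, fb = MIXTURE_FRACTIONS[label]
        specs.append(
            MixtureSpec(
                ratio_label=label,
                fraction_a=fa,
                fraction_b=fb,
                component_doses=tuple(zip(ladder_a.doses, ladder_b.doses)),
            )
        )
    return specs


@dataclass(frozen=True)
class DeqDesign:
    """Complete two-drug DEQ plan: both ladders plus the ratio mixtures."""

    ladder_a: DoseLadder
    ladder_b: DoseLadder
    mixtures: tuple[MixtureSpec, ...]


def make_deq_design(
    drug_a: str,
    log_ec50_a: float,
    drug_b: str,
    log_ec50_b: float,
    ratios: tuple[str, ...] = ("4:1", "2:1", "1:1", "1:2", "1:4"),
    step: float = GRID_STEP,
) -> DeqDesign:
    """Snap both EC50s to the grid, build ladders, and plan the mixtures."""
    la = build_ladder(snap_to_grid(log_ec50_a, step), step, drug=drug_a)
    lb = build_ladder(snap_to_grid(log_ec50_b, step), step, drug=drug_b)
    return DeqDesign(la, lb, tuple(two_drug_mixture_plan(la, lb, ratios)))


def bliss_band_plan(
    ladder_a: DoseLadder, ladder_b: DoseLadder
) -> dict[str, tuple[tuple[float, ...], tuple[float, ...]]]:
    """Three paired 10-point dose series for band-style Bliss analysis.

    Drug B's doses are held constant; drug A's are shifted one grid step up
    (2:1 band) or down (1:2 band) relative to the dose-equivalent 1:1
    pairing. Full doses are delivered — combination doses are not reduced
    for Bliss analysis.
    """
    return {
        "1:2": (ladder_a.shifted(-1), ladder_b.doses),
        "1:1": (ladder_a.doses, ladder_b.doses),
        "2:1": (ladder_a.shifted(+1), ladder_b.doses),
    }


@dataclass(frozen=True)
class BlissMatrixDesign:
    """Bliss plate plan: single-agent margins plus full-dose combinations.

    ``pairs`` lists the (log_dose_a, log_dose_b, label) combinations.
    Combination wells carry full doses of both drugs — doses are not
    reduced by volume fraction in Bliss designs.
    """

    ladder_a: DoseLadder
    ladder_b: DoseLadder
    pairs: tuple[tuple[float, float, str], ...]

    @classmethod
    def full_matrix(cls, ladder_a: DoseLadder, ladder_b: DoseLadder) -> "BlissMatrixDesign":
        pairs = tuple(
            (da, db, "combo") for da in ladder_a.doses for db in ladder_b.doses
        )
        return cls(ladder_a, ladder_b, pairs)

    @classmethod
    def bands(cls, ladder_a: DoseLadder, ladder_b: DoseLadder) -> "BlissMatrixDesign":
        """3x10 band plan: drug B constant, drug A shifted one step up/down."""
        pairs = []
        for label, (series_a, series_b) in bliss_band_plan(ladder_a, ladder_b).items():
            pairs.extend((da, db, label) for da, db in zip(series_a, series_b))
        return cls(ladder_a, ladder_b, tuple(pairs))
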