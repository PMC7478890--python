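"""Four-parameter logistic (variable-slope) dose-response fitting.

The model is the standard log(inhibitor)-vs-response form

    v(x) = bottom + (top - bottom) / (1 + 10**((x - log_ec50) * hill))

with x in log10 molar. With this sign convention hill > 0 means viability
decreases with dose (an inhibitor); v(log_ec50) = (top + bottom) / 2
regardless of slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


def four_pl(
    x: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float
) -> np.ndarray:
    """Evaluate the 4PL curve at log10 doses ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - log_ec50) * hill))


def inverse_four_pl(
    v: float, top: float, bottom: float, log_ec50: float, hill: float
) -> float:
    """Log10 dose producing viability ``v``; requires bottom < v < top."""
    if not (bottom < v < top):
        raise ValueError(f"viability {v} outside open range ({bottom}, {top})")
    return log_ec50 + np.log10((top - v) / (v - bottom)) / hill


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters plus diagnostics.

    ``max_effect`` (top - bottom) is the drug's maximal fractional kill on
    the normalized viability scale.
    """

    drug: str
    top: float
    bottom: float
    log_ec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool

    @property
    def max_effect(self) -> float:
        return self.top - self.bottom

    @property
    def ec50_molar(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.top, self.bottom, self.log_ec50, self.hill)


def fit_4pl(
    log_doses,
    viabilities,
    drug: str = "",
    top_bounds: tuple[float, float] = (0.5, 1.5),
    bottom_bounds: tuple[float, float] = (-0.1, 1.0),
    hill_bounds: tuple[float, float] = (0.05, 10.0),
    n_starts: int = 5,
) -> DoseResponseFit:
    """Least-squares 4PL fit on all replicate points jointly.

    Runs ``n_starts`` optimizations with log EC50 initial values spread
    across the dose range and keeps the lowest-RSS solution. The fit is
    flagged non-converged (never raised) if the optimizer fails or the
    fitted log EC50 falls more than one log unit outside the dose ladder.

    Parameters
    ----------
    log_doses, viabilities : array-like
        Paired observations; replicates appear as repeated doses.
    drug : str
        Label carried into the result.

    Raises
    ------
    ValueError
        Fewer than 5 distinct doses, or non-finite viabilities.
    """
    x = np.asarray(log_doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if x.shape != y.shape:
        raise ValueError("log_doses and viabilities must have equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("doses and viabilities must be finite")
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct doses to fit a 4PL")

    lo = np.array([top_bounds[0], bottom_bounds[0], x.min() - 2.0, hill_bounds[0]])
    hi = np.array([top_bounds[1], bottom_bounds[1], x.max() + 2.0, hill_bounds[1]])

    def resid(p):
        return four_pl(x, *p) - y

    top0 = float(np.clip(np.max(y), *top_bounds))
    bot0 = float(np.clip(np.min(y), *bottom_bounds))
    ec50_starts = np.linspace(x.min(), x.max(), n_starts)

    best = None
    for e0 in ec50_starts:
        p0 = np.clip(np.array([top0, bot0, e0, 1.0]), lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(
                resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)

    if best is None:
        return DoseResponseFit(drug, np.nan, np.nan, np.nan, np.nan, np.inf, len(x), False)

    rss, sol = best
    top, bottom, log_ec50, hill = sol.x
    in_range = (x.min() - 1.0) <= log_ec50 <= (x.max() + 1.0)
    return DoseResponseFit(
        drug=drug,
        top=float(top),
        bottom=float(bottom),
        log_ec50=float(log_ec50),
        hill=float(hill),
        rss=rss,
        n_points=len(x),
        converged=bool(sol.success and in_range),
    )


@dataclass(frozen=True)
class ParallelismVerdict:
    """Whether two single-agent curves are similar enough for linear
    isobologram analysis (similar maximal effects and Hill coefficients)."""

    drug_pair: tuple[str, str]
    hill_ratio: float
    max_effect_gap: float
    suitable_for_isobologram: bool
    reason: str


def parallelism_gate(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    hill_ratio_bounds: tuple[float, float] = (0.5, 2.0),
    max_effect_gap: float = 0.2,
    min_effect: float = 0.5,
) -> ParallelismVerdict:
    """Gate a drug pair for isobologram suitability.

    A pair is suitable when each drug kills at least ``min_effect`` of the
    population at saturation, the Hill-slope ratio lies within
    ``hill_ratio_bounds``, and the maximal-effect gap is at most
    ``max_effect_gap``. A pair that fails (e.g. one drug plateauing at
    <50% kill) should be analyzed by Bliss independence instead.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    pair = (fit_a.drug, fit_b.drug)
    ratio = fit_a.hill / fit_b.hill
    gap = abs(fit_a.max_effect - fit_b.max_effect)

    for f in (fit_a, fit_b):
        if f.max_effect < min_effect:
            return ParallelismVerdict(
                pair, ratio, gap, False,
                f"max effect below {min_effect} for {f.drug or 'drug'}",
            )
    if not (hill_ratio_bounds[0] <= ratio <= hill_ratio_bounds[1]):
        return ParallelismVerdict(pair, ratio, gap, False, "hill ratio outside bounds")
    if gap > max_effect_gap:
        return ParallelismVerdict(pair, ratio, gap, False, "max effect gap too large")
    return ParallelismVerdict(pair, ratio, gap, True, "ok")
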