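"""Quantitative pharmacology of competitive antagonism.

Dose-response curves are fitted with a fixed Hill slope of 1:

    y = bottom + (top - bottom) / (1 + midpoint / x)        (agonist)
    y = bottom + (top - bottom) / (1 + x / midpoint)        (antagonist)

with the midpoint (EC50 or IC50) parameterized on a log10 scale.  A
functional IC50 converts to an antagonist equilibrium constant via
Cheng-Prusoff:

    K_B = IC50 / (1 + [Agonist] / EC50)

and a family of agonist curves at increasing antagonist concentration
yields a Schild regression: log10(r - 1) on log10[B], where
r = EC50([B]) / EC50(0).  For a simple competitive (Gaddum, surmountable)
antagonist the slope is 1 and the x-intercept magnitude pA2 equals
-log10(K_B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseCurve",
    "CompetitionResult",
    "SchildResult",
    "fit_fixed_slope",
    "cheng_prusoff",
    "p_value_log",
    "schild_fit",
    "baseline_correct",
]

SCHILD_SLOPE_TOL = 0.2    # |slope - 1| above this flags the unconstrained K_B


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fixed-slope logistic fit of one titration."""

    concentrations: np.ndarray    # molar, sorted ascending
    responses: np.ndarray         # same order (replicate means)
    bottom: float
    top: float
    midpoint: float               # EC50 or IC50, molar
    direction: str                # 'agonist' (rising) or 'antagonist' (falling)
    hill_slope: float
    converged: bool
    reliable: bool
    rmse: float

    @property
    def ec50(self) -> float:
        return self.midpoint

    @property
    def ic50(self) -> float:
        return self.midpoint

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.direction == "agonist":
            return self.bottom + (self.top - self.bottom) / (1.0 + self.midpoint / x)
        return self.bottom + (self.top - self.bottom) / (1.0 + x / self.midpoint)


@dataclass(frozen=True)
class CompetitionResult:
    """Cheng-Prusoff conversion of a functional IC50."""

    ic50: float
    agonist_conc: float
    agonist_ec50: float
    k_b: float
    p_kb: float

    def __post_init__(self):
        if self.k_b > self.ic50 * (1 + 1e-12):
            raise ValueError("K_B cannot exceed IC50")


@dataclass(frozen=True)
class SchildResult:
    antagonist_concs: np.ndarray   # molar, the concentrations used in the regression
    dose_ratios: np.ndarray        # r = EC50([B]) / EC50(0)
    slope: float
    intercept: float
    pa2: float
    k_b: float                     # molar; from pA2 when slope ~ 1, else slope-1 refit
    k_b_unconstrained: float
    slope_ok: bool


def _model(x: np.ndarray, bottom: float, top: float, log_mid: float, direction: str) -> np.ndarray:
    mid = 10.0 ** log_mid
    if direction == "agonist":
        return bottom + (top - bottom) / (1.0 + mid / x)
    return bottom + (top - bottom) / (1.0 + x / mid)


def fit_fixed_slope(
    concs: np.ndarray, responses: np.ndarray, direction: str = "agonist"
) -> DoseResponseCurve:
    """Least-squares fixed-slope (Hill = 1) logistic fit.

    Requires at least five distinct concentrations.  Replicates (repeated
    concentrations) are averaged before fitting.  The midpoint is fitted
    in log space, bounded to four decades beyond the data range, and
    initialized by linear interpolation of the half-maximal response.
    Non-monotone data whose dynamic range is below three times the
    residual noise SD are flagged unreliable.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    # average replicates per concentration
    ux = np.unique(x)
    if len(ux) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    uy = np.array([y[x == xi].mean() for xi in ux])

    lo, hi = np.log10(ux.min()) - 4.0, np.log10(ux.max()) + 4.0
    if direction == "agonist":
        b0, t0 = float(uy[0]), float(uy[-1])
    else:
        b0, t0 = float(uy[-1]), float(uy[0])
    half = 0.5 * (b0 + t0)
    order = np.argsort(uy)
    log_mid0 = float(np.interp(half, uy[order], np.log10(ux)[order]))
    log_mid0 = np.clip(log_mid0, lo, hi)

    def resid(p):
        return _model(ux, p[0], p[1], p[2], direction) - uy

    sol = optimize.least_squares(
        resid,
        x0=[b0, t0, log_mid0],
        bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    bottom, top, log_mid = sol.x
    pred = _model(ux, bottom, top, log_mid, direction)
    rmse = float(np.sqrt(np.mean((pred - uy) ** 2)))
    dynamic = float(abs(top - bottom))
    reliable = dynamic > 3.0 * rmse and dynamic > 0
    return DoseResponseCurve(
        concentrations=ux,
        responses=uy,
        bottom=float(bottom),
        top=float(top),
        midpoint=float(10.0 ** log_mid),
        direction=direction,
        hill_slope=1.0 if direction == "agonist" else -1.0,
        converged=bool(sol.success),
        reliable=reliable,
        rmse=rmse,
    )


def cheng_prusoff(ic50: float, agonist_conc: float, agonist_ec50: float) -> CompetitionResult:
    """K_B = IC50 / (1 + [Agonist]/EC50); all inputs molar and positive."""
    if ic50 <= 0 or agonist_conc < 0 or agonist_ec50 <= 0:
        raise ValueError("Cheng-Prusoff inputs must be positive")
    k_b = ic50 / (1.0 + agonist_conc / agonist_ec50)
    return CompetitionResult(
        ic50=ic50,
        agonist_conc=agonist_conc,
        agonist_ec50=agonist_ec50,
        k_b=k_b,
        p_kb=p_value_log(k_b),
    )


def p_value_log(conc_molar: float) -> float:
    """pK value: -log10 of a molar concentration."""
    if conc_molar <= 0:
        raise ValueError("concentration must be positive")
    return float(-np.log10(conc_molar))


def baseline_correct(responses: np.ndarray, baseline: float | np.ndarray) -> np.ndarray:
    """Subtract the no-ligand baseline (mean of blank wells)."""
    return np.asarray(responses, dtype=float) - np.mean(baseline)


def schild_fit(
    control_curve: DoseResponseCurve,
    curves_by_antagonist_conc: dict[float, DoseResponseCurve],
) -> SchildResult:
    """Schild regression over fitted agonist curves.

    Dose ratios r([B]) = EC50([B]) / EC50(0); points with r <= 1 (no
    rightward shift) are dropped; at least three usable antagonist
    concentrations are required.  K_B is reported from the x-intercept
    when |slope - 1| <= 0.2, otherwise from a slope-constrained refit
    (and the unconstrained value is kept alongside).
    """
    ec50_0 = control_curve.ec50
    concs, ratios = [], []
    for bconc, curve in sorted(curves_by_antagonist_conc.items()):
        if bconc <= 0:
            continue
        r = curve.ec50 / ec50_0
        if r > 1.0:
            concs.append(bconc)
            ratios.append(r)
    if len(concs) < 3:
        raise ValueError(
            "Schild regression needs >= 3 antagonist concentrations with r > 1"
        )
    bx = np.log10(np.asarray(concs))
    ry = np.log10(np.asarray(ratios) - 1.0)
    fit = stats.linregress(bx, ry)
    slope, intercept = float(fit.slope), float(fit.intercept)
    # x-intercept is -intercept/slope; pA2 is its magnitude on the -log scale
    pa2 = intercept / slope
    k_b_unc = 10.0 ** (-pa2)
    slope_ok = abs(slope - 1.0) <= SCHILD_SLOPE_TOL
    if slope_ok:
        k_b = k_b_unc
    else:
        pa2_constrained = -float(np.mean(ry - bx))
        k_b = 10.0 ** (-pa2_constrained)
    return SchildResult(
        antagonist_concs=np.asarray(concs),
        dose_ratios=np.asarray(ratios),
        slope=slope,
        intercept=intercept,
        pa2=pa2,
        k_b=k_b,
        k_b_unconstrained=k_b_unc,
        slope_ok=slope_ok,
    )
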