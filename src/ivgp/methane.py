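"""GC methane calibration and CH4 yield.

A linear prediction equation %CH4 = a + b * area is fitted per
fermentation trial from the standard series (1, 2.5, 5, 10, 15 and 25%
CH4 in N2 in the reference protocol). The fit is ordinary least squares
of concentration on peak area — the "prediction" direction, so unknown
bags are read off directly. Calibrations with R^2 at or below 0.985 are
rejected as unusable.
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, ValidationError
from .types import GCCalibration

__all__ = ["fit_calibration", "predict_ch4_percent", "ch4_yield", "R2_BOUND"]

R2_BOUND = 0.985


def fit_calibration(
    standards: Sequence[Tuple[float, float]],
    r2_bound: float = R2_BOUND,
) -> GCCalibration:
    """OLS fit of %CH4 on mean peak area over the standard levels.

    Parameters
    ----------
    standards
        Pairs ``(ch4_percent, mean_area)``, one per standard level
        (analytical replicates averaged beforehand).
    r2_bound
        Minimum acceptable coefficient of determination (exclusive).
    """
    standards = [(float(p), float(a)) for p, a in standards]
    pct = np.array([p for p, _ in standards])
    area = np.array([a for _, a in standards])
    if np.unique(pct).size < 2:
        raise CalibrationError("calibration needs at least 2 distinct standard levels")
    if np.all(area == area[0]):
        raise CalibrationError("all standard areas identical: singular calibration fit")
    fit = sps.linregress(area, pct)
    r2 = float(fit.rvalue**2)
    if not (r2 > r2_bound):
        raise CalibrationError(
            f"calibration R^2 = {r2:.4f} does not exceed the acceptance bound "
            f"{r2_bound}; re-run the standard series"
        )
    return GCCalibration(
        slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2,
        standards=standards,
    )


def predict_ch4_percent(area: float, cal: GCCalibration) -> Tuple[float, bool]:
    """Predicted %CH4 for a bag's mean peak area, clipped to [0, 100].

    Returns ``(percent, clipped)``; ``clipped`` flags predictions that fell
    outside the physical range before clipping.
    """
    raw = float(cal.intercept + cal.slope * area)
    clipped = not (0.0 <= raw <= 100.0)
    return min(max(raw, 0.0), 100.0), clipped


def ch4_yield(tgp: float, ch4_percent: float) -> float:
    """CH4 yield (mL STP/g DM) from total gas production and CH4 concentration."""
    if tgp < 0 or ch4_percent < 0:
        raise ValidationError(
            f"ch4_yield: inputs must be non-negative (tgp={tgp}, pct={ch4_percent})"
        )
    return tgp * ch4_percent / 100.0
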