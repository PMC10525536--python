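"""Nonparametric fermentation-kinetics parameters from gas curves.

No parametric model is fitted here: total gas production (TGP) at the
report hours is read off the curve by linear interpolation, the rate is
the slope over each recording interval, and the half-max quantities follow
directly from the end-of-fermentation value. Parametric curve families
exist only in the synthetic-data generator.
"""
from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .types import GasCurve, KineticSummary

__all__ = ["tgp_at", "curve_parameters", "average_curves", "REPORT_HOURS"]

REPORT_HOURS = (3.0, 6.0, 9.0, 12.0, 24.0)


def tgp_at(curve: GasCurve, hour: float) -> float:
    """TGP (mL STP/g DM) at ``hour``, linearly interpolated between grid points."""
    t_min = hour * 60.0
    if hour < 0 or t_min > curve.grid_min[-1] or t_min < curve.grid_min[0]:
        raise ValidationError(
            f"curve {curve.bottle_id}: hour {hour} outside recorded range "
            f"[{curve.grid_min[0] / 60:g}, {curve.end_hour:g}] h"
        )
    return float(np.interp(t_min, curve.grid_min, curve.ml_stp_per_g_dm))


def _first_crossing_hour(grid_min: np.ndarray, v: np.ndarray, level: float) -> float:
    """Earliest (interpolated) time in hours at which v reaches ``level``."""
    idx = np.nonzero(v >= level)[0]
    if idx.size == 0:
        return float(grid_min[-1]) / 60.0
    i = int(idx[0])
    if i == 0 or v[i] == level:
        return float(grid_min[i]) / 60.0
    # linear interpolation within the crossing interval
    t0, t1, v0, v1 = grid_min[i - 1], grid_min[i], v[i - 1], v[i]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0)) / 60.0


def curve_parameters(
    curve: GasCurve,
    end_hour: float | None = None,
    report_hours: Sequence[float] = REPORT_HOURS,
) -> KineticSummary:
    """Extract TGP at the report hours plus H, H1, Vmax and Tmax.

    ``tgp_end`` is the curve value at ``end_hour`` (default: last grid
    point); H = tgp_end / 2 by definition; H1 is the earliest time the
    interpolated curve reaches H (sub-grid resolution); the rate over each
    recording interval is the slope in mL/g/h, Vmax its maximum and Tmax
    the left endpoint of the earliest maximal-rate interval (grid
    resolution, earliest tie-break).
    """
    if curve.grid_min.size < 2:
        raise ValidationError(f"curve {curve.bottle_id}: need at least 2 grid points")
    if end_hour is None:
        end_hour = curve.end_hour
    end_min = end_hour * 60.0
    if end_min > curve.grid_min[-1] + 1e-9:
        raise ValidationError(
            f"curve {curve.bottle_id}: spans {curve.end_hour:g} h, "
            f"shorter than requested end {end_hour:g} h"
        )
    keep = curve.grid_min <= end_min + 1e-9
    t, v = curve.grid_min[keep], curve.ml_stp_per_g_dm[keep]

    tgp_end = float(np.interp(end_min, t, v))
    h_level = tgp_end / 2.0
    rates = np.diff(v) / (np.diff(t) / 60.0)
    imax = int(np.argmax(rates))
    return KineticSummary(
        tgp_at_h={h: tgp_at(curve, h) for h in report_hours if h * 60.0 <= end_min + 1e-9},
        tgp_end=tgp_end,
        H=h_level,
        H1_h=_first_crossing_hour(t, v, h_level) if tgp_end != 0 else 0.0,
        Vmax=float(rates[imax]),
        Tmax_h=float(t[imax]) / 60.0,
    )


def average_curves(curves: Sequence[GasCurve]) -> Tuple[GasCurve, np.ndarray]:
    """Pointwise mean of gas curves on the first curve's grid.

    Returns the mean curve and the pointwise standard error of the mean
    (zeros when a single curve is given).
    """
    curves = list(curves)
    if not curves:
        raise ValidationError("average_curves: empty curve list")
    grid = curves[0].grid_min
    mat = np.vstack(
        [np.interp(grid, c.grid_min, c.ml_stp_per_g_dm) for c in curves]
    )
    mean = mat.mean(axis=0)
    if len(curves) > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        sem = np.zeros_like(mean)
    ids = {c.trial_id for c in curves}
    return (
        GasCurve(
            bottle_id="mean(%d)" % len(curves),
            trial_id=ids.pop() if len(ids) == 1 else "multi",
            grid_min=grid,
            ml_stp_per_g_dm=mean,
        ),
        sem,
    )
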