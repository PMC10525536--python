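"""Quality-control rules for technical and analytical replicates.

Two rules, both thresholded at 10% relative deviation:

* gas-curve technical replicates (bottles within a trial) are excluded
  from the trial average when their TGP at 12 h deviates by more than the
  threshold from the group mean;
* GC analytical replicates (repeat injections from one bag) must agree
  within the threshold, otherwise the bag needs re-injection.
"""
from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .errors import QCError
from .kinetics import tgp_at
from .types import GasCurve, QCDecision

__all__ = ["filter_technical_replicates", "average_gc_replicates"]


def filter_technical_replicates(
    curves: Sequence[GasCurve],
    threshold: float = 0.10,
    at_hour: float = 12.0,
    iterative: bool = False,
) -> Tuple[List[GasCurve], List[QCDecision]]:
    """Exclude bottles deviating > ``threshold`` from the group mean TGP at ``at_hour``.

    The reference mean is computed once over all candidate bottles
    (single pass); ``iterative=True`` recomputes the mean after each
    exclusion round until stable, for sensitivity analysis.
    """
    curves = list(curves)
    if not curves:
        raise QCError("technical-replicate filter: no curves supplied")
    if len(curves) == 1:
        c = curves[0]
        return [c], [QCDecision(c.bottle_id, True, 0.0, "single replicate")]

    all_values = np.array([tgp_at(c, at_hour) for c in curves])
    active = np.ones(len(curves), dtype=bool)
    while True:
        mean = all_values[active].mean() if active.any() else 0.0
        if mean == 0:
            if np.any([np.any(c.ml_stp_per_g_dm != 0) for c in curves]):
                raise QCError(
                    f"group mean TGP at {at_hour:g} h is 0 with non-zero curves: "
                    "degenerate QC reference"
                )
            # all-zero group: nothing deviates
            return list(curves), [
                QCDecision(c.bottle_id, True, 0.0, "included") for c in curves
            ]
        dev = np.abs(all_values - mean) / mean
        keep = dev <= threshold
        if not iterative or np.array_equal(keep, active):
            break
        active = keep

    decisions = [
        QCDecision(
            c.bottle_id,
            bool(k),
            float(d),
            "included" if k else f"deviation at {at_hour:g} h exceeds {threshold:.0%}",
        )
        for c, d, k in zip(curves, dev, keep)
    ]
    return [c for c, k in zip(curves, keep) if k], decisions


def average_gc_replicates(areas: Sequence[float], threshold: float = 0.10) -> float:
    """Mean of GC analytical replicate areas, enforcing < ``threshold`` deviation.

    Raises :class:`QCError` (prompting re-injection) when any replicate
    deviates from the mean by more than the threshold.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size < 2:
        raise QCError("GC replicate averaging requires at least 2 injections")
    mean = areas.mean()
    if mean == 0:
        if np.any(areas != 0):
            raise QCError(f"GC replicate mean is 0 for areas {areas.tolist()}")
        return 0.0
    dev = np.abs(areas - mean) / np.abs(mean)
    if np.any(dev > threshold):
        raise QCError(
            f"GC analytical replicates deviate > {threshold:.0%} from their mean: "
            f"areas {areas.tolist()} (deviations {np.round(dev, 4).tolist()}); re-inject"
        )
    return float(mean)
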