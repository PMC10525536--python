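"""Two-phase blank (baseline) correction of sample pressure curves.

Blank bottles contain buffered rumen fluid without substrate and quantify
the gas produced by the baseline microbial activity of the inoculum. Their
cumulative curve rises while the baseline community ferments residual
substrate and stops rising once headspace gas is absorbed back into the
fluid. The correction is therefore two-phase:

* up to the time the mean blank curve peaks, the time-matched mean blank
  pressure is subtracted from each sample bottle;
* after the peak, the blank's maximum is subtracted (the baseline
  community produced no further gas; any later decline of the blank record
  is absorption, not negative production).

At the phase boundary both formulas agree, so the corrected series has no
jump introduced by the rule itself.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .types import BlankProfile, BottleRun

__all__ = ["build_blank_profile", "correct_sample"]


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with edge truncation (window = full width, odd)."""
    if window <= 1:
        return x
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def build_blank_profile(
    blanks: Sequence[BottleRun],
    grid_min,
    smooth_window: int = 0,
    blank_id: Optional[str] = None,
) -> BlankProfile:
    """Pointwise mean of blank-bottle cumulative curves and its earliest peak.

    Parameters
    ----------
    blanks
        Blank bottles; each series must cover the grid (linear
        interpolation fills gaps within the recorded range).
    grid_min
        Common time grid in minutes.
    smooth_window
        Optional centred moving-mean width (grid points) applied only for
        peak *detection*, guarding against sensor noise creating a spurious
        early maximum. 0 (default) disables smoothing.
    blank_id
        Use a single named blank instead of the mean of all blanks.
    """
    if blank_id is not None:
        blanks = [b for b in blanks if b.bottle_id == blank_id]
        if not blanks:
            raise ConfigurationError(f"no blank bottle with id {blank_id!r}")
    blanks = [b for b in blanks if b.role == "blank"]
    if not blanks:
        raise ConfigurationError("blank correction requires at least one blank bottle")
    grid_min = np.asarray(grid_min, dtype=float)
    mean_cum = np.mean([b.cum_at(grid_min) for b in blanks], axis=0)
    detect = _moving_mean(mean_cum, smooth_window) if smooth_window else mean_cum
    peak_idx = int(np.argmax(detect))  # argmax returns the earliest maximum
    return BlankProfile(
        grid_min=grid_min,
        mean_cum_psi=mean_cum,
        peak_time_min=float(grid_min[peak_idx]),
        peak_psi=float(mean_cum[peak_idx]),
        n_blanks=len(blanks),
    )


def correct_sample(sample: BottleRun, profile: BlankProfile) -> np.ndarray:
    """Apply the two-phase blank correction to one sample bottle.

    Returns the corrected cumulative pressure on the profile's grid.
    Negative corrected values are retained (clamping would bias total gas
    production upward); callers may count them as a QC flag.
    """
    if sample.role != "sample":
        raise ValidationError(f"bottle {sample.bottle_id}: blank correction applies to samples")
    if sample.end_min < profile.grid_min[-1]:
        raise ValidationError(
            f"bottle {sample.bottle_id}: series ends at {sample.end_min:g} min, "
            f"shorter than the blank profile grid ({profile.grid_min[-1]:g} min)"
        )
    s = sample.cum_at(profile.grid_min)
    pre_peak = profile.grid_min <= profile.peak_time_min
    return np.where(pre_peak, s - profile.mean_cum_psi, s - profile.peak_psi)
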