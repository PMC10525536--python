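"""Core data containers for the IVGP pipeline.

All time series are stored as parallel numpy arrays on an integer minute
grid ("minutes since incubation start"). Gas volumes are cumulative mL at
standard temperature and pressure (STP), normalised per gram of incubated
dry matter (DM) where stated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PhysicsConfig",
    "BottleRun",
    "TrialMeta",
    "BlankProfile",
    "GasCurve",
    "KineticSummary",
    "GCCalibration",
    "MethaneResult",
    "DegradationRecord",
    "QCDecision",
]

PSI_TO_KPA = 6.894757


@dataclass(frozen=True)
class PhysicsConfig:
    """Physical constants used to convert headspace gauge pressure to gas volume.

    headspace_ml
        Free headspace volume of the fermentation bottle in mL. Nominal
        default: 100 mL bottle minus 90 mL buffered rumen fluid. Real
        bottles exceed their nominal volume, so override this when the
        effective headspace has been measured.
    incubation_temp_C
        Incubation temperature in deg C (39.5 by default).
    ambient_pressure_kPa
        Reference (ambient) pressure the gauge sensor measures against.
    stp_temp_K / stp_pressure_kPa
        The STP convention used for reporting (273.15 K / 101.325 kPa,
        the Menke-style convention; configurable for labs using 25 deg C).
    """

    headspace_ml: float = 10.0
    incubation_temp_C: float = 39.5
    ambient_pressure_kPa: float = 101.325
    stp_temp_K: float = 273.15
    stp_pressure_kPa: float = 101.325
    psi_to_kPa: float = PSI_TO_KPA

    def __post_init__(self) -> None:
        if self.headspace_ml <= 0:
            raise ConfigurationError(f"headspace_ml must be > 0, got {self.headspace_ml}")
        if self.incubation_temp_C <= -273.15 or self.stp_temp_K <= 0:
            raise ConfigurationError("temperatures must be above absolute zero")
        if self.ambient_pressure_kPa <= 0 or self.stp_pressure_kPa <= 0:
            raise ConfigurationError("pressures must be positive")

    @property
    def incubation_temp_K(self) -> float:
        return self.incubation_temp_C + 273.15

    def with_overrides(self, **kw) -> "PhysicsConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})


@dataclass
class BottleRun:
    """One fermentation bottle: identity, role and its recorded pressure series.

    ``time_min`` is strictly increasing; ``cum_pressure_psi`` is the
    cumulative (released + current) gauge pressure and must be
    non-decreasing; ``abs_pressure_psi`` is the instantaneous gauge
    pressure at the recording time (may be negative during absorption).
    """

    bottle_id: str
    trial_id: str
    role: str  # 'blank' | 'sample'
    substrate_dm_g: float
    time_min: np.ndarray
    cum_pressure_psi: np.ndarray
    abs_pressure_psi: Optional[np.ndarray] = None
    bag_areas: Optional[list] = None
    residue_g: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.cum_pressure_psi = np.asarray(self.cum_pressure_psi, dtype=float)
        if self.abs_pressure_psi is not None:
            self.abs_pressure_psi = np.asarray(self.abs_pressure_psi, dtype=float)
        if self.role not in ("blank", "sample"):
            raise ValidationError(f"bottle {self.bottle_id}: unknown role {self.role!r}")
        if self.role == "blank" and self.substrate_dm_g != 0:
            raise ValidationError(
                f"bottle {self.bottle_id}: blank bottles must have substrate_dm_g = 0"
            )
        if self.time_min.size != self.cum_pressure_psi.size:
            raise ValidationError(f"bottle {self.bottle_id}: time/pressure length mismatch")
        if self.time_min.size and np.any(np.diff(self.time_min) <= 0):
            raise ValidationError(f"bottle {self.bottle_id}: time_min not strictly increasing")

    def validate_monotone(self) -> "BottleRun":
        """Enforce a non-decreasing cumulative register (the reader's contract).

        A cumulative register that decreases indicates a corrupt export.
        (In-memory analysis of declining blank curves is still legal: the
        blank-correction peak logic handles them.)
        """
        dec = np.nonzero(np.diff(self.cum_pressure_psi) < 0)[0]
        if dec.size:
            t = self.time_min[dec[0] + 1]
            raise ValidationError(
                f"bottle {self.bottle_id}: cumulative pressure decreases at t={t:g} min"
            )
        return self

    @property
    def end_min(self) -> float:
        return float(self.time_min[-1])

    def cum_at(self, grid_min: np.ndarray) -> np.ndarray:
        """Cumulative pressure linearly interpolated onto ``grid_min``.

        Missing samples within the series are allowed; the grid must not
        extend beyond the recorded range.
        """
        grid_min = np.asarray(grid_min, dtype=float)
        if grid_min[-1] > self.end_min or grid_min[0] < self.time_min[0]:
            raise ValidationError(
                f"bottle {self.bottle_id}: series [{self.time_min[0]:g}, "
                f"{self.end_min:g}] min does not cover requested grid"
            )
        return np.interp(grid_min, self.time_min, self.cum_pressure_psi)


@dataclass
class TrialMeta:
    """Per-trial metadata: donor type, pH readings and physics settings."""

    trial_id: str
    donor_type: str  # 'RF_T' (fasted heifers) | 'RF_A' (lactating cows)
    rumen_pH_pre: list = field(default_factory=list)
    filtrate_pH_post: list = field(default_factory=list)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    record_interval_min: int = 10

    def __post_init__(self) -> None:
        if self.donor_type not in ("RF_T", "RF_A"):
            raise ValidationError(
                f"trial {self.trial_id}: unknown donor_type {self.donor_type!r} "
                "(expected RF_T or RF_A)"
            )
        for ph in list(self.rumen_pH_pre) + list(self.filtrate_pH_post):
            if not (4.0 <= ph <= 9.0):
                raise ValidationError(f"trial {self.trial_id}: pH {ph} outside [4, 9]")


@dataclass
class BlankProfile:
    """Mean blank-bottle cumulative pressure and its (earliest) peak."""

    grid_min: np.ndarray
    mean_cum_psi: np.ndarray
    peak_time_min: float
    peak_psi: float
    n_blanks: int = 1


@dataclass
class GasCurve:
    """Blank-corrected cumulative gas (mL STP / g DM) on a regular minute grid."""

    bottle_id: str
    trial_id: str
    grid_min: np.ndarray
    ml_stp_per_g_dm: np.ndarray

    def __post_init__(self) -> None:
        self.grid_min = np.asarray(self.grid_min, dtype=float)
        self.ml_stp_per_g_dm = np.asarray(self.ml_stp_per_g_dm, dtype=float)
        if self.grid_min.size != self.ml_stp_per_g_dm.size:
            raise ValidationError(f"curve {self.bottle_id}: grid/value length mismatch")

    @property
    def end_hour(self) -> float:
        return float(self.grid_min[-1]) / 60.0


@dataclass
class KineticSummary:
    """Nonparametric curve parameters for one gas curve (or a mean of curves).

    ``tgp_at_h`` maps the standard report hours to mL STP/g DM. ``H`` is
    half the end-of-fermentation volume by definition; ``H1_h`` the earliest
    time the curve reaches H; ``Vmax`` the maximum per-interval production
    rate (mL/g/h over the recording interval); ``Tmax_h`` the left endpoint
    of the earliest maximal-rate interval.
    """

    tgp_at_h: dict
    tgp_end: float
    H: float
    H1_h: float
    Vmax: float
    Tmax_h: float


@dataclass
class GCCalibration:
    """Linear GC prediction equation: %CH4 = intercept + slope * peak area."""

    slope: float
    intercept: float
    r_squared: float
    standards: list = field(default_factory=list)  # (ch4_percent, mean_area)

    def predict(self, area) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(area, dtype=float)


@dataclass
class MethaneResult:
    trial_id: str
    ch4_percent: float
    ch4_yield: float  # mL CH4 at STP / g DM
    clipped: bool = False


@dataclass
class DegradationRecord:
    bottle_id: str
    residue_g: float
    blank_biomass_g: float
    sample_dm_g: float
    ddm: float
    out_of_range: bool = False


@dataclass
class QCDecision:
    bottle_id: str
    included: bool
    deviation_at_12h: float
    reason: str = ""
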