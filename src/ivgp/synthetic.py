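"""Seeded generator of complete synthetic fermentation trials.

The generator emulates the measurement chain of an automated in vitro
gas production (IVGP) apparatus: bottles with buffered rumen fluid (with
or without substrate) produce gas following a known kinetic curve, the
headspace gauge pressure is vented into a collection bag whenever it
reaches the vent threshold (0.75 psi above ambient), absolute and
cumulative pressures are recorded every 10 min, and Gaussian sensor,
weighing and GC noise are added on top. Every downstream quantity
(TGP at the report hours, H, H1, Vmax, Tmax, CH4 concentration, dDM)
has a closed-form ground truth.

Two donor-type curve shapes are modelled:

* ``RF_T`` (fasted heifers): a monophasic sigmoidal curve — an offset
  logistic, zero at t = 0, inflection near 12 h;
* ``RF_A`` (lactating cows): a fast exponential rise with a short lag.

Baseline (blank) gas is modelled with a *produced* component that rises
to a small peak and stays there, and an *observed* component that
declines after the peak as headspace gas is absorbed back into the
fluid. Sample bottles carry the produced component (their continued
fermentation keeps the headspace flushed), blank bottles show the
observed one — which is exactly the situation the two-phase blank
correction is designed for.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError
from .gas import ml_stp_per_psi
from .types import BottleRun, PhysicsConfig, TrialMeta

__all__ = [
    "CurveModel",
    "BlankModel",
    "NoiseModel",
    "SyntheticTrialConfig",
    "TrialDataset",
    "default_trial_config",
    "simulate_bottle",
    "simulate_trial",
    "simulate_study",
    "GC_TRUE_SLOPE",
    "GC_STANDARD_LEVELS",
]

# true GC response used to generate areas: %CH4 = GC_TRUE_SLOPE * area
GC_TRUE_SLOPE = 0.1
GC_STANDARD_LEVELS = (1.0, 2.5, 5.0, 10.0, 15.0, 25.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CurveModel:
    """Closed-form cumulative gas curve, mL STP per g DM.

    family 'sigmoid_monophasic': offset logistic
        V(t) = A * (sigma(k*(t - t_half)) - sigma(-k*t_half)),
    zero at t = 0, inflection (maximum rate A*k/4) at t = t_half.

    family 'exponential': lagged first-order rise
        V(t) = A * (1 - exp(-k * max(0, t - lag))),
    maximum rate A*k reached at t = lag.
    """

    family: str  # 'sigmoid_monophasic' | 'exponential'
    A: float
    k: float           # /h
    t_half: float = 0.0  # h, sigmoid inflection
    lag: float = 0.0     # h, exponential lag

    def __post_init__(self):
        if self.family not in ("sigmoid_monophasic", "exponential"):
            raise ConfigurationError(f"unknown curve family {self.family!r}")
        if self.A < 0 or self.k <= 0 or self.lag < 0:
            raise ConfigurationError("curve parameters must be positive (lag >= 0)")

    def volume(self, t_h):
        """Cumulative gas at time t (hours), mL STP / g DM."""
        t = np.asarray(t_h, dtype=float)
        if self.family == "sigmoid_monophasic":
            v = self.A * (_sigmoid(self.k * (t - self.t_half)) - _sigmoid(-self.k * self.t_half))
        else:
            v = self.A * (1.0 - np.exp(-self.k * np.maximum(0.0, t - self.lag)))
        return v if v.shape else float(v)

    def rate(self, t_h):
        """Instantaneous production rate, mL/g/h."""
        t = np.asarray(t_h, dtype=float)
        if self.family == "sigmoid_monophasic":
            s = _sigmoid(self.k * (t - self.t_half))
            r = self.A * self.k * s * (1.0 - s)
        else:
            r = np.where(
                t >= self.lag, self.A * self.k * np.exp(-self.k * np.maximum(0.0, t - self.lag)), 0.0
            )
        return r if r.shape else float(r)

    def vmax_tmax(self, end_h: float) -> Tuple[float, float]:
        """Analytic maximum rate and its time within [0, end_h]."""
        if self.family == "sigmoid_monophasic":
            tm = min(max(self.t_half, 0.0), end_h)
        else:
            tm = min(self.lag, end_h)
        return float(self.rate(tm)), float(tm)

    def half_time(self, end_h: float) -> float:
        """Time at which the curve reaches half its value at end_h."""
        target = self.volume(end_h) / 2.0
        if target == 0:
            return 0.0
        return float(brentq(lambda t: self.volume(t) - target, 0.0, end_h))


@dataclass(frozen=True)
class BlankModel:
    """Baseline (blank-bottle) gas in absolute mL STP per bottle.

    ``produced(t)`` rises smoothly to ``peak_ml`` at ``peak_time_h`` and
    stays there (total gas made by the baseline community); ``observed(t)``
    additionally declines at ``decline_ml_per_h`` after the peak
    (absorption of headspace gas into the fluid). ``biomass_g`` is the
    microbial biomass recovered in a blank bottle's filter bag.
    """

    peak_ml: float = 8.0
    peak_time_h: float = 6.0
    decline_ml_per_h: float = 0.15
    biomass_g: float = 0.05

    def produced(self, t_h):
        t = np.asarray(t_h, dtype=float)
        x = np.minimum(t / self.peak_time_h, 1.0)
        v = self.peak_ml * x * (2.0 - x)  # smooth rise, zero slope at the peak
        return v if v.shape else float(v)

    def observed(self, t_h):
        t = np.asarray(t_h, dtype=float)
        v = self.produced(t) - self.decline_ml_per_h * np.maximum(0.0, t - self.peak_time_h)
        v = np.maximum(v, 0.0)
        return v if v.shape else float(v)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise magnitudes for the simulated measurement chain."""

    pressure_sd_psi: float = 0.005   # additive, per recorded pressure
    weighing_sd_g: float = 0.002     # additive, per weighing
    gc_area_cv: float = 0.01         # multiplicative, per GC injection
    bottle_scale_cv: float = 0.01    # between technical-replicate bottles
    ph_sd: float = 0.02              # per pH reading

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


# defaults echo the two donor-type profiles of the reference study
_RFT_CURVE = CurveModel("sigmoid_monophasic", A=196.7, k=0.2226, t_half=11.81)
_RFA_CURVE = CurveModel("exponential", A=201.9, k=0.0819, lag=0.23)
_DONOR_DEFAULTS = {
    "RF_T": dict(curve=_RFT_CURVE, true_ch4_percent=9.2, true_ddm=0.609,
                 ph_pre_mean=7.00, ph_post_mean=6.85),
    "RF_A": dict(curve=_RFA_CURVE, true_ch4_percent=9.9, true_ddm=0.587,
                 ph_pre_mean=5.90, ph_post_mean=6.71),
}
# between-trial variation of the curve scale (multiplicative SD)
_BETWEEN_TRIAL_CV = {"RF_T": 0.03, "RF_A": 0.01}
_CH4_TRIAL_SD = {"RF_T": 0.30, "RF_A": 0.15}
_DDM_TRIAL_SD = 0.003


@dataclass(frozen=True)
class SyntheticTrialConfig:
    trial_id: str
    donor_type: str
    curve: CurveModel
    blank: BlankModel = field(default_factory=BlankModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    true_ch4_percent: float = 9.5
    true_ddm: float = 0.6
    ph_pre_mean: float = 6.5
    ph_post_mean: float = 6.8
    substrate_dm_g: float = 0.5
    n_sample_bottles: int = 3
    n_blank_bottles: int = 2
    vent_threshold_psi: float = 0.75
    record_interval_min: int = 10
    step_min: int = 1
    end_h: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.vent_threshold_psi <= 0:
            raise ConfigurationError("vent threshold must be > 0")
        for sd in (self.noise.pressure_sd_psi, self.noise.weighing_sd_g,
                   self.noise.gc_area_cv, self.noise.bottle_scale_cv, self.noise.ph_sd):
            if sd < 0:
                raise ConfigurationError("noise SDs must be >= 0")


def default_trial_config(
    donor_type: str,
    trial_id: str = "T01",
    seed: int = 0,
    noise: Optional[NoiseModel] = None,
    **overrides,
) -> SyntheticTrialConfig:
    """Study-default configuration for one trial of the given donor type."""
    if donor_type not in _DONOR_DEFAULTS:
        raise ConfigurationError(f"unknown donor_type {donor_type!r}")
    kw = dict(_DONOR_DEFAULTS[donor_type])
    kw.update(overrides)
    if noise is not None:
        kw["noise"] = noise
    return SyntheticTrialConfig(trial_id=trial_id, donor_type=donor_type, seed=seed, **kw)


def _rng(*key) -> np.random.Generator:
    """Independent stream from a stable hash of the key tuple.

    Adding bottles or trials never perturbs the streams of existing ones.
    """
    digest = hashlib.sha256("|".join(str(k) for k in key).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _vent(cum_psi: np.ndarray, threshold: float) -> Tuple[np.ndarray, float]:
    """Instantaneous gauge pressure under threshold venting.

    Returns the instantaneous pressure trace and the total vented pressure
    (psi-equivalents; multiply by mL/psi for the bag volume). Venting
    conserves gas: vented + instantaneous == cumulative at every step.
    """
    p = 0.0
    vented = 0.0
    inst = np.empty_like(cum_psi)
    prev = 0.0
    for i, c in enumerate(cum_psi):
        p += c - prev
        prev = c
        if p >= threshold:
            vented += p
            p = 0.0
        inst[i] = p
    return inst, vented


def simulate_bottle(
    cfg: SyntheticTrialConfig, role: str, bottle_id: str
) -> Tuple[BottleRun, Dict[str, float]]:
    """Simulate one bottle's pressure log; returns the run and its ground truth.

    The internal simulation step is ``cfg.step_min`` (1 min by default,
    the sensor's live transmission interval); records are kept every
    ``cfg.record_interval_min``. Recorded cumulative pressure gets
    additive sensor noise and is forced non-decreasing, as the logger's
    cumulative register is.
    """
    rng = _rng(cfg.seed, "bottle", cfg.trial_id, bottle_id)
    nz = cfg.noise
    t_int = np.arange(0.0, cfg.end_h * 60.0 + 0.5 * cfg.step_min, cfg.step_min)
    th = t_int / 60.0

    scale = 1.0
    dm = 0.0
    if role == "sample":
        scale = 1.0 + rng.normal(0.0, nz.bottle_scale_cv) if nz.bottle_scale_cv else 1.0
        dm = cfg.substrate_dm_g + (rng.normal(0.0, nz.weighing_sd_g) if nz.weighing_sd_g else 0.0)

    if role == "sample":
        true_ml = dm * scale * cfg.curve.volume(th) + cfg.blank.produced(th)
    else:
        true_ml = cfg.blank.observed(th)

    mlpp = ml_stp_per_psi(cfg.physics)
    cum_true_psi = true_ml / mlpp
    inst, vented = _vent(cum_true_psi, cfg.vent_threshold_psi)

    rec = np.nonzero(t_int % cfg.record_interval_min == 0)[0]
    cum_rec = cum_true_psi[rec]
    abs_rec = inst[rec]
    if nz.pressure_sd_psi:
        cum_rec = cum_rec + rng.normal(0.0, nz.pressure_sd_psi, cum_rec.size)
        abs_rec = abs_rec + rng.normal(0.0, nz.pressure_sd_psi, abs_rec.size)
    cum_rec = np.maximum.accumulate(np.maximum(cum_rec, 0.0))

    residue_true = cfg.blank.biomass_g + ((1.0 - cfg.true_ddm) * dm if role == "sample" else 0.0)
    residue = residue_true + (rng.normal(0.0, nz.weighing_sd_g) if nz.weighing_sd_g else 0.0)

    bag_areas = None
    if role == "sample":
        area_true = cfg.true_ch4_percent / GC_TRUE_SLOPE
        mult = (1.0 + rng.normal(0.0, nz.gc_area_cv, 2)) if nz.gc_area_cv else np.ones(2)
        bag_areas = (area_true * mult).tolist()

    run = BottleRun(
        bottle_id=bottle_id,
        trial_id=cfg.trial_id,
        role=role,
        substrate_dm_g=dm if role == "sample" else 0.0,
        time_min=t_int[rec],
        cum_pressure_psi=cum_rec,
        abs_pressure_psi=abs_rec,
        bag_areas=bag_areas,
        residue_g=residue,
    )

    vmax, tmax = cfg.curve.vmax_tmax(cfg.end_h)
    truth = {
        "scale": scale,
        "tgp_end": scale * cfg.curve.volume(cfg.end_h),
        "H": scale * cfg.curve.volume(cfg.end_h) / 2.0,
        "H1_h": cfg.curve.half_time(cfg.end_h),
        "Vmax": scale * vmax,
        "Tmax_h": tmax,
        "ch4_percent": cfg.true_ch4_percent,
        "ddm": cfg.true_ddm,
        "bag_ml_stp": vented * mlpp,
        "vented_psi": vented,
        "final_inst_psi": float(inst[-1]),
        "cum_end_psi": float(cum_true_psi[-1]),
    }
    for h in (3.0, 6.0, 9.0, 12.0, 24.0):
        if h <= cfg.end_h:
            truth[f"tgp_{h:g}h"] = scale * cfg.curve.volume(h)
    return run, truth


@dataclass
class TrialDataset:
    """One simulated trial: pipeline inputs plus per-bottle ground truth."""

    meta: TrialMeta
    bottles: List[BottleRun]
    gc_standards: pd.DataFrame  # ch4_percent, area, replicate
    truth: Dict[str, Dict[str, float]]  # bottle_id -> truth


def simulate_trial(cfg: SyntheticTrialConfig) -> TrialDataset:
    """Simulate all bottles, GC standards and metadata for one trial."""
    rng = _rng(cfg.seed, "trial", cfg.trial_id)
    bottles: List[BottleRun] = []
    truth: Dict[str, Dict[str, float]] = {}
    for i in range(cfg.n_sample_bottles):
        bid = f"{cfg.trial_id}-S{i + 1}"
        run, tr = simulate_bottle(cfg, "sample", bid)
        bottles.append(run)
        truth[bid] = tr
    for i in range(cfg.n_blank_bottles):
        bid = f"{cfg.trial_id}-B{i + 1}"
        run, tr = simulate_bottle(cfg, "blank", bid)
        bottles.append(run)
        truth[bid] = tr

    rows = []
    for pct in GC_STANDARD_LEVELS:
        for rep in (1, 2):
            mult = 1.0 + (rng.normal(0.0, cfg.noise.gc_area_cv) if cfg.noise.gc_area_cv else 0.0)
            rows.append({"ch4_percent": pct, "area": pct / GC_TRUE_SLOPE * mult, "replicate": rep})
    standards = pd.DataFrame(rows)

    ph_noise = lambda n: rng.normal(0.0, cfg.noise.ph_sd, n) if cfg.noise.ph_sd else np.zeros(n)
    meta = TrialMeta(
        trial_id=cfg.trial_id,
        donor_type=cfg.donor_type,
        rumen_pH_pre=list(np.round(cfg.ph_pre_mean + ph_noise(2), 4)),
        filtrate_pH_post=list(np.round(cfg.ph_post_mean + ph_noise(cfg.n_sample_bottles), 4)),
        physics=cfg.physics,
        record_interval_min=cfg.record_interval_min,
    )
    return TrialDataset(meta=meta, bottles=bottles, gc_standards=standards, truth=truth)


def simulate_study(
    out_dir,
    seed: int = 0,
    n_rft: int = 5,
    n_rfa: int = 12,
    noise: Optional[NoiseModel] = None,
    between_trial_cv: Optional[Dict[str, float]] = None,
    **trial_overrides,
) -> pd.DataFrame:
    """Simulate the full unbalanced study (default 5 RF_T + 12 RF_A trials).

    Writes the canonical input files for every trial under
    ``out_dir/trial_<id>/`` plus ``out_dir/ground_truth.csv`` (never read
    by the pipeline). Between-trial biological variation scales each
    trial's curve amplitude and shifts its true CH4% and dDM.

    Returns the per-trial ground-truth table.
    """
    from .io import write_trial_inputs  # deferred: io imports types only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bcv = dict(_BETWEEN_TRIAL_CV)
    if between_trial_cv:
        bcv.update(between_trial_cv)

    trial_ids = [("RF_T", f"T{i + 1:02d}") for i in range(n_rft)] + [
        ("RF_A", f"A{i + 1:02d}") for i in range(n_rfa)
    ]
    truth_rows = []
    for donor, tid in trial_ids:
        trng = _rng(seed, "study", tid)
        base = default_trial_config(donor, trial_id=tid, seed=seed, noise=noise, **trial_overrides)
        zero_noise = noise is not None and noise == NoiseModel.none()
        if zero_noise:
            a_scale, ddm, ch4 = 1.0, base.true_ddm, base.true_ch4_percent
        else:
            a_scale = 1.0 + trng.normal(0.0, bcv[donor])
            ddm = base.true_ddm + trng.normal(0.0, _DDM_TRIAL_SD)
            ch4 = base.true_ch4_percent + trng.normal(0.0, _CH4_TRIAL_SD[donor])
        cfg = replace(
            base,
            curve=replace(base.curve, A=base.curve.A * a_scale),
            true_ddm=ddm,
            true_ch4_percent=ch4,
        )
        ds = simulate_trial(cfg)
        write_trial_inputs(ds, out_dir / f"trial_{tid}")
        row = {
            "trial_id": tid,
            "donor_type": donor,
            "curve_scale": a_scale,
            "true_ddm": ddm,
            "true_ch4_percent": ch4,
            "true_tgp_end": cfg.curve.volume(cfg.end_h),
            "true_H1_h": cfg.curve.half_time(cfg.end_h),
        }
        vmax, tmax = cfg.curve.vmax_tmax(cfg.end_h)
        row["true_Vmax"], row["true_Tmax_h"] = vmax, tmax
        for h in (3.0, 6.0, 9.0, 12.0, 24.0):
            row[f"true_tgp_{h:g}h"] = cfg.curve.volume(h)
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return truth
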