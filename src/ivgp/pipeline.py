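"""End-to-end orchestration: trial directories -> study report.

Stage order per trial: read inputs -> blank correction -> gas conversion
-> technical-replicate QC -> kinetics -> GC calibration and CH4 ->
degradation. Across trials: repeatability (CV_RF) statistics, the
trial x donor fixed-effects model and Welch tests per parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import blank, degradation, gas, io, kinetics, methane, qc, stats
from .errors import IvgpError, QCError, ValidationError
from .types import GasCurve, GCCalibration, KineticSummary, MethaneResult, TrialMeta

__all__ = [
    "RunConfig",
    "TrialResult",
    "StudyResult",
    "analyze_trial",
    "analyze_trial_data",
    "analyze_dataset",
    "run_pipeline",
]

# parameters entering the repeatability / model layer, in report order
PARAMETERS = [
    "dDM_pct", "pH_pre", "pH_post",
    "TGP_3h", "TGP_6h", "TGP_9h", "TGP_12h", "TGP_24h",
    "CH4_pct", "CH4_yield", "H", "H1_h", "Vmax", "Tmax_h",
]


@dataclass
class RunConfig:
    """Options for a pipeline run (thresholds in (0, 1), hours in h)."""

    input_dir: Optional[Path] = None
    output_dir: Optional[Path] = None
    qc_threshold: float = 0.10
    qc_hour: float = 12.0
    qc_iterative: bool = False
    blank_smooth_window: int = 0
    blank_id: Optional[str] = None
    end_hour: float = 24.0
    alpha: float = 0.05
    yield_basis: str = "blank_corrected"  # or 'uncorrected'
    physics_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.qc_threshold < 1.0):
            raise ValidationError(f"qc_threshold must be in (0, 1), got {self.qc_threshold}")
        if self.yield_basis not in ("blank_corrected", "uncorrected"):
            raise ValidationError(f"unknown yield_basis {self.yield_basis!r}")


@dataclass
class TrialResult:
    trial_id: str
    donor_type: str
    meta: TrialMeta
    summary: KineticSummary                  # mean over included bottles
    bottle_summaries: Dict[str, KineticSummary]
    qc_decisions: list
    methane: Optional[MethaneResult]
    calibration: Optional[GCCalibration]
    ddm: Optional[float]                     # trial-mean fraction
    ddm_per_bottle: Dict[str, float]
    ph_pre: Optional[float]
    ph_post: Optional[float]
    mean_curve: GasCurve
    curve_sem: np.ndarray
    n_negative_corrected: int

    def parameter_row(self) -> Dict[str, float]:
        row = {"trial_id": self.trial_id, "donor_type": self.donor_type}
        for h, v in self.summary.tgp_at_h.items():
            row[f"TGP_{h:g}h"] = v
        row.update(
            H=self.summary.H, H1_h=self.summary.H1_h,
            Vmax=self.summary.Vmax, Tmax_h=self.summary.Tmax_h,
        )
        if self.ddm is not None:
            row["dDM_pct"] = 100.0 * self.ddm
        if self.methane is not None:
            row["CH4_pct"] = self.methane.ch4_percent
            row["CH4_yield"] = self.methane.ch4_yield
        if self.ph_pre is not None:
            row["pH_pre"] = self.ph_pre
        if self.ph_post is not None:
            row["pH_post"] = self.ph_post
        return row


@dataclass
class StudyResult:
    trials: List[TrialResult]
    per_trial: pd.DataFrame
    per_bottle: pd.DataFrame
    repeatability: pd.DataFrame
    model_fits: Dict[str, stats.ModelFit]
    summary: dict


def _stage(name: str):
    """Decorate trial-stage failures with the stage name for the run log."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise IvgpError(f"stage '{name}' failed: {exc}") from exc
    return _ctx()


def _mean_summary(summaries: List[KineticSummary]) -> KineticSummary:
    hours = summaries[0].tgp_at_h.keys()
    return KineticSummary(
        tgp_at_h={h: float(np.mean([s.tgp_at_h[h] for s in summaries])) for h in hours},
        tgp_end=float(np.mean([s.tgp_end for s in summaries])),
        H=float(np.mean([s.H for s in summaries])),
        H1_h=float(np.mean([s.H1_h for s in summaries])),
        Vmax=float(np.mean([s.Vmax for s in summaries])),
        Tmax_h=float(np.mean([s.Tmax_h for s in summaries])),
    )


def analyze_trial(trial_dir, config: Optional[RunConfig] = None) -> TrialResult:
    """Run the per-trial analysis on one canonical trial directory."""
    cfg = config or RunConfig()
    trial_dir = Path(trial_dir)

    with _stage(f"io({trial_dir.name})"):
        meta = io.read_trial_meta(trial_dir / "meta.yaml")
        bottle_table = io.read_bottle_table(trial_dir / "bottles.csv")
        runs = io.read_pressure_log(trial_dir / "pressure_log.csv", bottle_table=bottle_table)
        for r in runs:
            r.trial_id = r.trial_id or meta.trial_id
        std_path = trial_dir / "gc_standards.csv"
        bags_path = trial_dir / "gc_bags.csv"
        standards = io.read_gc_standards(std_path) if std_path.exists() else None
        bags = io.read_gc_bags(bags_path) if bags_path.exists() else None
        res_path = trial_dir / "residues.csv"
        residues = io.read_residues(res_path) if res_path.exists() else None
    return analyze_trial_data(meta, runs, standards, bags, residues, cfg)


def analyze_trial_data(
    meta: TrialMeta,
    runs,
    standards=None,
    bags=None,
    residues=None,
    config: Optional[RunConfig] = None,
) -> TrialResult:
    """Per-trial analysis on in-memory inputs (see :func:`analyze_trial`).

    ``standards``/``bags``/``residues`` are the canonical DataFrames
    (or None to skip the corresponding stage).
    """
    cfg = config or RunConfig()
    if cfg.physics_overrides:
        meta.physics = meta.physics.with_overrides(**cfg.physics_overrides)
    blanks = [r for r in runs if r.role == "blank"]
    samples = [r for r in runs if r.role == "sample"]
    if not samples:
        raise IvgpError(f"trial {meta.trial_id}: no sample bottles")
    grid = samples[0].time_min

    with _stage("blank_correction"):
        profile = blank.build_blank_profile(
            blanks, grid, smooth_window=cfg.blank_smooth_window, blank_id=cfg.blank_id
        )
        corrected = {s.bottle_id: blank.correct_sample(s, profile) for s in samples}
    n_negative = int(sum((c < 0).sum() for c in corrected.values()))

    with _stage("gas"):
        curves = [
            gas.to_gas_curve(
                corrected[s.bottle_id], grid, s.substrate_dm_g, meta.physics,
                bottle_id=s.bottle_id, trial_id=meta.trial_id,
            )
            for s in samples
        ]

    with _stage("qc"):
        included, decisions = qc.filter_technical_replicates(
            curves, threshold=cfg.qc_threshold, at_hour=cfg.qc_hour,
            iterative=cfg.qc_iterative,
        )
        if not included:
            raise QCError(
                f"trial {meta.trial_id}: all technical replicates excluded at "
                f"{cfg.qc_hour:g} h; trial unusable"
            )

    with _stage("kinetics"):
        bottle_summaries = {
            c.bottle_id: kinetics.curve_parameters(c, end_hour=cfg.end_hour) for c in curves
        }
        summary = _mean_summary([bottle_summaries[c.bottle_id] for c in included])
        mean_curve, curve_sem = kinetics.average_curves(included)

    included_ids = {c.bottle_id for c in included}

    ch4_result = None
    calibration = None
    if standards is not None and bags is not None:
        with _stage("methane"):
            levels = [
                (p, qc.average_gc_replicates(g["area"], threshold=cfg.qc_threshold))
                for p, g in standards.groupby("ch4_percent")
            ]
            calibration = methane.fit_calibration(levels)
            pcts, clipped_any = [], False
            for bid, g in bags.groupby("bottle_id"):
                if str(bid) not in included_ids:
                    continue
                area = qc.average_gc_replicates(g["area"], threshold=cfg.qc_threshold)
                pct, clipped = methane.predict_ch4_percent(area, calibration)
                clipped_any |= clipped
                pcts.append(pct)
            if pcts:
                ch4_pct = float(np.mean(pcts))
                if cfg.yield_basis == "blank_corrected":
                    tgp_basis = summary.tgp_at_h.get(cfg.end_hour, summary.tgp_end)
                else:
                    raw_curves = [
                        gas.to_gas_curve(
                            s.cum_at(grid), grid, s.substrate_dm_g, meta.physics,
                            bottle_id=s.bottle_id,
                        )
                        for s in samples
                        if s.bottle_id in included_ids
                    ]
                    tgp_basis = float(
                        np.mean([kinetics.tgp_at(c, cfg.end_hour) for c in raw_curves])
                    )
                ch4_result = MethaneResult(
                    trial_id=meta.trial_id,
                    ch4_percent=ch4_pct,
                    ch4_yield=methane.ch4_yield(tgp_basis, ch4_pct),
                    clipped=clipped_any,
                )

    ddm_mean = None
    ddm_per_bottle: Dict[str, float] = {}
    if residues is not None:
        with _stage("degradation"):
            res = residues.set_index(residues["bottle_id"].astype(str))
            blank_ids = [b.bottle_id for b in blanks if b.bottle_id in res.index]
            if blank_ids:
                biomass = degradation.mean_blank_biomass(res.loc[blank_ids, "residue_g"])
                dm_by_id = {s.bottle_id: s.substrate_dm_g for s in samples}
                for bid, dm in dm_by_id.items():
                    if bid in res.index:
                        ddm_per_bottle[bid] = degradation.compute_ddm(
                            float(res.loc[bid, "residue_g"]), biomass, dm
                        )
                inc = [v for k, v in ddm_per_bottle.items() if k in included_ids]
                if inc:
                    ddm_mean = float(np.mean(inc))

    return TrialResult(
        trial_id=meta.trial_id,
        donor_type=meta.donor_type,
        meta=meta,
        summary=summary,
        bottle_summaries=bottle_summaries,
        qc_decisions=decisions,
        methane=ch4_result,
        calibration=calibration,
        ddm=ddm_mean,
        ddm_per_bottle=ddm_per_bottle,
        ph_pre=float(np.mean(meta.rumen_pH_pre)) if meta.rumen_pH_pre else None,
        ph_post=float(np.mean(meta.filtrate_pH_post)) if meta.filtrate_pH_post else None,
        mean_curve=mean_curve,
        curve_sem=curve_sem,
        n_negative_corrected=n_negative,
    )


def analyze_dataset(dataset, config: Optional[RunConfig] = None) -> TrialResult:
    """Analyse an in-memory simulated trial (:class:`ivgp.synthetic.TrialDataset`)."""
    bag_rows = [
        {"bottle_id": b.bottle_id, "replicate": i, "area": a}
        for b in dataset.bottles
        if b.bag_areas
        for i, a in enumerate(b.bag_areas, 1)
    ]
    residue_rows = [
        {"bottle_id": b.bottle_id, "empty_bag_g": 0.0, "bag_after_g": b.residue_g,
         "residue_g": b.residue_g}
        for b in dataset.bottles
        if b.residue_g is not None
    ]
    return analyze_trial_data(
        dataset.meta,
        dataset.bottles,
        standards=dataset.gc_standards,
        bags=pd.DataFrame(bag_rows) if bag_rows else None,
        residues=pd.DataFrame(residue_rows) if residue_rows else None,
        config=config,
    )


def run_pipeline(config: RunConfig) -> StudyResult:
    """Analyse every ``trial_*`` directory under ``config.input_dir``.

    Writes per-bottle and per-trial CSVs plus ``summary.json`` when
    ``config.output_dir`` is set.
    """
    if config.input_dir is None:
        raise ValidationError("run_pipeline requires config.input_dir")
    trial_dirs = sorted(Path(config.input_dir).glob("trial_*"))
    if not trial_dirs:
        raise IvgpError(f"no trial_* directories under {config.input_dir}")

    trials = [analyze_trial(d, config) for d in trial_dirs]

    per_trial = pd.DataFrame([t.parameter_row() for t in trials])
    bottle_rows = []
    for t in trials:
        dec = {d.bottle_id: d for d in t.qc_decisions}
        for bid, s in t.bottle_summaries.items():
            d = dec.get(bid)
            bottle_rows.append(
                {
                    "trial_id": t.trial_id, "bottle_id": bid, "donor_type": t.donor_type,
                    "included": d.included if d else True,
                    "deviation_at_12h": d.deviation_at_12h if d else 0.0,
                    "qc_reason": d.reason if d else "",
                    "TGP_24h": s.tgp_at_h.get(24.0, s.tgp_end),
                    "H": s.H, "H1_h": s.H1_h, "Vmax": s.Vmax, "Tmax_h": s.Tmax_h,
                    "dDM": t.ddm_per_bottle.get(bid),
                }
            )
    per_bottle = pd.DataFrame(bottle_rows)

    # long-format per-trial parameter table for the statistics layer
    long_rows = []
    for t in trials:
        row = t.parameter_row()
        for p in PARAMETERS:
            if p in row and row[p] is not None:
                long_rows.append(
                    {"parameter": p, "trial_id": t.trial_id,
                     "donor_type": t.donor_type, "value": row[p]}
                )
    long_df = pd.DataFrame(long_rows)

    with _stage("stats"):
        repeat = stats.repeatability_report(long_df)
        model_fits: Dict[str, stats.ModelFit] = {}
        if long_df["donor_type"].nunique() == 2:
            for p, sub in long_df.groupby("parameter", sort=False):
                if sub.groupby("donor_type")["value"].count().min() >= 2:
                    model_fits[p] = stats.fit_trial_donor_model(sub, alpha=config.alpha)

    summary = {
        "n_trials": len(trials),
        "n_trials_by_donor": per_trial.groupby("donor_type")["trial_id"].count().to_dict(),
        "config": {
            "qc_threshold": config.qc_threshold,
            "qc_hour": config.qc_hour,
            "end_hour": config.end_hour,
            "alpha": config.alpha,
            "yield_basis": config.yield_basis,
            "headspace_ml": trials[0].meta.physics.headspace_ml,
            "stp_temp_K": trials[0].meta.physics.stp_temp_K,
            "stp_pressure_kPa": trials[0].meta.physics.stp_pressure_kPa,
        },
        "repeatability": repeat.to_dict(orient="records"),
        "donor_tests": {
            p: {
                "donor_p": f.donor_p,
                "interaction_p": f.interaction_p,
                "welch_t": f.welch.t if f.welch else None,
                "welch_df": f.welch.df if f.welch else None,
                "welch_p": f.welch.p if f.welch else None,
                "reduced_terms": f.reduced_terms,
                "warnings": f.warnings,
            }
            for p, f in model_fits.items()
        },
        "trials": {t.trial_id: t.parameter_row() for t in trials},
    }

    result = StudyResult(
        trials=trials, per_trial=per_trial, per_bottle=per_bottle,
        repeatability=repeat, model_fits=model_fits, summary=summary,
    )
    if config.output_dir is not None:
        io.write_report(result, config.output_dir)
    return result
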