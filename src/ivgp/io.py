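"""Reading and writing the pipeline's canonical file formats.

Canonical inputs per trial directory:

* ``pressure_log.csv`` — one row per (bottle, time point):
  ``bottle_id,time_min,abs_pressure_psi,cum_pressure_psi``. Other column
  names can be mapped via a dialect.
* ``bottles.csv`` — ``bottle_id,role,substrate_dm_g``.
* ``meta.yaml`` — trial metadata (donor type, pH readings, physics).
* ``gc_standards.csv`` — ``ch4_percent,area,replicate``.
* ``gc_bags.csv`` — ``bottle_id,replicate,area``.
* ``residues.csv`` — ``bottle_id,empty_bag_g,bag_after_g``.

Outputs: tidy per-bottle and per-trial CSVs plus a JSON summary, all at
full precision.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .types import BottleRun, PhysicsConfig, TrialMeta

__all__ = [
    "read_pressure_log",
    "read_bottle_table",
    "read_trial_meta",
    "read_gc_standards",
    "read_gc_bags",
    "read_residues",
    "write_trial_inputs",
    "write_report",
]

_LOG_COLUMNS = ("bottle_id", "time_min", "cum_pressure_psi")


def _validated(**kw) -> BottleRun:
    return BottleRun(**kw).validate_monotone()


def _read_csv(path, required: tuple, dialect: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    try:
        # round_trip parser: values reload bit-identically to what was written
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise FormatError(f"input file not found: {path}")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_pressure_log(
    path,
    dialect: Optional[Dict[str, str]] = None,
    bottle_table: Optional[pd.DataFrame] = None,
) -> List[BottleRun]:
    """Read a cumulative-pressure log into one :class:`BottleRun` per bottle.

    ``dialect`` maps canonical column names to the file's column names for
    vendor exports (e.g. ``{"bottle_id": "Module"}``). ``bottle_table``
    (from :func:`read_bottle_table`) supplies role and substrate mass;
    without it every bottle is read as a substrate-free sample.

    Series are sorted by time; non-decreasing cumulative pressure is
    enforced (a decreasing register indicates a corrupt export).
    """
    df = _read_csv(path, _LOG_COLUMNS, dialect)
    roles: Dict[str, tuple] = {}
    if bottle_table is not None:
        for _, r in bottle_table.iterrows():
            roles[str(r["bottle_id"])] = (str(r["role"]), float(r["substrate_dm_g"]))

    runs = []
    for bid, g in df.groupby("bottle_id", sort=False):
        g = g.sort_values("time_min")
        role, dm = roles.get(str(bid), ("sample", 0.0))
        runs.append(
            _validated(
                bottle_id=str(bid),
                trial_id=str(g["trial_id"].iloc[0]) if "trial_id" in g else "",
                role=role,
                substrate_dm_g=dm,
                time_min=g["time_min"].to_numpy(dtype=float),
                cum_pressure_psi=g["cum_pressure_psi"].to_numpy(dtype=float),
                abs_pressure_psi=(
                    g["abs_pressure_psi"].to_numpy(dtype=float)
                    if "abs_pressure_psi" in g
                    else None
                ),
            )
        )
    return runs


def read_bottle_table(path) -> pd.DataFrame:
    return _read_csv(path, ("bottle_id", "role", "substrate_dm_g"))


def read_trial_meta(path) -> TrialMeta:
    """Read the YAML trial-metadata file, applying physics defaults."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise FormatError(f"metadata file not found: {path}")
    if "donor_type" not in doc:
        raise FormatError(f"{path}: missing required key 'donor_type'")
    physics = PhysicsConfig(**doc.get("physics", {}))
    return TrialMeta(
        trial_id=str(doc.get("trial_id", Path(path).parent.name)),
        donor_type=str(doc["donor_type"]),
        rumen_pH_pre=[float(x) for x in doc.get("rumen_pH_pre", [])],
        filtrate_pH_post=[float(x) for x in doc.get("filtrate_pH_post", [])],
        physics=physics,
        record_interval_min=int(doc.get("record_interval_min", 10)),
    )


def read_gc_standards(path) -> pd.DataFrame:
    return _read_csv(path, ("ch4_percent", "area", "replicate"))


def read_gc_bags(path) -> pd.DataFrame:
    return _read_csv(path, ("bottle_id", "replicate", "area"))


def read_residues(path) -> pd.DataFrame:
    """Residue weights; dried residue = bag_after_g - empty_bag_g."""
    df = _read_csv(path, ("bottle_id", "empty_bag_g", "bag_after_g"))
    df["residue_g"] = df["bag_after_g"] - df["empty_bag_g"]
    if (df["residue_g"] < 0).any():
        bad = df.loc[df["residue_g"] < 0, "bottle_id"].tolist()
        raise ValidationError(f"negative dried residue for bottles {bad}")
    return df


def write_trial_inputs(dataset, trial_dir) -> None:
    """Write one simulated trial as the canonical input files.

    ``dataset`` is a :class:`ivgp.synthetic.TrialDataset`. A per-bottle
    ground-truth CSV is written alongside but never read by the pipeline.
    """
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)

    log_rows, bottle_rows, bag_rows, residue_rows, truth_rows = [], [], [], [], []
    for b in dataset.bottles:
        for t, cum, ab in zip(b.time_min, b.cum_pressure_psi, b.abs_pressure_psi):
            log_rows.append(
                {"bottle_id": b.bottle_id, "time_min": int(t),
                 "abs_pressure_psi": ab, "cum_pressure_psi": cum}
            )
        bottle_rows.append(
            {"bottle_id": b.bottle_id, "role": b.role, "substrate_dm_g": b.substrate_dm_g}
        )
        if b.bag_areas:
            for i, a in enumerate(b.bag_areas, 1):
                bag_rows.append({"bottle_id": b.bottle_id, "replicate": i, "area": a})
        if b.residue_g is not None:
            residue_rows.append(
                {"bottle_id": b.bottle_id, "empty_bag_g": 0.5,
                 "bag_after_g": 0.5 + b.residue_g}
            )
        truth_rows.append({"bottle_id": b.bottle_id, **dataset.truth[b.bottle_id]})

    pd.DataFrame(log_rows).to_csv(trial_dir / "pressure_log.csv", index=False, float_format="%.17g")
    pd.DataFrame(bottle_rows).to_csv(trial_dir / "bottles.csv", index=False, float_format="%.17g")
    dataset.gc_standards.to_csv(trial_dir / "gc_standards.csv", index=False, float_format="%.17g")
    pd.DataFrame(bag_rows).to_csv(trial_dir / "gc_bags.csv", index=False, float_format="%.17g")
    pd.DataFrame(residue_rows).to_csv(trial_dir / "residues.csv", index=False, float_format="%.17g")
    pd.DataFrame(truth_rows).to_csv(trial_dir / "truth_bottles.csv", index=False, float_format="%.17g")

    m = dataset.meta
    doc = {
        "trial_id": m.trial_id,
        "donor_type": m.donor_type,
        "rumen_pH_pre": [float(x) for x in m.rumen_pH_pre],
        "filtrate_pH_post": [float(x) for x in m.filtrate_pH_post],
        "record_interval_min": m.record_interval_min,
        "physics": {
            "headspace_ml": m.physics.headspace_ml,
            "incubation_temp_C": m.physics.incubation_temp_C,
            "ambient_pressure_kPa": m.physics.ambient_pressure_kPa,
            "stp_temp_K": m.physics.stp_temp_K,
            "stp_pressure_kPa": m.physics.stp_pressure_kPa,
        },
    }
    with open(trial_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


class _NumpyJSON(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_report(results, out_dir) -> None:
    """Write per-bottle CSV, per-trial CSV and the JSON study summary.

    ``results`` must expose ``per_bottle`` and ``per_trial`` DataFrames
    and a JSON-serialisable ``summary`` dict (see
    :class:`ivgp.pipeline.StudyResult`). Numbers are written at full
    precision; empty result sets produce header-only files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        results.per_bottle.to_csv(out_dir / "bottles.csv", index=False, float_format="%.17g")
        results.per_trial.to_csv(out_dir / "trials.csv", index=False, float_format="%.17g")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(results.summary, fh, indent=2, cls=_NumpyJSON)
    except OSError as exc:
        raise OSError(f"cannot write report to {out_dir}: {exc}") from exc
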