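"""Ideal-gas conversion of gauge pressure to gas volume at STP.

The sensor records headspace gauge pressure (psi above concurrently
measured ambient). The moles of gas corresponding to a cumulative gauge
pressure p in a fixed headspace V_h at incubation temperature T_inc are
n = (p * V_h) / (R * T_inc); re-expanded at the STP convention this gives

    V_STP = p_kPa * V_h * T_STP / (T_inc * P_STP)

which is linear in p, so the conversion is a single multiplicative factor.
"""
from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .types import GasCurve, PhysicsConfig

__all__ = ["ml_stp_per_psi", "psi_to_ml_stp", "ml_stp_to_psi", "to_gas_curve"]


def ml_stp_per_psi(cfg: PhysicsConfig) -> float:
    """mL of gas at STP represented by 1 psi of gauge pressure in the headspace."""
    return (
        cfg.psi_to_kPa
        * cfg.headspace_ml
        * cfg.stp_temp_K
        / (cfg.incubation_temp_K * cfg.stp_pressure_kPa)
    )


def psi_to_ml_stp(cum_psi, cfg: PhysicsConfig):
    """Convert (cumulative) gauge pressure in psi to mL gas at STP.

    Accepts scalars or arrays; linear through the origin.
    """
    return np.multiply(cum_psi, ml_stp_per_psi(cfg))


def ml_stp_to_psi(ml_stp, cfg: PhysicsConfig):
    """Inverse of :func:`psi_to_ml_stp`."""
    return np.divide(ml_stp, ml_stp_per_psi(cfg))


def to_gas_curve(
    corrected_psi,
    grid_min,
    substrate_dm_g: float,
    cfg: PhysicsConfig,
    bottle_id: str = "",
    trial_id: str = "",
) -> GasCurve:
    """Blank-corrected cumulative pressure -> mL STP per g incubated DM.

    Only sample bottles carry substrate; blanks must never reach this step.
    """
    if substrate_dm_g <= 0:
        raise ValidationError(
            f"bottle {bottle_id or '?'}: substrate_dm_g must be > 0 for gas "
            f"normalisation, got {substrate_dm_g}"
        )
    ml = psi_to_ml_stp(np.asarray(corrected_psi, dtype=float), cfg) / substrate_dm_g
    return GasCurve(
        bottle_id=bottle_id, trial_id=trial_id, grid_min=np.asarray(grid_min, dtype=float),
        ml_stp_per_g_dm=ml,
    )
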