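"""Dry-matter degradation with baseline microbial-biomass correction.

The residue filtered from a blank bottle is the minimum microbial biomass
contributed by the inoculum itself; it is subtracted from each sample
bottle's residue before computing the fraction of incubated dry matter
degraded:

    dDM = 1 - (residue - blank_biomass) / sample_DM

Values outside [0, 1] (weighing noise) are retained and flagged rather
than truncated, so downstream repeatability statistics are not biased.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ValidationError
from .types import DegradationRecord

__all__ = ["compute_ddm", "degradation_record", "mean_blank_biomass"]


def compute_ddm(residue_g: float, blank_biomass_g: float, sample_dm_g: float) -> float:
    """Fraction of incubated DM degraded, blank-biomass corrected."""
    if sample_dm_g <= 0:
        raise ValidationError(f"sample_dm_g must be > 0, got {sample_dm_g}")
    if residue_g < 0 or blank_biomass_g < 0:
        raise ValidationError("residue and blank biomass weights must be >= 0")
    return 1.0 - (residue_g - blank_biomass_g) / sample_dm_g


def mean_blank_biomass(blank_residues_g: Sequence[float]) -> float:
    """Arithmetic mean of blank-bottle residues (single-blank fallback included)."""
    residues = np.asarray(list(blank_residues_g), dtype=float)
    if residues.size == 0:
        raise ValidationError("no blank residues available for biomass correction")
    return float(residues.mean())


def degradation_record(
    bottle_id: str, residue_g: float, blank_biomass_g: float, sample_dm_g: float
) -> DegradationRecord:
    ddm = compute_ddm(residue_g, blank_biomass_g, sample_dm_g)
    return DegradationRecord(
        bottle_id=bottle_id,
        residue_g=residue_g,
        blank_biomass_g=blank_biomass_g,
        sample_dm_g=sample_dm_g,
        ddm=ddm,
        out_of_range=not (0.0 <= ddm <= 1.0),
    )
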