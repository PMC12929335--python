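"""MR-PDFF-equivalent fat fraction from liver attenuation.

A validated linear relation converts non-contrast (or corrected
non-contrast-equivalent) mean liver attenuation L (HU) into an estimated
magnetic-resonance proton density fat fraction:

    FF (%) = -0.58 * L + 38.2

The moderate-to-severe steatosis reference of L < 40 HU corresponds exactly
to FF > 15% under this line, so classification by either statistic is
algebraically identical.  Implausible inputs are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import math

from .correction import PUBLISHED_MODELS, CorrectionModel, correct

__all__ = [
    "FF_SLOPE",
    "FF_INTERCEPT",
    "STEATOSIS_L_THRESHOLD_HU",
    "STEATOSIS_FF_THRESHOLD_PCT",
    "FatFractionResult",
    "ff_from_attenuation",
    "classify",
    "end_to_end",
]

FF_SLOPE = -0.58
FF_INTERCEPT = 38.2

# L < 40 HU and FF > 15% define the same moderate-to-severe steatosis call.
STEATOSIS_L_THRESHOLD_HU = 40.0
STEATOSIS_FF_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class FatFractionResult:
    """Estimated fat fraction plus provenance and quality flags."""

    ff_percent: float
    source_phase: str
    corrected_l: float
    flags: frozenset = field(default_factory=frozenset)


def ff_from_attenuation(l_nc_equivalent: float, source_phase: str = "non-contrast") -> FatFractionResult:
    """Apply the linear CT-to-PDFF conversion to a non-contrast-equivalent L.

    Negative fat fractions (very dense livers) are reported as-is and
    carry a ``negative_ff`` flag for downstream QC.
    """
    l = float(l_nc_equivalent)
    if not math.isfinite(l):
        raise ValueError("liver attenuation must be finite")
    ff = FF_SLOPE * l + FF_INTERCEPT
    flags = set()
    if ff < 0:
        flags.add("negative_ff")
    return FatFractionResult(ff, source_phase, l, frozenset(flags))


def classify(value: float, threshold: float, direction: str) -> bool:
    """Strict threshold call: ``less_than`` means value < threshold."""
    if direction == "less_than":
        return value < threshold
    if direction == "greater_than":
        return value > threshold
    raise ValueError(f"direction must be 'less_than' or 'greater_than', got {direction!r}")


def end_to_end(
    l_post: float,
    phase: str,
    models: Mapping[str, CorrectionModel] = PUBLISHED_MODELS,
) -> FatFractionResult:
    """Measured liver attenuation in any phase -> corrected L -> FF.

    Non-contrast input bypasses correction.  Non-positive post-contrast
    attenuation is physically implausible and flagged.
    """
    l_post = float(l_post)
    if phase == "non-contrast":
        return ff_from_attenuation(l_post, source_phase=phase)
    if phase not in models:
        raise KeyError(f"no correction model registered for phase {phase!r}")
    corrected = correct(l_post, models[phase])
    result = ff_from_attenuation(corrected, source_phase=phase)
    flags = set(result.flags)
    if l_post <= 0:
        flags.add("implausible_input")
    return FatFractionResult(result.ff_percent, phase, corrected, frozenset(flags))
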