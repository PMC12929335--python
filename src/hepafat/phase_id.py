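"""Scan-level contrast-phase determination by confidence-weighted voting.

A slice-level classifier assigns each sampled axial slice one of four phase
labels with a confidence score; the scan-level phase is the label whose
confidences sum highest.  Ties are broken by a fixed, documented phase
order so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = ["PHASES", "SlicePrediction", "VoteResult", "vote_phase"]

logger = logging.getLogger(__name__)

PHASES = ("non-contrast", "arterial", "venous", "delayed")

# Fixed tie-break precedence (earlier wins on an exact weight tie).
_TIE_ORDER = ("non-contrast", "delayed", "venous", "arterial")


@dataclass(frozen=True)
class SlicePrediction:
    slice_index: int
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if self.label not in PHASES:
            raise ValueError(f"label must be one of {PHASES}, got {self.label!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class VoteResult:
    label: str
    weights: dict
    tied: bool
    method: str  # "confidence" or "count" (all-zero confidence fallback)


def vote_phase(predictions) -> VoteResult:
    """Return the confidence-weighted majority phase over slice predictions.

    The full per-label weight table is returned for audit.  If every
    confidence is zero the vote falls back to an unweighted slice count.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("need at least one slice prediction to vote")

    method = "confidence"
    weights = {phase: 0.0 for phase in PHASES}
    if all(p.confidence == 0.0 for p in predictions):
        logger.warning("all slice confidences are zero; falling back to unweighted majority")
        method = "count"
        for p in predictions:
            weights[p.label] += 1.0
    else:
        for p in predictions:
            weights[p.label] += p.confidence

    top = max(weights.values())
    leaders = [phase for phase in _TIE_ORDER if weights[phase] == top]
    return VoteResult(label=leaders[0], weights=weights, tied=len(leaders) > 1, method=method)
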