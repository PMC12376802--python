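"""Composite 0-4 inflammation score.

Each of the four markers (BEC, total IgE, FENO, skin prick) is dichotomized
at a predefined cutoff — inclusive ``>=`` comparison, so a value exactly at
the cutoff scores 1 — and the four indicators are summed. Classification at
a score threshold ``t`` is "positive iff score >= t", which expresses both
reported operating rules under one convention: the ">2 points" rule is
``t=3`` and the "2 points" rule is ``t=2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, Participant
from .errors import MissingDataError

__all__ = [
    "CutoffConfig",
    "IndicatorVector",
    "CompositeScore",
    "dichotomize",
    "composite_score",
    "classify",
    "score_participant",
    "score_cohort",
]

SCORE_COLUMNS = ["feno_high", "ige_high", "bec_high", "prick_high", "composite_score"]


@dataclass(frozen=True)
class CutoffConfig:
    """Dichotomization thresholds; comparison is always inclusive (>=)."""

    bec_cutoff: float = 150.0   # cells/uL
    ige_cutoff: float = 100.0   # IU/mL
    feno_cutoff: float = 25.0   # ppb

    def __post_init__(self) -> None:
        for name in ("bec_cutoff", "ige_cutoff", "feno_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class IndicatorVector:
    bec_high: bool
    ige_high: bool
    feno_high: bool
    prick_positive: bool

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            int(self.bec_high),
            int(self.ige_high),
            int(self.feno_high),
            int(self.prick_positive),
        )


@dataclass(frozen=True)
class CompositeScore:
    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 4:
            raise ValueError(f"composite score must be in 0..4, got {self.value}")

    def __int__(self) -> int:
        return self.value


def dichotomize(p: Participant, cfg: CutoffConfig | None = None) -> IndicatorVector:
    """Map a participant's panel to four 0/1 indicators (>= cutoff scores 1)."""
    cfg = cfg or CutoffConfig()
    for marker in ("feno", "ige", "bec"):
        if getattr(p, marker) is None:
            raise MissingDataError(f"participant {p.id}: missing biomarker {marker!r}")
    return IndicatorVector(
        bec_high=p.bec >= cfg.bec_cutoff,
        ige_high=p.ige >= cfg.ige_cutoff,
        feno_high=p.feno >= cfg.feno_cutoff,
        prick_positive=p.prick_positive,
    )


def composite_score(iv: IndicatorVector) -> CompositeScore:
    """Sum of the four indicators."""
    return CompositeScore(sum(iv.as_tuple()))


def score_participant(p: Participant, cfg: CutoffConfig | None = None) -> CompositeScore:
    return composite_score(dichotomize(p, cfg))


def classify(score: CompositeScore | int, threshold: int) -> bool:
    """Test-positive iff score >= threshold, threshold in 1..4."""
    if threshold not in (1, 2, 3, 4):
        raise ValueError(f"threshold must be in 1..4, got {threshold}")
    return int(score) >= threshold


def score_cohort(cohort: Cohort, cfg: CutoffConfig | None = None) -> pd.DataFrame:
    """Cohort frame with indicator and composite-score columns appended."""
    cfg = cfg or CutoffConfig()
    frame = cohort.to_frame()
    ivs = [dichotomize(p, cfg) for p in cohort]
    frame["feno_high"] = [int(iv.feno_high) for iv in ivs]
    frame["ige_high"] = [int(iv.ige_high) for iv in ivs]
    frame["bec_high"] = [int(iv.bec_high) for iv in ivs]
    frame["prick_high"] = [int(iv.prick_positive) for iv in ivs]
    frame["composite_score"] = [int(composite_score(iv)) for iv in ivs]
    return frame
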