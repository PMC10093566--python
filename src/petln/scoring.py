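"""SUV ratio features and the two composite malignancy scores.

Four ratios normalize a node's SUVmax by patient-level reference uptakes
(primary tumor, liver, brainstem, contralateral healthy lung).  Two scoring
systems build on them:

* the *quantified visual score* (1-3) orders the node's maximum uptake
  against liver and primary-tumor uptake, mirroring clinical visual reading;
* the *multifactorial score* (0-5) counts how many of five thresholded
  conditions hold — SUVmax and the four ratios, each compared inclusively
  (>=) against cut-offs originally derived by ROC analysis.

Both scores classify a node as malignant at score >= 3 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import ReferenceUptake

__all__ = [
    "RatioSet",
    "ScoreThresholds",
    "VisualScoreQ",
    "MultiScore",
    "compute_ratios",
    "visual_score_q",
    "multifactorial_score",
    "classify",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatioSet:
    """The four node-to-reference SUVmax ratios."""

    ln_to_primary: float
    ln_to_liver: float
    ln_to_brainstem: float
    ln_to_lung: float

    def __post_init__(self) -> None:
        for name in ("ln_to_primary", "ln_to_liver", "ln_to_brainstem", "ln_to_lung"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ratio {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class ScoreThresholds:
    """Cut-offs of the five multifactorial-score conditions.

    Defaults are the clinically derived values; they can be overridden, e.g.
    with thresholds re-derived on a new cohort via
    :func:`petln.performance.optimal_cutoff`.
    """

    suvmax_t: float = 5.495
    primary_t: float = 0.457
    liver_t: float = 1.374
    brainstem_t: float = 0.749
    lung_t: float = 4.593

    def __post_init__(self) -> None:
        for name in ("suvmax_t", "primary_t", "liver_t", "brainstem_t", "lung_t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"threshold {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class VisualScoreQ:
    """Quantified visual reading score: 1, 2 or 3."""

    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError(f"visual score must be 1, 2 or 3, got {self.score}")


@dataclass(frozen=True)
class MultiScore:
    """Multifactorial score 0-5 with the five condition flags (I-V)."""

    score: int
    condition_flags: tuple[bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.condition_flags) != 5:
            raise ValueError("exactly five condition flags (I-V) are required")
        if self.score != sum(self.condition_flags):
            raise ValueError("score must equal the number of fulfilled conditions")

    @property
    def flags_string(self) -> str:
        """Flags I-V as a 5-character 0/1 string (for CSV columns)."""
        return "".join("1" if f else "0" for f in self.condition_flags)


def compute_ratios(node_suvmax: float, refs: ReferenceUptake) -> RatioSet:
    """The four unrounded quotients node SUVmax / reference SUVmax."""
    if not np.isfinite(node_suvmax) or node_suvmax <= 0:
        raise ValueError(f"node suvmax must be finite and > 0, got {node_suvmax}")
    for organ, ref in [
        ("primary", refs.primary_suvmax), ("liver", refs.liver_suvmax),
        ("brainstem", refs.brainstem_suvmax), ("lung", refs.lung_suvmax),
    ]:
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError(f"reference uptake of {organ} must be finite and > 0, got {ref}")
    return RatioSet(
        ln_to_primary=node_suvmax / refs.primary_suvmax,
        ln_to_liver=node_suvmax / refs.liver_suvmax,
        ln_to_brainstem=node_suvmax / refs.brainstem_suvmax,
        ln_to_lung=node_suvmax / refs.lung_suvmax,
    )


def visual_score_q(ln_suvmax: float, liver_suvmax: float, primary_suvmax: float) -> VisualScoreQ:
    """Quantified visual score of a node against liver and primary uptake.

    Score 1: node <= liver; score 2: liver < node <= primary; score 3:
    node > primary.  Conditions are evaluated in that order, so in the
    degenerate case primary < liver a node with primary < node <= liver
    still receives score 1 (first matching rule wins); this configuration is
    logged because the ordering assumption liver <= primary then fails.
    """
    for name, v in [("ln_suvmax", ln_suvmax), ("liver_suvmax", liver_suvmax),
                    ("primary_suvmax", primary_suvmax)]:
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {v}")
    if primary_suvmax < liver_suvmax:
        log.warning(
            "visual score: primary SUVmax (%.3f) below liver SUVmax (%.3f); "
            "rules applied in listed order", primary_suvmax, liver_suvmax,
        )
    if ln_suvmax <= liver_suvmax:
        return VisualScoreQ(1)
    if ln_suvmax <= primary_suvmax:
        return VisualScoreQ(2)
    return VisualScoreQ(3)


def multifactorial_score(
    node_suvmax: float,
    ratios: RatioSet,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> MultiScore:
    """Count the fulfilled conditions I-V (one point each, inclusive >=).

    I: SUVmax >= suvmax_t; II: node/primary >= primary_t; III: node/liver >=
    liver_t; IV: node/brainstem >= brainstem_t; V: node/lung >= lung_t.
    """
    if not np.isfinite(node_suvmax) or node_suvmax <= 0:
        raise ValueError(f"node suvmax must be finite and > 0, got {node_suvmax}")
    flags = (
        node_suvmax >= thresholds.suvmax_t,
        ratios.ln_to_primary >= thresholds.primary_t,
        ratios.ln_to_liver >= thresholds.liver_t,
        ratios.ln_to_brainstem >= thresholds.brainstem_t,
        ratios.ln_to_lung >= thresholds.lung_t,
    )
    return MultiScore(score=int(sum(flags)), condition_flags=flags)


def classify(score: int, cutoff: int = 3, max_score: int = 5) -> str:
    """Dichotomize a score: ``"positive"`` iff score >= cutoff."""
    if not (0 <= score <= max_score):
        raise ValueError(f"score {score} outside the valid range 0-{max_score}")
    if not (1 <= cutoff <= max_score):
        raise ValueError(f"cutoff {cutoff} outside the valid range 1-{max_score}")
    return "positive" if score >= cutoff else "negative"
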