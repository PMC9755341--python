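"""Heart-to-mediastinum ratios and pathological classification.

The ratio is the mean counts/pixel in the cardiac ROI divided by the mean
counts/pixel in the mediastinal ROI (mean, not integrated, so that ROI areas
that differ between methods and raters do not bias the ratio).  A scan is
pathological iff the ratio is strictly below the cut-off (default 1.9 for
the early phase, 1.7 for the late phase); ties classify as non-pathological.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .errors import DivisionError, ValidationError
from .roi import ROI, mean_counts

__all__ = ["HMResult", "Classification", "DEFAULT_CUTOFFS", "hm_ratio", "classify"]

DEFAULT_CUTOFFS: Tuple[float, float] = (1.9, 1.7)  # (early, late)


@dataclass(frozen=True)
class HMResult:
    early_hm: float
    late_hm: float
    method: str
    rater: str
    subject_id: str

    def __post_init__(self) -> None:
        for name, v in (("early_hm", self.early_hm), ("late_hm", self.late_hm)):
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class Classification:
    early_pathological: bool
    late_pathological: bool
    cutoff_early: float = DEFAULT_CUTOFFS[0]
    cutoff_late: float = DEFAULT_CUTOFFS[1]

    def __post_init__(self) -> None:
        if self.cutoff_early <= 0 or self.cutoff_late <= 0:
            raise ValidationError("cut-offs must be > 0")


def hm_ratio(image, cardiac_roi: ROI, mediastinal_roi: ROI) -> float:
    """Mean cardiac counts/pixel divided by mean mediastinal counts/pixel."""
    med = mean_counts(image, mediastinal_roi)
    if med <= 0:
        raise DivisionError(f"mediastinal ROI mean counts is {med}, cannot form a ratio")
    return mean_counts(image, cardiac_roi) / med


def classify(
    early_hm: float,
    late_hm: float,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
) -> Classification:
    """Label each phase pathological iff its ratio is strictly below cut-off."""
    cutoff_early, cutoff_late = cutoffs
    for name, v in (("early_hm", early_hm), ("late_hm", late_hm)):
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be finite and > 0, got {v}")
    return Classification(
        early_pathological=early_hm < cutoff_early,
        late_pathological=late_hm < cutoff_late,
        cutoff_early=cutoff_early,
        cutoff_late=cutoff_late,
    )
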