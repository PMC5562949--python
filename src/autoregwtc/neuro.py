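"""Neuroimaging abnormality scoring for ECMO patients.

Brain imaging (head ultrasound during ECMO, CT during ECMO, or MRI after
decannulation) is rated in three categories of abnormality — bleeding,
parenchymal lesions (ischemia/infarction), and ventricular dilatation —
each with a severity from 0 (absent) to 3.  Each severity is multiplied by
a category weight and summed into a total score.  The weight factors come
from a previously validated ECMO scoring system and are supplied through
configuration; the category boundaries of the total are fixed:

- ``NORMAL``: total = 0
- ``MILD_MODERATE``: 0 < total <= 6.0
- ``SEVERE``: total > 6.0 (no upper cap is enforced)

The boundary total of exactly 6.0 is mild-to-moderate; this is the only
assignment consistent with the published category counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Severity", "Category", "Modality", "NeuroScore", "total_score", "categorize"]

_VALID_SEVERITIES = (0, 1, 2, 3)
SEVERE_THRESHOLD = 6.0


class Category(str, enum.Enum):
    NORMAL = "normal"
    MILD_MODERATE = "mild_moderate"
    SEVERE = "severe"


class Modality(str, enum.Enum):
    ULTRASOUND = "ultrasound"
    CT = "CT"
    MRI = "MRI"


def total_score(
    bleeding: int,
    parenchymal: int,
    ventricular: int,
    weights: tuple[float, float, float],
) -> float:
    """Weighted sum of the three severity ratings.

    Severities must be integers in 0..3; weights must be positive (they may
    be fractional — the published category range starting at 0.5 implies a
    half-point weight exists).
    """
    sev = (bleeding, parenchymal, ventricular)
    for name, s in zip(("bleeding", "parenchymal", "ventricular"), sev):
        if s not in _VALID_SEVERITIES:
            raise ValueError(f"{name} severity must be one of {_VALID_SEVERITIES}, got {s!r}")
    if len(weights) != 3 or any(w <= 0 for w in weights):
        raise ValueError("three positive category weights are required")
    return float(sum(s * w for s, w in zip(sev, weights)))


def categorize(total: float) -> Category:
    """Map a total score onto the normal / mild-moderate / severe categories."""
    if not total >= 0:
        raise ValueError("total score must be non-negative")
    if total == 0:
        return Category.NORMAL
    if total <= SEVERE_THRESHOLD:
        return Category.MILD_MODERATE
    return Category.SEVERE


@dataclass(frozen=True)
class NeuroScore:
    """One patient's neuroimaging assessment."""

    bleeding: int
    parenchymal: int
    ventricular: int
    weights: tuple[float, float, float]
    modality: Modality = Modality.MRI
    timing: str = ""

    @property
    def total(self) -> float:
        return total_score(self.bleeding, self.parenchymal, self.ventricular, self.weights)

    @property
    def category(self) -> Category:
        return categorize(self.total)
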