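"""Deterministic clinical outcome metrics.

The 4-point global histopathology score (1 = normal placental histology,
4 = severely abnormal), the small-for-gestational-age classification at
the 10th birth-weight percentile, and twin birth-weight discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

SEVERITIES = ("minor", "moderate", "severe_listed")


@dataclass(frozen=True)
class PathologyFinding:
    """One histopathology finding with its severity class.

    Minor: e.g. chorangiosis in a normal-weight placenta, placental weight
    outside the 10th–90th percentiles, low-grade fetal vascular
    malperfusion.  Moderate: e.g. high-grade fetal vascular malperfusion,
    diffuse chorangiosis, fetal normoblastemia, extensive perivillous
    fibrin, infarcts of >5% of placental mass.  ``severe_listed`` marks a
    finding explicitly graded severe on its own.
    """

    name: str = ""
    severity: str = "minor"

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValidationError(f"unknown severity {self.severity!r}")


@dataclass
class TwinRecord:
    """Per-fetus outcomes linked to the placental ROI summary."""

    pair_id: str
    twin_label: str  # "A" or "B"
    ga_at_mri: float = float("nan")  # weeks
    scan_to_birth: float = float("nan")  # weeks
    birth_weight: float = float("nan")  # grams
    weight_percentile: float = float("nan")
    efw: float = float("nan")  # grams
    doppler_grade: int | None = None
    brain_volume: float = float("nan")  # cm^3
    liver_volume: float = float("nan")  # cm^3
    findings: list = field(default_factory=list)
    ttp_mean: float = float("nan")  # minutes

    @property
    def pathology_score(self) -> int:
        return pathology_score(self.findings)

    @property
    def growth_class(self) -> str:
        return classify_sga(self.weight_percentile)


def _severity(f) -> str:
    s = f.severity if isinstance(f, PathologyFinding) else str(f)
    if s not in SEVERITIES:
        raise ValidationError(f"unknown severity {s!r}")
    return s


def pathology_score(findings) -> int:
    """Global 4-point histopathology score from a findings list.

    Printed rules: one minor → 1; two minor → 2; one moderate → 2; one
    minor plus one moderate → 3; two (or more) moderate, three (or more)
    minor, or any finding listed as severe → 4.  An empty list scores 1
    (normal).  Combinations not covered by a printed sentence resolve to
    the maximum of all applicable rules, so adding a finding can never
    lower the score.
    """
    sevs = [_severity(f) for f in findings]
    m = sevs.count("minor")
    mod = sevs.count("moderate")
    severe = sevs.count("severe_listed")
    candidates = [1]
    if m == 1:
        candidates.append(1)
    if m == 2:
        candidates.append(2)
    if mod >= 1:
        candidates.append(2)
    if m >= 1 and mod >= 1:
        candidates.append(3)
    if m >= 3 or mod >= 2 or severe >= 1:
        candidates.append(4)
    return max(candidates)


def classify_sga(weight_percentile: float) -> str:
    """SGA iff birth-weight percentile ≤ 10; AGA otherwise."""
    if not (0.0 <= weight_percentile <= 100.0):
        raise ValidationError("weight percentile must lie in [0, 100]")
    return "SGA" if weight_percentile <= 10.0 else "AGA"


def birth_weight_discordance(w_a: float, w_b: float) -> float:
    """|wA − wB| / max(wA, wB) — fraction of the larger twin's weight."""
    if w_a <= 0 or w_b <= 0:
        raise ValidationError("birth weights must be > 0")
    return abs(w_a - w_b) / max(w_a, w_b)
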