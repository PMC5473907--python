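"""The maternal oxygen schedule driving both simulation and model fitting.

The acquisition alternates the mother's inspired-oxygen fraction through
three consecutive epochs — room air (FiO2 0.21), 100% oxygen, room air —
each 10 minutes long by default.  All pipeline stages locate the
hemodynamic response relative to the start of the hyperoxia epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class OxygenParadigm:
    """FiO2 schedule: normoxia -> hyperoxia -> normoxia.

    Durations are in minutes; epoch boundaries are cumulative sums
    starting at the acquisition origin (t = 0 min).
    """

    baseline_dur: float = 10.0
    hyperoxia_dur: float = 10.0
    post_dur: float = 10.0
    fio2_baseline: float = 0.21
    fio2_hyperoxia: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_dur", "hyperoxia_dur", "post_dur"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 < self.fio2_baseline < self.fio2_hyperoxia <= 1.0):
            raise ValidationError("require 0 < fio2_baseline < fio2_hyperoxia <= 1")

    @property
    def hyperoxia_start(self) -> float:
        return self.baseline_dur

    @property
    def hyperoxia_end(self) -> float:
        return self.baseline_dur + self.hyperoxia_dur

    @property
    def total(self) -> float:
        return self.baseline_dur + self.hyperoxia_dur + self.post_dur

    @property
    def boundaries(self) -> tuple[float, float, float]:
        """Cumulative epoch end times (minutes)."""
        return (self.hyperoxia_start, self.hyperoxia_end, self.total)

    def fio2(self, t_min):
        """FiO2 at time(s) ``t_min`` (minutes from acquisition start)."""
        import numpy as np

        t = np.asarray(t_min, dtype=float)
        out = np.where(
            (t >= self.hyperoxia_start) & (t < self.hyperoxia_end),
            self.fio2_hyperoxia,
            self.fio2_baseline,
        )
        return out if out.ndim else float(out)
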