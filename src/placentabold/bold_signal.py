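"""ΔR2* computation and ROI time-activity curve summaries.

ΔR2*(t) = ln(S(t)/S_baseline)/TE, in s⁻¹, signed so that it increases with
oxygenation (dHb falls, S rises, R2* falls).  Curve slopes are derivatives
of the shared cubic B-spline representation (knots every 2 minutes), the
same basis the functional-data group comparison uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import splines
from .errors import RangeError, ValidationError
from .io import ROISet, VolumeSeries
from .paradigm import OxygenParadigm


@dataclass
class DeltaR2Series:
    """Voxel-wise ΔR2*(t) in s⁻¹ on the acquisition time grid (minutes)."""

    data: np.ndarray  # 4-D, NaN where invalid
    frame_times: np.ndarray
    te: float
    baseline: np.ndarray  # 3-D reference map
    valid: np.ndarray  # 3-D voxel validity
    paradigm: OxygenParadigm | None = None

    @property
    def spatial_shape(self):
        return self.data.shape[:3]


@dataclass
class TimeActivityCurve:
    """Mean ± sd ΔR2* over an ROI per frame."""

    roi_role: str
    t: np.ndarray  # minutes
    mean: np.ndarray  # s^-1
    sd: np.ndarray  # s^-1
    n_voxels: int

    def __post_init__(self):
        if not (len(self.t) == len(self.mean) == len(self.sd)):
            raise ValidationError("curve arrays must share one length")
        if self.n_voxels < 1:
            raise ValidationError("n_voxels must be >= 1")


def delta_r2star(
    series: VolumeSeries,
    baseline: np.ndarray,
    te: float | None = None,
    paradigm: OxygenParadigm | None = None,
) -> DeltaR2Series:
    """Compute ΔR2*(t) = ln(S(t)/S_baseline)/TE voxel-wise.

    Voxels with nonpositive baseline or any nonpositive intensity are
    flagged invalid (NaN) and excluded downstream rather than raising.
    """
    te = series.te if te is None else te
    if te <= 0:
        raise ValidationError("te must be > 0")
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != series.spatial_shape:
        raise ValidationError("baseline map shape must match the series grid")
    valid = (baseline > 0) & np.all(series.data > 0, axis=-1)
    data = np.full(series.data.shape, np.nan)
    data[valid] = np.log(series.data[valid] / baseline[valid, None]) / te
    return DeltaR2Series(
        data=data,
        frame_times=series.frame_times,
        te=te,
        baseline=baseline,
        valid=valid,
        paradigm=paradigm,
    )


def roi_curve(d: DeltaR2Series, rois: ROISet, role: str) -> TimeActivityCurve:
    """Per-frame mean and sd of ΔR2* over the valid voxels of one ROI."""
    mask = rois.mask_for_role(role) & d.valid
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(f"no valid voxels in ROI {role!r}")
    vox = d.data[mask]  # (n_voxels, n_t)
    return TimeActivityCurve(
        roi_role=role,
        t=d.frame_times,
        mean=vox.mean(axis=0),
        sd=vox.std(axis=0),
        n_voxels=n,
    )


def curve_spline(c: TimeActivityCurve, knot_spacing: float = splines.DEFAULT_KNOT_SPACING):
    """Shared cubic B-spline representation of a time-activity curve."""
    return splines.fit_curve_spline(c.t, c.mean, knot_spacing)


def curve_slope(
    c: TimeActivityCurve,
    at_time: float,
    knot_spacing: float = splines.DEFAULT_KNOT_SPACING,
) -> float:
    """d(ΔR2*)/dt at ``at_time`` (min) from the B-spline representation, s⁻¹/min."""
    if not (c.t[0] <= at_time <= c.t[-1]):
        raise RangeError(f"at_time {at_time} outside curve support [{c.t[0]}, {c.t[-1]}]")
    spl = curve_spline(c, knot_spacing)
    return float(spl.derivative()(at_time))


def curve_value(
    c: TimeActivityCurve,
    at_time: float,
    knot_spacing: float = splines.DEFAULT_KNOT_SPACING,
) -> float:
    """Spline-smoothed ΔR2* value at ``at_time`` minutes."""
    if not (c.t[0] <= at_time <= c.t[-1]):
        raise RangeError(f"at_time {at_time} outside curve support")
    return float(curve_spline(c, knot_spacing)(at_time))


def amplitude_summary(c: TimeActivityCurve, paradigm: OxygenParadigm) -> dict:
    """Amplitude features: peak |ΔR2*|, late-hyperoxia mean, end-of-post mean.

    ``last2min_mean`` averages the final 2 minutes of hyperoxia (the
    plateau estimate) and ``end_post_value`` the final minute of the
    post-hyperoxia epoch (undershoot indicator).
    """
    t = c.t
    if t[0] > paradigm.hyperoxia_start or t[-1] < paradigm.hyperoxia_end:
        raise RangeError("curve does not span the hyperoxia epoch")
    last2 = (t >= paradigm.hyperoxia_end - 2.0) & (t <= paradigm.hyperoxia_end)
    out = {
        "max_abs": float(np.max(np.abs(c.mean))),
        "last2min_mean": float(c.mean[last2].mean()),
        "end_post_value": float("nan"),
    }
    post = (t >= paradigm.total - 1.0) & (t <= paradigm.total)
    if post.any():
        out["end_post_value"] = float(c.mean[post].mean())
    return out
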