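"""Frame QC, spatial/temporal smoothing and baseline estimation.

The pipeline assumes motion-corrected input (registration and bias-field
correction are handled upstream by external tools); what remains before
ΔR2* computation is outlier-frame rejection, a 5-pixel/σ=1.5 Gaussian
spatial smooth, temporal interpolation with a ~1-minute moving-average
window, and the voxel-wise baseline over the first (normoxic) epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d
from scipy.interpolate import interp1d

from .errors import InsufficientBaselineError, ValidationError
from .io import VolumeSeries
from .paradigm import OxygenParadigm


@dataclass
class FrameQC:
    """Per-frame quality record for a masked series."""

    outlier_flags: np.ndarray  # bool per frame
    frame_mean: np.ndarray  # masked mean intensity per frame
    robust_z: np.ndarray  # |residual| / (1.4826 * MAD)
    threshold: float

    def __post_init__(self):
        n = len(self.frame_mean)
        if len(self.outlier_flags) != n or len(self.robust_z) != n:
            raise ValidationError("FrameQC arrays must share one length")

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.outlier_flags))


def detect_outlier_frames(
    series: VolumeSeries,
    mask: np.ndarray,
    threshold: float = 3.0,
    neighborhood: int = 2,
) -> FrameQC:
    """Flag frames whose masked mean jumps away from its temporal neighbors.

    Each frame's masked mean is compared against the median of the means of
    its ±``neighborhood`` neighboring frames (the frame itself excluded);
    the residuals are standardized by 1.4826·MAD and frames with robust
    z above ``threshold`` are flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    n = series.n_frames
    if n < 5:
        raise ValidationError("need at least 5 frames for outlier detection")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    fm = series.data[mask].mean(axis=0)
    resid = np.empty(n)
    for k in range(n):
        lo, hi = max(0, k - neighborhood), min(n, k + neighborhood + 1)
        nbr = np.concatenate([fm[lo:k], fm[k + 1 : hi]])
        resid[k] = fm[k] - np.median(nbr)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        z = np.where(resid == 0, 0.0, np.inf)
    else:
        z = np.abs(resid) / scale
    flags = z > threshold
    return FrameQC(outlier_flags=flags, frame_mean=fm, robust_z=z, threshold=threshold)


def gaussian_kernel_1d(width: int, sigma: float) -> np.ndarray:
    """Discrete Gaussian sampled on the integer offsets of an odd window."""
    if width % 2 == 0 or width < 1:
        raise ValidationError("kernel width must be odd and >= 1")
    r = width // 2
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def spatial_smooth(
    series: VolumeSeries,
    kernel_width: int = 5,
    sigma: float = 1.5,
    mask: np.ndarray | None = None,
) -> VolumeSeries:
    """Per-frame 3-D Gaussian smoothing, truncated at ``kernel_width`` pixels.

    The separable kernel is normalized to unit sum.  Near volume edges (and,
    when ``mask`` is given, near mask edges) the output is renormalized by
    the smoothed support indicator so constant signal stays constant.
    """
    k = gaussian_kernel_1d(kernel_width, sigma)
    support = np.ones(series.spatial_shape) if mask is None else np.asarray(mask, float)
    if mask is not None and not support.any():
        raise ValidationError("mask is empty")

    def smooth3(vol):
        out = vol
        for ax in range(3):
            out = correlate1d(out, k, axis=ax, mode="constant", cval=0.0)
        return out

    w = smooth3(support)
    out = np.empty_like(series.data)
    inside = support > 0
    for f in range(series.n_frames):
        num = smooth3(series.data[..., f] * support)
        frame = np.zeros(series.spatial_shape)
        frame[inside] = num[inside] / w[inside]
        if mask is not None:
            frame[~inside] = series.data[..., f][~inside]
        out[..., f] = frame
    return series.with_data(out)


def temporal_smooth(
    series: VolumeSeries,
    window: int = 10,
    resample_dt: float | None = None,
    exclude: np.ndarray | None = None,
) -> VolumeSeries:
    """Interpolate onto a uniform grid, then apply a moving-average window.

    Frames flagged in ``exclude`` are dropped before linear interpolation;
    edge frames are averaged over truncated windows.  ``resample_dt``
    defaults to the median inter-frame interval (minutes).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    t = series.frame_times
    keep = np.ones(series.n_frames, dtype=bool)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        if keep.sum() < 2:
            raise ValidationError("need at least 2 unflagged frames")
    t_keep = t[keep]
    if resample_dt is None:
        resample_dt = float(np.median(np.diff(t)))
    if resample_dt <= 0:
        raise ValidationError("resample_dt must be > 0")
    n_new = int(np.floor((t_keep[-1] - t_keep[0]) / resample_dt + 1e-9)) + 1
    t_new = np.minimum(t_keep[0] + resample_dt * np.arange(n_new), t_keep[-1])
    if window > n_new:
        raise ValidationError("smoothing window longer than resampled series")
    interp = interp1d(t_keep, series.data[..., keep], axis=-1, assume_sorted=True)
    data = interp(t_new)
    ones = np.ones(n_new)
    kern = np.ones(window)
    counts = correlate1d(ones, kern, mode="constant", cval=0.0)
    num = correlate1d(data, kern, axis=-1, mode="constant", cval=0.0)
    return series.with_data(num / counts, frame_times=t_new)


def compute_baseline(
    series: VolumeSeries,
    paradigm: OxygenParadigm,
    qc: FrameQC | None = None,
) -> np.ndarray:
    """Voxel-wise mean over unflagged frames of the first (normoxic) epoch."""
    in_baseline = series.frame_times < series.t0 + paradigm.baseline_dur
    usable = in_baseline.copy()
    if qc is not None:
        usable &= ~qc.outlier_flags
    if usable.sum() < 3:
        raise InsufficientBaselineError(
            f"only {int(usable.sum())} usable baseline frames (need >= 3)"
        )
    return series.data[..., usable].mean(axis=-1)
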