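"""Least-squares cubic B-spline representation of time-activity curves.

One basis definition is shared by the per-curve slope estimator and the
functional-data group comparison: cubic splines with interior knots every
``knot_spacing`` minutes (default 2 min).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .errors import ValidationError

DEFAULT_KNOT_SPACING = 2.0
_K = 3  # cubic


def knot_vector(t_start: float, t_end: float, knot_spacing: float = DEFAULT_KNOT_SPACING) -> np.ndarray:
    """Full clamped knot vector with interior knots every ``knot_spacing`` min."""
    if knot_spacing <= 0:
        raise ValidationError("knot_spacing must be > 0")
    if t_end - t_start < knot_spacing:
        raise ValidationError("time grid shorter than one knot interval")
    # interior knots strictly inside (t_start, t_end)
    n_int = int(np.floor((t_end - t_start) / knot_spacing + 1e-9)) - 1
    interior = t_start + knot_spacing * np.arange(1, n_int + 1)
    interior = interior[interior < t_end - 1e-9]
    return np.concatenate(
        [np.full(_K + 1, t_start), interior, np.full(_K + 1, t_end)]
    )


def fit_curve_spline(t: np.ndarray, y: np.ndarray, knot_spacing: float = DEFAULT_KNOT_SPACING) -> BSpline:
    """Least-squares projection of samples (t, y) onto the shared cubic basis."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValidationError("t and y must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("t must be strictly increasing")
    kv = knot_vector(t[0], t[-1], knot_spacing)
    return make_lsq_spline(t, y, kv, k=_K)


def design_matrix(t: np.ndarray, knot_spacing: float, t_start: float, t_end: float) -> np.ndarray:
    """Dense basis-evaluation matrix (n_samples x n_basis) on the shared knots."""
    kv = knot_vector(t_start, t_end, knot_spacing)
    return BSpline.design_matrix(np.asarray(t, float), kv, _K).toarray()
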