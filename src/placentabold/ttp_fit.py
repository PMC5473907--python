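"""Gamma-convolution oxygenation model and time-to-plateau (TTP) fitting.

The regional oxygenation response is modeled as a unit step in inspired
oxygen (starting Δ minutes after hyperoxia onset) convolved with a gamma
kernel with shape α and scale β (minutes).  With the kernel normalized to
unit area the convolution has the closed form

    ΔR2*(s) = C1 + C2 · P(α, (s − Δ)/β)    for s ≥ Δ,   C1 otherwise,

where s is time since hyperoxia onset and P the regularized lower
incomplete gamma function, so C2 is exactly the plateau amplitude (s⁻¹).
TTP = Δ + τ with τ = α·(β−1) under the ``as_printed`` convention, or
τ = (α−1)·β (the standard gamma-density mode) under ``standard_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc

from .errors import ValidationError
from .io import ROISet
from .paradigm import OxygenParadigm

TTP_CONVENTIONS = ("as_printed", "standard_mode")


def gamma_step_response(s, alpha: float, beta: float):
    """Unit-step ⊗ unit-normalized gamma kernel: P(α, s/β), 0 for s ≤ 0."""
    if alpha < 1 or beta < 1:
        raise ValidationError("alpha and beta must each be >= 1")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.zeros_like(s_arr)
    pos = s_arr > 0
    out[pos] = gammainc(alpha, s_arr[pos] / beta)
    return out if np.ndim(s) else float(out[0])


def ttp_from_params(alpha: float, beta: float, delta: float, convention: str = "as_printed") -> float:
    """Time-to-plateau (minutes since hyperoxia onset) from gamma parameters."""
    if alpha < 1 or beta < 1 or delta < 0:
        raise ValidationError("require alpha >= 1, beta >= 1, delta >= 0")
    if convention == "as_printed":
        tau = alpha * (beta - 1.0)
    elif convention == "standard_mode":
        tau = (alpha - 1.0) * beta
    else:
        raise ValidationError(f"unknown TTP convention {convention!r}")
    return float(delta + tau)


@dataclass
class GammaFitParams:
    """Fitted parameter vector of the gamma-convolution model plus QC."""

    alpha: float
    beta: float
    delta: float  # minutes after hyperoxia onset
    c1: float  # baseline offset, s^-1
    c2: float  # plateau amplitude, s^-1
    rss: float = np.nan
    converged: bool = False
    n_points: int = 0
    convention: str = "as_printed"

    @property
    def tau(self) -> float:
        if self.convention == "as_printed":
            return self.alpha * (self.beta - 1.0)
        return (self.alpha - 1.0) * self.beta

    @property
    def ttp(self) -> float:
        """Minutes since hyperoxia onset; NaN when the fit is degenerate
        (vanishing amplitude) or failed outright."""
        if not np.isfinite(self.c2) or self.c2 <= 0:
            return float("nan")
        return ttp_from_params(self.alpha, self.beta, self.delta, self.convention)

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.ttp))


def model_eval(params, t, paradigm: OxygenParadigm | None = None):
    """Predicted ΔR2* curve of the gamma-convolution model.

    ``t`` is in minutes; when a paradigm is given, time is measured from
    acquisition start and the response is anchored at hyperoxia onset,
    otherwise ``t`` is taken as time since hyperoxia onset already.
    """
    if isinstance(params, GammaFitParams):
        alpha, beta, delta, c1, c2 = params.alpha, params.beta, params.delta, params.c1, params.c2
    else:
        alpha, beta, delta, c1, c2 = params
    t = np.asarray(t, dtype=float)
    if t.ndim and np.any(np.diff(t) < 0):
        raise ValidationError("t must be nondecreasing")
    onset = paradigm.hyperoxia_start if paradigm is not None else 0.0
    s = np.atleast_1d(t) - onset - delta
    out = c1 + c2 * gamma_step_response(s, alpha, beta)
    return out if t.ndim else float(out[0])


def _default_grid(delta_max: float, alpha_max: float, beta_max: float):
    alphas = np.geomspace(1.0, alpha_max, 8)
    betas = np.concatenate([[1.0], np.geomspace(1.15, beta_max, 8)])
    deltas = np.arange(0.0, delta_max + 1e-9, 0.5)
    return alphas, betas, deltas


class _GridBasis:
    """Precomputed step-response curves over a coarse (α, β, Δ) grid.

    Shared across all voxels of a map so the per-voxel initialization is a
    vectorized closed-form (c1, c2) linear solve per grid point.
    """

    def __init__(self, s: np.ndarray, alphas, betas, deltas):
        self.s = s
        combos = []
        rows = []
        for a in alphas:
            for b in betas:
                for d in deltas:
                    combos.append((a, b, d))
                    rows.append(gamma_step_response(s - d, a, b))
        self.combos = np.array(combos)
        self.G = np.array(rows)  # (n_grid, n_t)
        n = len(s)
        self.Sg = self.G.sum(axis=1)
        self.Sgg = (self.G**2).sum(axis=1)
        self.n = n

    def init_candidates(self, y: np.ndarray, k: int):
        """Best-k grid points by RSS after closed-form (c1, c2 >= 0) solve."""
        Sy = y.sum()
        Sgy = self.G @ y
        denom = self.n * self.Sgg - self.Sg**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2 = (self.n * Sgy - self.Sg * Sy) / denom
        c2 = np.where(np.isfinite(c2), c2, 0.0)
        c2 = np.maximum(c2, 0.0)
        c1 = (Sy - c2 * self.Sg) / self.n
        rss = ((y[None, :] - c1[:, None] - c2[:, None] * self.G) ** 2).sum(axis=1)
        order = np.argsort(rss)[:k]
        return [
            (self.combos[i], float(c1[i]), float(c2[i]), float(rss[i])) for i in order
        ]


def fit_voxel(
    curve: np.ndarray,
    t: np.ndarray,
    paradigm: OxygenParadigm,
    bounds: dict | None = None,
    n_starts: int = 6,
    fit_window: tuple | None = None,
    convention: str = "as_printed",
    _basis: _GridBasis | None = None,
) -> GammaFitParams:
    """Bounded least-squares fit of the gamma-convolution model to one curve.

    The fit window defaults to the baseline + hyperoxia epochs (the step
    input never turns off within the fitted interval).  Initialization is a
    multi-start from a coarse (α, β, Δ) grid with closed-form (c1, c2); the
    best starts are polished with a trust-region reflective solver.  A
    vanishing amplitude (c2 → 0) marks the fit degenerate: converged but
    with no defined TTP.
    """
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(t, dtype=float)
    if curve.shape != t.shape:
        raise ValidationError("curve and t must have equal length")
    if fit_window is None:
        fit_window = (t[0], paradigm.hyperoxia_end)
    sel = (t >= fit_window[0]) & (t <= fit_window[1]) & np.isfinite(curve)
    n_pts = int(sel.sum())
    if n_pts < 10:
        return GammaFitParams(1.0, 1.0, 0.0, np.nan, np.nan, n_points=n_pts, convention=convention)
    s = t[sel] - paradigm.hyperoxia_start
    y = curve[sel]

    b = {
        "alpha": (1.0, 20.0),
        "beta": (1.0, 10.0),
        "delta": (0.0, max(paradigm.hyperoxia_dur - 1.0, 0.5)),
        "c1": (-np.inf, np.inf),
        "c2": (0.0, np.inf),
    }
    if bounds:
        b.update(bounds)

    if _basis is None:
        alphas, betas, deltas = _default_grid(b["delta"][1], b["alpha"][1], b["beta"][1])
        _basis = _GridBasis(s, alphas, betas, deltas)
    starts = _basis.init_candidates(y, n_starts)

    lo = np.array([b["alpha"][0], b["beta"][0], b["delta"][0], b["c1"][0], b["c2"][0]])
    hi = np.array([b["alpha"][1], b["beta"][1], b["delta"][1], b["c1"][1], b["c2"][1]])

    def resid(x):
        a, bb, d, c1, c2 = x
        return c1 + c2 * gamma_step_response(s - d, a, bb) - y

    best = None
    for (a0, b0, d0), c1_0, c2_0, grid_rss in starts:
        x0 = np.clip(np.array([a0, b0, d0, c1_0, max(c2_0, 1e-8)]), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
        if rss < 1e-22:
            break
    if best is None:
        return GammaFitParams(1.0, 1.0, 0.0, np.nan, np.nan, n_points=n_pts, convention=convention)
    rss, sol = best
    a, bb, d, c1, c2 = sol.x
    # amplitude indistinguishable from the noise floor -> degenerate timing
    c2_eff = c2 if c2 > max(1e-6, 1e-3 * np.std(y)) else 0.0
    return GammaFitParams(
        alpha=float(a), beta=float(bb), delta=float(d), c1=float(c1), c2=float(c2_eff),
        rss=rss, converged=bool(sol.status > 0), n_points=n_pts, convention=convention,
    )


@dataclass
class TTPMap:
    """Voxel-wise TTP (minutes) with validity flags and per-voxel fit QC."""

    ttp: np.ndarray
    valid: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    convention: str = "as_printed"

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    @property
    def convergence_rate(self) -> float:
        fitted = np.isfinite(self.rss)
        if not fitted.any():
            return 0.0
        return float(self.converged[fitted].mean())


def fit_map(
    d,
    rois: ROISet,
    role: str,
    n_starts: int = 4,
    fit_window: tuple | None = None,
    convention: str = "as_printed",
    bounds: dict | None = None,
) -> TTPMap:
    """Voxel-wise gamma-model fit over one ROI of a ΔR2* series.

    ``d`` is a DeltaR2Series (see :mod:`placentabold.bold_signal`).
    Failed or degenerate voxels are flagged invalid, never raised.
    """
    mask = rois.mask_for_role(role)
    shape = mask.shape
    paradigm = d.paradigm
    t = d.frame_times
    if fit_window is None:
        fit_window = (t[0], paradigm.hyperoxia_end)
    sel = (t >= fit_window[0]) & (t <= fit_window[1])
    s = t[sel] - paradigm.hyperoxia_start

    b = bounds or {}
    delta_hi = b.get("delta", (0.0, max(paradigm.hyperoxia_dur - 1.0, 0.5)))[1]
    alpha_hi = b.get("alpha", (1.0, 20.0))[1]
    beta_hi = b.get("beta", (1.0, 10.0))[1]
    basis = _GridBasis(s, *_default_grid(delta_hi, alpha_hi, beta_hi))

    ttp = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    converged = np.zeros(shape, dtype=bool)
    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        curve = d.data[i, j, k, :]
        if not np.all(np.isfinite(curve)):
            continue
        p = fit_voxel(
            curve, t, paradigm, bounds=bounds, n_starts=n_starts,
            fit_window=fit_window, convention=convention, _basis=basis,
        )
        rss[i, j, k] = p.rss
        converged[i, j, k] = p.converged
        if p.valid:
            ttp[i, j, k] = p.ttp
            valid[i, j, k] = True
    return TTPMap(ttp=ttp, valid=valid, rss=rss, converged=converged, convention=convention)


def ttp_summary(
    m: TTPMap,
    rois: ROISet | None = None,
    role: str | None = None,
    bin_width: float = 0.5,
) -> dict:
    """Moments and histogram of valid TTP values, optionally within one ROI."""
    sel = m.valid.copy()
    if rois is not None and role is not None:
        sel &= rois.mask_for_role(role)
    vals = m.ttp[sel]
    if vals.size == 0:
        raise ValidationError("no valid TTP voxels in selection")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width * 1.5, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return {
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "sd": float(vals.std()),
        "n_valid": int(vals.size),
        "hist_counts": counts,
        "hist_edges": edges,
    }
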