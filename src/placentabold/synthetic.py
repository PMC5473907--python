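"""Synthetic phantoms and twin cohorts with known ground truth.

The generator emulates the study conditions the analysis assumes: a
10/10/10-minute normoxia–hyperoxia–normoxia paradigm, BOLD signal from a
two-compartment placental blood model (maternal intervillous space, volume
fraction 0.40, baseline saturation 0.80; fetal capillaries, fraction 0.10,
saturation 0.60), voxel-wise gamma-convolution response truth, and
AGA/SGA group differences in plateau amplitude and rise slope.

The oxygenation response rises as the step-convolved gamma kernel of
:mod:`placentabold.ttp_fit`; after hyperoxia ends it returns to baseline by
a mirrored gamma decay (its own shape/scale), optionally undershooting to a
negative asymptote — the behavior reported for organs of growth-restricted
fetuses.  The two-compartment model is used for generation realism only;
the fit never sees compartment parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammainc

from . import bold_signal
from .errors import GeometryError, ValidationError
from .io import ROISet, VolumeSeries
from .paradigm import OxygenParadigm
from .ttp_fit import gamma_step_response, ttp_from_params


@dataclass(frozen=True)
class CompartmentParams:
    """Two-compartment placental blood model (volume fractions, saturations)."""

    v_m: float = 0.40  # maternal (intervillous) blood volume fraction
    v_f: float = 0.10  # fetal capillary blood volume fraction
    r2star_relaxivity: float = 25.0  # s^-1 per unit [dHb] (calibrated unit)
    sat_m_baseline: float = 0.80
    sat_f_baseline: float = 0.60
    sat_m_plateau: float = 0.98
    sat_f_plateau: float = 0.85

    def __post_init__(self):
        if not (0 <= self.v_f < self.v_m < 1):
            raise ValidationError("require 0 <= v_f < v_m < 1")
        for b, p in ((self.sat_m_baseline, self.sat_m_plateau), (self.sat_f_baseline, self.sat_f_plateau)):
            if not (0 < b <= 1 and 0 < p <= 1):
                raise ValidationError("saturations must lie in (0, 1]")
            if p < b:
                raise ValidationError("plateau saturation below baseline")


@dataclass(frozen=True)
class VoxelTruth:
    """Ground-truth response parameters of one voxel (or one ROI curve)."""

    alpha: float = 2.0
    beta: float = 2.0  # minutes-scale
    delta: float = 0.0  # oxygen arrival delay, minutes after hyperoxia onset
    c1: float = 0.0  # baseline ΔR2* offset, s^-1
    c2: float = 9.83  # plateau amplitude, s^-1
    decay_alpha: float | None = None  # post-phase kinetics; defaults mirror rise
    decay_beta: float | None = None
    undershoot: float = 0.0  # post-phase asymptote as a (signed) fraction of c2

    def __post_init__(self):
        if self.alpha < 1 or self.beta < 1 or self.delta < 0:
            raise ValidationError("require alpha >= 1, beta >= 1, delta >= 0")

    @property
    def ttp_true(self) -> float:
        """TTP (minutes after hyperoxia onset) under the as-printed convention."""
        return ttp_from_params(self.alpha, self.beta, self.delta, "as_printed")


def response_fraction(truth: VoxelTruth, t: np.ndarray, paradigm: OxygenParadigm) -> np.ndarray:
    """Normalized oxygenation response g(t): 0 at baseline, 1 at plateau.

    Rise: step ⊗ gamma kernel, anchored ``delta`` minutes after hyperoxia
    onset.  Post phase: mirrored gamma decay toward the ``undershoot``
    asymptote, anchored the same delay after hyperoxia offset.
    """
    t = np.asarray(t, dtype=float)
    s = t - paradigm.hyperoxia_start
    rise = gamma_step_response(s - truth.delta, truth.alpha, truth.beta)
    da = truth.decay_alpha if truth.decay_alpha is not None else truth.alpha
    db = truth.decay_beta if truth.decay_beta is not None else truth.beta
    fall = gamma_step_response(s - paradigm.hyperoxia_dur - truth.delta, da, db)
    return rise - (1.0 - truth.undershoot) * fall


def delta_r2star_model(truth: VoxelTruth, t: np.ndarray, paradigm: OxygenParadigm) -> np.ndarray:
    """Noiseless ΔR2*(t) = c1 + c2·g(t) of the generating model, s⁻¹."""
    return truth.c1 + truth.c2 * response_fraction(truth, t, paradigm)


def simulate_dhb(
    paradigm: OxygenParadigm,
    comp: CompartmentParams,
    response: VoxelTruth,
    dt: float = 0.1,
) -> dict:
    """Per-compartment Δ[dHb](t) curves consistent with the voxel's response.

    Both compartments follow the voxel's gamma-convolution kinetics, scaled
    in proportion to their saturation excursions so that the relaxivity-
    weighted sum −r2*·(V_F·Δ[dHb_F] + V_M·Δ[dHb_M]) equals c2·g(t) (and
    hence c2 at plateau).  Δ[dHb] ≤ 0 during hyperoxia: dHb falls.
    """
    t = np.arange(0.0, paradigm.total + dt / 2, dt)
    g = response_fraction(response, t, paradigm)
    w_m = comp.sat_m_plateau - comp.sat_m_baseline
    w_f = comp.sat_f_plateau - comp.sat_f_baseline
    denom = comp.r2star_relaxivity * (comp.v_f * w_f + comp.v_m * w_m)
    if denom <= 0:
        raise ValidationError("compartment excursions yield a nonpositive response scale")
    lam = response.c2 / denom
    return {
        "t": t,
        "dhb_m": -lam * w_m * g,
        "dhb_f": -lam * w_f * g,
        "delta_r2star": comp.r2star_relaxivity
        * -(comp.v_f * (-lam * w_f * g) + comp.v_m * (-lam * w_m * g)),
    }


def simulate_voxel_series(
    truth: VoxelTruth,
    paradigm: OxygenParadigm,
    te: float = 0.035,
    s_baseline: float = 100.0,
    noise_sd: float = 0.0,
    tr: float = 6.0,
    seed: int | np.random.Generator = 0,
    rician: bool = False,
) -> dict:
    """Intensity time series S(t) = S0·exp(TE·ΔR2*_model(t)) + noise.

    Returns the series, its time grid (minutes), the noiseless model and a
    flag for samples clipped at the positive intensity floor.
    """
    if s_baseline <= 0:
        raise ValidationError("s_baseline must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, paradigm.total + 1e-9, tr / 60.0)
    dr2 = delta_r2star_model(truth, t, paradigm)
    clean = s_baseline * np.exp(te * dr2)
    if noise_sd > 0:
        if rician:
            re = clean + rng.normal(0.0, noise_sd, clean.shape)
            im = rng.normal(0.0, noise_sd, clean.shape)
            s = np.hypot(re, im)
        else:
            s = clean + rng.normal(0.0, noise_sd, clean.shape)
    else:
        s = clean.copy()
    floor = 1e-6 * s_baseline
    clipped = s < floor
    s = np.maximum(s, floor)
    return {"t": t, "signal": s, "model_delta_r2star": dr2, "clean": clean, "clipped": clipped}


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    q = sum(((grids[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def generate_phantom(
    shape: tuple = (32, 32, 8),
    paradigm: OxygenParadigm | None = None,
    spatial_ttp_field: str = "cotyledon",
    seed: int = 0,
    tr: float = 6.0,
    te: float = 0.035,
    s_baseline: float = 100.0,
    noise_sd: float = 0.0,
    base_ttp: float = 1.5,
    patch_offset: float = 3.0,
    amplitude: float = 9.83,
    n_lobules: int = 5,
) -> tuple[VolumeSeries, ROISet, dict]:
    """Build a 4-D phantom: ellipsoidal placenta plus two fetal-organ blobs.

    ``spatial_ttp_field`` selects the truth TTP structure over the placenta:
    ``uniform`` (constant), ``cotyledon`` (smooth lobular variation, short
    TTP at lobule centers), or ``pathological_patch`` (a contiguous region
    delayed by ``patch_offset`` minutes).  Truth parameter maps are
    returned alongside the series and masks.
    """
    paradigm = paradigm or OxygenParadigm()
    shape = tuple(int(n) for n in shape)
    if min(shape) < 8:
        raise GeometryError("phantom needs at least 8 voxels per axis")
    if spatial_ttp_field not in ("uniform", "cotyledon", "pathological_patch"):
        raise ValidationError(f"unknown spatial_ttp_field {spatial_ttp_field!r}")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    center = (nx * 0.5, ny * 0.38, nz * 0.5)
    semi = (nx * 0.36, ny * 0.24, max(nz * 0.32, 1.5))
    placenta = _ellipsoid_mask(shape, center, semi)
    if not placenta.any():
        raise GeometryError("placental ellipsoid does not fit the grid")
    # split the shared placenta into twin territories along x
    twin_a = placenta & (np.arange(nx)[:, None, None] < center[0])
    twin_b = placenta & ~twin_a
    r_org = max(min(nx, ny, nz) * 0.14, 1.2)
    brain = _ellipsoid_mask(shape, (nx * 0.22, ny * 0.8, nz * 0.5), (r_org,) * 3) & ~placenta
    liver = _ellipsoid_mask(shape, (nx * 0.78, ny * 0.8, nz * 0.5), (r_org,) * 3) & ~placenta & ~brain

    labels = np.zeros(shape, dtype=np.int32)
    labels[twin_a] = 1
    labels[twin_b] = 2
    labels[brain] = 3
    labels[liver] = 4
    rois = ROISet(
        labels=labels,
        dictionary={1: "placenta_twinA", 2: "placenta_twinB", 3: "brain_twinA", 4: "liver_twinA"},
    )

    ttp = np.full(shape, np.nan)
    ttp[placenta] = base_ttp
    patch = np.zeros(shape, dtype=bool)
    if spatial_ttp_field == "cotyledon":
        centers = np.column_stack(
            [rng.uniform(c - a * 0.8, c + a * 0.8, n_lobules) for c, a in zip(center, semi)]
        )
        grids = np.indices(shape, dtype=float)
        pts = grids.reshape(3, -1).T
        d = np.min(
            np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2), axis=1
        ).reshape(shape)
        dmax = d[placenta].max()
        ttp[placenta] = base_ttp * (0.3 + 1.4 * d[placenta] / max(dmax, 1e-9))
    elif spatial_ttp_field == "pathological_patch":
        pc = (center[0] + semi[0] * 0.45, center[1], center[2])
        patch = _ellipsoid_mask(shape, pc, tuple(a * 0.45 for a in semi)) & placenta
        if not patch.any():
            raise GeometryError("pathological patch does not fit inside the placenta")
        ttp[patch] = base_ttp + patch_offset

    ttp[brain] = base_ttp
    ttp[liver] = base_ttp
    tissue = placenta | brain | liver

    # parameterize alpha fixed, split TTP evenly between arrival delay and
    # kernel mode: delta = ttp/2, alpha*(beta-1) = ttp/2
    alpha = np.full(shape, np.nan)
    beta = np.full(shape, np.nan)
    delta = np.full(shape, np.nan)
    c2 = np.full(shape, np.nan)
    alpha[tissue] = 2.0
    delta[tissue] = ttp[tissue] / 2.0
    beta[tissue] = 1.0 + ttp[tissue] / 4.0
    c2[placenta] = amplitude
    c2[brain] = amplitude / 6.0
    c2[liver] = amplitude / 2.0

    t = np.arange(0.0, paradigm.total + 1e-9, tr / 60.0)
    s = t - paradigm.hyperoxia_start
    data = np.full(shape + (len(t),), s_baseline * 0.6)
    vox = np.argwhere(tissue)
    dv = delta[tissue]
    bv = beta[tissue]
    c2v = c2[tissue]
    rise = gammainc(2.0, np.maximum(s[None, :] - dv[:, None], 0.0) / bv[:, None])
    fall = gammainc(
        2.0, np.maximum(s[None, :] - paradigm.hyperoxia_dur - dv[:, None], 0.0) / bv[:, None]
    )
    dr2 = c2v[:, None] * (rise - fall)
    data[tissue] = s_baseline * np.exp(te * dr2)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)
        data = np.maximum(data, 1e-6 * s_baseline)

    series = VolumeSeries(data=data, tr=tr, te=te)
    truth = {
        "ttp": ttp, "alpha": alpha, "beta": beta, "delta": delta, "c2": c2,
        "tissue": tissue, "patch": patch,
    }
    return series, rois, truth


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions for a monochorionic-twin cohort.

    Group plateau amplitudes default to the study's healthy/pathological
    placental ΔR2* over the last 2 min of hyperoxia (9.83 ± 4.49 vs
    6.55 ± 3.30 s⁻¹); group rise slopes default to the AGA/SGA values
    1.89 vs 0.88 s⁻¹/min measured at hyperoxia onset.  A subject's slope
    is defined operationally as the shared B-spline derivative of its
    noiseless curve at onset; see the methods note.
    """

    n_pairs: int = 7
    assignment: str = "discordant"  # twin A AGA, twin B SGA; or "all_aga"
    amp_mean_aga: float = 9.83
    amp_sd_aga: float = 4.49
    amp_mean_sga: float = 6.55
    amp_sd_sga: float = 3.30
    slope_aga: float = 1.89  # s^-1 per minute at hyperoxia onset
    slope_sga: float = 0.88
    slope_sd: float = 0.4
    organ_ratio: tuple = (6.0, 3.0, 1.0)  # placenta : liver : brain
    sga_organ_undershoot: float = -0.15  # post-phase asymptote fraction for SGA organs
    noise_sd: float = 0.5  # s^-1 on each curve sample
    dt: float = 0.1  # minutes between curve samples
    bw_intercept: float = 2600.0  # grams at TTP 0
    bw_ttp_slope: float = 250.0  # grams lost per minute of TTP
    bw_pair_sd: float = 150.0  # pair-shared random intercept sd
    bw_noise_sd: float = 100.0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        for name in ("amp_sd_aga", "amp_sd_sga", "slope_sd", "noise_sd", "bw_pair_sd", "bw_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if min(self.amp_mean_aga, self.amp_mean_sga, self.slope_aga, self.slope_sga) <= 0:
            raise ValidationError("amplitudes and slopes must be > 0")
        if self.assignment not in ("discordant", "all_aga"):
            raise ValidationError("assignment must be 'discordant' or 'all_aga'")


@dataclass
class Cohort:
    """Generated cohort: common time grid, per-subject organ curves, tables."""

    t: np.ndarray
    curves: dict  # (subject_id, organ) -> ΔR2* ndarray
    records: pd.DataFrame  # one row per fetus
    truth: pd.DataFrame  # generating parameters per subject/organ

    def curve_set(self, organ: str = "placenta"):
        """Curves of one organ as a twin_stats CurveSet (AGA/SGA labels)."""
        from .twin_stats import CurveSet

        subjects = self.records["subject_id"].tolist()
        rows = np.array([self.curves[(s, organ)] for s in subjects])
        groups = self.records["group"].to_numpy()
        return CurveSet(t=self.t, curves=rows, groups=groups)


def _solve_subject_beta(
    amplitude: float,
    slope: float,
    paradigm: OxygenParadigm,
    t: np.ndarray,
    decay_beta: float,
    undershoot: float,
) -> tuple[float, float]:
    """Find (β, c2) so the noiseless curve has the target plateau amplitude
    (last-2-min-of-hyperoxia mean) and onset slope (B-spline derivative)."""

    def features(b):
        truth = VoxelTruth(alpha=1.0, beta=b, delta=0.0, c2=1.0,
                           decay_beta=decay_beta, undershoot=undershoot)
        g = delta_r2star_model(truth, t, paradigm)
        curve = bold_signal.TimeActivityCurve("placenta_twinA", t, g, np.zeros_like(g), 1)
        h = bold_signal.amplitude_summary(curve, paradigm)["last2min_mean"]
        f = bold_signal.curve_slope(curve, paradigm.hyperoxia_start)
        return h, f

    def q(b):
        h, f = features(b)
        return amplitude * f / h - slope

    lo, hi = 1.0, 25.0
    if q(lo) <= 0 or q(hi) >= 0:
        # target slope unreachable for this amplitude within beta in [1, 25]
        return None
    b = brentq(q, lo, hi, xtol=1e-6)
    h, _ = features(b)
    return float(b), float(amplitude / h)


def _truncated_normal(rng, mean, sd, low, size=None):
    """Rejection-sample a normal truncated below at ``low``."""
    if sd == 0:
        return np.full(size or 1, float(mean)) if size else float(mean)
    draw = rng.normal(mean, sd, size=size)
    for _ in range(200):
        bad = draw <= low
        if not np.any(bad):
            break
        draw = np.where(bad, rng.normal(mean, sd, size=np.shape(draw)), draw)
    return np.maximum(draw, low)


def generate_cohort(
    spec: CohortSpec | None = None,
    paradigm: OxygenParadigm | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate twin pairs with placenta/liver/brain ΔR2* curves and outcomes.

    Each pair shares one mother identifier.  Placental kinetics per subject
    are solved so the noiseless curve hits the drawn plateau amplitude and
    onset slope; organ curves scale the placental curve by the 6:3:1
    amplitude ratio, with SGA organs decaying fast and undershooting below
    baseline after hyperoxia.  Birth weight decreases in true TTP with a
    pair-shared random intercept; longer-TTP placentas tend to carry
    moderate pathology findings.
    """
    spec = spec or CohortSpec()
    paradigm = paradigm or OxygenParadigm()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, paradigm.total + spec.dt / 2, spec.dt)
    ratio = np.asarray(spec.organ_ratio, dtype=float)

    curves: dict = {}
    records = []
    truth_rows = []
    for pair in range(1, spec.n_pairs + 1):
        ga = rng.uniform(29.0, 34.0)
        stb = rng.uniform(0.2, 5.5)
        pair_re = rng.normal(0.0, spec.bw_pair_sd)
        for twin in ("A", "B"):
            group = "SGA" if (spec.assignment == "discordant" and twin == "B") else "AGA"
            sid = f"P{pair:02d}{twin}"
            if group == "AGA":
                amp_mean, amp_sd = spec.amp_mean_aga, spec.amp_sd_aga
                slope_mean = spec.slope_aga
                organ_decay_beta, organ_under = 8.0, 0.0
            else:
                amp_mean, amp_sd = spec.amp_mean_sga, spec.amp_sd_sga
                slope_mean = spec.slope_sga
                organ_decay_beta, organ_under = 2.0, spec.sga_organ_undershoot
            # rejection-sample (amplitude, slope) jointly until the pair is
            # kinetically feasible with beta >= 1
            solved = None
            for _ in range(100):
                amp = float(_truncated_normal(rng, amp_mean, amp_sd, 1.0))
                slope = float(_truncated_normal(rng, slope_mean, spec.slope_sd, 0.1))
                solved = _solve_subject_beta(amp, slope, paradigm, t, decay_beta=4.0, undershoot=0.0)
                if solved is not None:
                    break
            if solved is None:  # pathological spec; fall back to fastest kinetics
                solved = (1.0, amp)
            beta, c2 = solved
            pl_truth = VoxelTruth(alpha=1.0, beta=beta, delta=0.0, c2=c2, decay_beta=4.0)
            ttp = pl_truth.ttp_true
            organ_truths = {
                "placenta": pl_truth,
                "liver": replace(pl_truth, c2=c2 * ratio[1] / ratio[0],
                                 decay_beta=organ_decay_beta, undershoot=organ_under),
                "brain": replace(pl_truth, c2=c2 * ratio[2] / ratio[0],
                                 decay_beta=organ_decay_beta, undershoot=organ_under),
            }
            for organ, tr_ in organ_truths.items():
                clean = delta_r2star_model(tr_, t, paradigm)
                noisy = clean + (rng.normal(0.0, spec.noise_sd, clean.shape) if spec.noise_sd > 0 else 0.0)
                curves[(sid, organ)] = noisy
                truth_rows.append({
                    "subject_id": sid, "pair_id": pair, "organ": organ, "group": group,
                    "alpha": tr_.alpha, "beta": tr_.beta, "delta": tr_.delta,
                    "c2": tr_.c2, "slope_true": slope * tr_.c2 / c2, "ttp_true": tr_.ttp_true,
                    "undershoot": tr_.undershoot,
                })

            bw = spec.bw_intercept - spec.bw_ttp_slope * ttp + pair_re + rng.normal(0.0, spec.bw_noise_sd)
            bw = max(bw, 500.0)
            percentile = rng.uniform(1.0, 10.0) if group == "SGA" else rng.uniform(15.0, 90.0)
            n_mod = rng.binomial(2, float(np.clip((ttp - 1.5) / 3.0, 0.0, 0.9)))
            n_min = rng.binomial(2, 0.3)
            findings = ";".join(["moderate"] * n_mod + ["minor"] * n_min)
            records.append({
                "subject_id": sid, "pair_id": pair, "mother_id": f"M{pair:02d}",
                "twin_label": twin, "group": group, "ga_at_mri": ga, "scan_to_birth": stb,
                "birth_weight": bw, "weight_percentile": percentile,
                "efw": bw * (1.0 + rng.normal(0.0, 0.08)),
                "doppler_grade": int(np.clip(round((ttp - 1.0) / 1.2 + rng.normal(0.0, 0.5)), 0, 3)),
                "brain_volume": max(bw * 0.060 + rng.normal(0.0, 8.0), 20.0),
                "liver_volume": max(bw * 0.025 + rng.normal(0.0, 5.0), 10.0),
                "findings": findings, "ttp_true": ttp,
            })
    return Cohort(
        t=t,
        curves=curves,
        records=pd.DataFrame.from_records(records),
        truth=pd.DataFrame.from_records(truth_rows),
    )
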