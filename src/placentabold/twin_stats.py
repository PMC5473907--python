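"""The study's statistical layer for twin-pair cohorts.

Four families of tests: the Friedman rank-sum over twin-pair blocks, a
pair-resampled Spearman correlation (one twin per pair drawn at random,
repeated; median correlation reported), linear mixed models with the
mother as a random intercept, and a functional-data comparison of group
mean curves on a shared cubic B-spline basis (knots every 2 minutes) with
pointwise Welch t and p functions.  All p-values are reported raw; no
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bold_signal, splines
from .errors import CollinearityError, ValidationError
from .paradigm import OxygenParadigm


@dataclass
class CurveSet:
    """Per-subject ΔR2* curves on a common time grid with group labels."""

    t: np.ndarray
    curves: np.ndarray  # (n_subjects, n_t)
    groups: np.ndarray  # e.g. "AGA"/"SGA" per curve

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.curves.ndim != 2 or self.curves.shape[1] != len(self.t):
            raise ValidationError("curves must be (n_subjects, n_t) on the shared grid")
        if len(self.groups) != self.curves.shape[0]:
            raise ValidationError("one group label per curve required")

    def split(self):
        labels = sorted(set(self.groups.tolist()))
        if len(labels) != 2:
            raise ValidationError(f"expected exactly 2 groups, got {labels}")
        return labels, [self.curves[self.groups == g] for g in labels]


def friedman_test(blocks: np.ndarray) -> dict:
    """Friedman rank-sum over an (n_blocks x k_conditions) outcome matrix.

    Within-block mid-ranks; χ² = 12/(n·k·(k+1))·ΣRⱼ² − 3n(k+1), referred to
    a χ² distribution with k−1 degrees of freedom.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValidationError("blocks must be a 2-D matrix")
    n, k = blocks.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 blocks and >= 2 conditions")
    if not np.all(np.isfinite(blocks)):
        raise ValidationError("blocks contain missing values")
    ranks = np.apply_along_axis(stats.rankdata, 1, blocks)  # mid-ranks for ties
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    df = k - 1
    return {"chi2": float(chi2), "df": df, "p": float(stats.chi2.sf(chi2, df))}


def pair_resampled_spearman(
    pairs: pd.DataFrame,
    x_field: str,
    y_field: str,
    reps: int = 1000,
    seed: int = 0,
    pair_field: str = "pair_id",
) -> dict:
    """Spearman correlation adjusted for twin pairs by resampling.

    Each replicate draws one twin per pair uniformly at random and computes
    Spearman r and p over the selected fetuses; the median r, the p of the
    replicate attaining the median r, the median p, and the full r
    distribution are returned.  Replicates with a constant x or y are
    recorded as missing and excluded from the median (count reported).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    grouped = pairs.groupby(pair_field)
    xs, ys = [], []
    for _, g in grouped:
        if len(g) != 2:
            raise ValidationError("every pair must contribute exactly two fetuses")
        xs.append(g[x_field].to_numpy(dtype=float))
        ys.append(g[y_field].to_numpy(dtype=float))
    x = np.array(xs)  # (n_pairs, 2)
    y = np.array(ys)
    n_pairs = len(x)
    if n_pairs < 4:
        raise ValidationError("need >= 4 twin pairs")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, size=(reps, n_pairs))
    rows = np.arange(n_pairs)
    rs = np.full(reps, np.nan)
    ps = np.full(reps, np.nan)
    for i in range(reps):
        xi = x[rows, picks[i]]
        yi = y[rows, picks[i]]
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            continue
        res = stats.spearmanr(xi, yi)
        rs[i], ps[i] = res.statistic, res.pvalue
    ok = np.isfinite(rs)
    if not ok.any():
        raise ValidationError("all replicates degenerate (constant x or y)")
    med = float(np.median(rs[ok]))
    idx_ok = np.flatnonzero(ok)
    at_median = idx_ok[np.argmin(np.abs(rs[idx_ok] - med))]
    return {
        "median_r": med,
        "median_p": float(ps[at_median]),
        "median_of_p": float(np.median(ps[ok])),
        "r_distribution": rs,
        "n_degenerate": int((~ok).sum()),
    }


def mixed_model_fit(
    table: pd.DataFrame,
    response_field: str,
    fixed_fields: list,
    group_field: str = "mother_id",
    re_variance: float | None = None,
) -> dict:
    """Linear mixed model with a random intercept per mother (REML, Wald p).

    ``re_variance=0`` constrains the random-intercept variance to zero, in
    which case the model reduces to ordinary least squares.  A rank-
    deficient fixed design raises CollinearityError naming the columns.
    """
    import statsmodels.api as sm

    X = table[list(fixed_fields)].to_numpy(dtype=float)
    y = table[response_field].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(y)), X])
    names = ["intercept"] + list(fixed_fields)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = []
        for j in range(1, exog.shape[1]):
            others = np.delete(exog, j, axis=1)
            resid = exog[:, j] - others @ np.linalg.lstsq(others, exog[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(exog[:, j]), 1.0):
                bad.append(names[j])
        raise CollinearityError(bad or names[1:])
    if table[group_field].nunique() < 2:
        raise ValidationError("need >= 2 groups for a random intercept")

    if re_variance == 0:
        res = sm.OLS(y, exog).fit()
        coefs, se, p = res.params, res.bse, res.pvalues
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=table[group_field].to_numpy())
            res = model.fit(reml=True)
        coefs = res.params[: len(names)]
        se = res.bse[: len(names)]
        p = res.pvalues[: len(names)]
        converged = bool(res.converged)
    return {
        "coefficients": dict(zip(names, np.asarray(coefs, dtype=float))),
        "se": dict(zip(names, np.asarray(se, dtype=float))),
        "p": dict(zip(names, np.asarray(p, dtype=float))),
        "converged": converged,
    }


def _welch(m1, s1, n1, m2, s2, n2):
    v1, v2 = s1**2 / n1, s2**2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance in both groups: identical means are a non-difference
    degenerate = (v1 + v2) == 0
    t = np.where(degenerate & (m1 == m2), 0.0, t)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), 0.0, p)
    return t, p


def fda_group_curves(
    c: CurveSet,
    knot_spacing: float = splines.DEFAULT_KNOT_SPACING,
    n_eval: int = 121,
) -> dict:
    """Functional comparison of AGA/SGA group mean curves.

    Each subject curve is least-squares-projected onto the shared cubic
    B-spline basis; group mean and sd functions are evaluated on a dense
    grid together with pointwise Welch t and two-sided p functions.
    """
    labels, (ga, gb) = c.split()
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("need >= 2 curves per group")
    B = splines.design_matrix(c.t, knot_spacing, c.t[0], c.t[-1])
    coef, *_ = np.linalg.lstsq(B, c.curves.T, rcond=None)  # (n_basis, n_subj)
    grid = np.linspace(c.t[0], c.t[-1], n_eval)
    Bg = splines.design_matrix(grid, knot_spacing, c.t[0], c.t[-1])
    smooth = (Bg @ coef).T  # (n_subj, n_eval)
    sa = smooth[np.asarray(c.groups) == labels[0]]
    sb = smooth[np.asarray(c.groups) == labels[1]]
    m1, s1 = sa.mean(axis=0), sa.std(axis=0, ddof=1)
    m2, s2 = sb.mean(axis=0), sb.std(axis=0, ddof=1)
    t_fun, p_fun = _welch(m1, s1, len(sa), m2, s2, len(sb))
    return {
        "grid": grid,
        "groups": labels,
        "mean": {labels[0]: m1, labels[1]: m2},
        "sd": {labels[0]: s1, labels[1]: s2},
        "t": t_fun,
        "p": p_fun,
    }


def group_difference_at(
    c: CurveSet,
    feature: str,
    t: float | None = None,
    paradigm: OxygenParadigm | None = None,
    knot_spacing: float = splines.DEFAULT_KNOT_SPACING,
) -> dict:
    """Two-sample Welch test of a per-subject curve feature between groups.

    ``feature`` is one of ``slope@t`` (B-spline derivative at ``t`` min),
    ``value@t`` (spline-smoothed value), or ``end_post_value`` (mean over
    the final minute of the post-hyperoxia epoch; requires ``paradigm``).
    """
    if feature in ("slope@t", "value@t") and t is None:
        raise ValidationError(f"feature {feature!r} needs a time point")
    feats = []
    for row in c.curves:
        tac = bold_signal.TimeActivityCurve("curve", c.t, row, np.zeros_like(row), 1)
        if feature == "slope@t":
            feats.append(bold_signal.curve_slope(tac, t, knot_spacing))
        elif feature == "value@t":
            feats.append(bold_signal.curve_value(tac, t, knot_spacing))
        elif feature == "end_post_value":
            if paradigm is None:
                raise ValidationError("end_post_value needs the paradigm")
            feats.append(bold_signal.amplitude_summary(tac, paradigm)["end_post_value"])
        else:
            raise ValidationError(f"unknown feature {feature!r}")
    feats = np.asarray(feats)
    labels, _ = c.split()
    fa = feats[np.asarray(c.groups) == labels[0]]
    fb = feats[np.asarray(c.groups) == labels[1]]
    if len(fa) < 2 or len(fb) < 2:
        raise ValidationError("need >= 2 subjects per group (variance undefined)")
    res = stats.ttest_ind(fa, fb, equal_var=False)
    return {
        "means": {labels[0]: float(fa.mean()), labels[1]: float(fb.mean())},
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "features": {labels[0]: fa, labels[1]: fb},
    }
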