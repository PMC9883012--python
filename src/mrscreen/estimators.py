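"""Univariable MR estimators and the quality-control battery.

Given a :class:`~mrscreen.instruments.HarmonisedSet` with J instruments,
the causal effect of the exposure on the outcome is estimated by:

* ``wald_ratio``     — single-variant ratio b_Y/b_X (first-order delta SE).
* ``ivw``            — weighted regression of b_Y on b_X through the
  origin, weights 1/se_Y²; the multiplicative-random-effects (MRE) variant,
  the primary estimate throughout, inflates the fixed-effect SE by
  max(1, sqrt(Q/(J-1))) so heterogeneous instruments widen the interval.
* ``egger``          — weighted regression with an intercept after
  orienting all rows to b_X >= 0; the intercept is the directional
  pleiotropy test, inference on t(J-2).
* ``weighted_median``— weighted 50th percentile of the per-variant ratios
  (consistent when >50% of weight is valid); parametric-bootstrap SE.
* ``weighted_mode``  — argmax of a weighted kernel density over the ratios
  (consistent when the largest weight cluster is valid); bootstrap SE.

``qc_battery`` assembles the diagnostics the screen gates on: mean
instrument F (weak below 10), Cochran's Q heterogeneity, the Egger
intercept, the I²_GX NOME statistic (Egger attenuation below 0.9) and
leave-one-out refits of the MRE IVW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .instruments import HarmonisedSet, InsufficientInstrumentsError

_Z95 = sps.norm.ppf(0.975)


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snv: int
    or_scale: float | None = None

    @classmethod
    def from_normal(cls, method, estimate, se, n_snv, or_scale_ok=False):
        p = float(np.clip(2.0 * sps.norm.sf(abs(estimate) / se), 1e-300, 1.0))
        return cls(method, float(estimate), float(se),
                   float(estimate - _Z95 * se), float(estimate + _Z95 * se),
                   p, int(n_snv),
                   float(np.exp(estimate)) if or_scale_ok else None)


@dataclass
class QCReport:
    cochran_q: float
    q_df: int
    q_pvalue: float
    egger_intercept: MRResult | None
    i2_gx: float
    mean_f: float
    loo: list[tuple[str, MRResult]]
    flags: set[str] = field(default_factory=set)
    notes: dict = field(default_factory=dict)


def _require(hset: HarmonisedSet, n: int, what: str) -> None:
    if len(hset) < n:
        raise InsufficientInstrumentsError(
            f"{what} needs >= {n} instruments, got {len(hset)}")


def _or_ok(hset: HarmonisedSet) -> bool:
    # ORs are only meaningful per 1 SD of a continuous exposure
    return hset.exposure_meta.trait_type == "continuous"


def wald_ratio(b_x: float, se_x: float, b_y: float, se_y: float,
               n_snv: int = 1) -> MRResult:
    """Single-instrument ratio estimate with first-order SE se_Y/|b_X|."""
    est = b_y / b_x
    se = se_y / abs(b_x)
    return MRResult.from_normal("wald_ratio", est, se, n_snv)


def ivw_stats(b_x, se_x, b_y, se_y):
    """Closed-form IVW pieces: (theta, fixed-effect se, Q)."""
    w = 1.0 / np.asarray(se_y, float) ** 2
    b_x = np.asarray(b_x, float); b_y = np.asarray(b_y, float)
    sxx = np.sum(w * b_x * b_x)
    theta = np.sum(w * b_x * b_y) / sxx
    se_fe = 1.0 / np.sqrt(sxx)
    q = float(np.sum(w * (b_y - theta * b_x) ** 2))
    return float(theta), float(se_fe), q


def ivw(hset: HarmonisedSet, effects: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate; MRE inflates SE under heterogeneity."""
    _require(hset, 2, "IVW")
    theta, se_fe, q = ivw_stats(hset.b_x, hset.se_x, hset.b_y, hset.se_y)
    j = len(hset)
    if effects == "multiplicative_random":
        se = se_fe * max(1.0, np.sqrt(q / (j - 1)))
        method = "ivw_mre"
    elif effects == "fixed":
        se, method = se_fe, "ivw_fe"
    else:
        raise ValueError(f"unknown effects model {effects!r}")
    return MRResult.from_normal(method, theta, se, j, or_scale_ok=_or_ok(hset))


def egger(hset: HarmonisedSet) -> tuple[MRResult, MRResult]:
    """MR-Egger slope and intercept (directional-pleiotropy test).

    Rows are oriented so b_X >= 0; weights 1/se_Y²; SEs inflated by
    max(1, sqrt(Q_egger/(J-2))); p-values from t(J-2).
    """
    _require(hset, 3, "Egger")
    sign = np.where(hset.b_x < 0, -1.0, 1.0)
    x = sign * hset.b_x
    y = sign * hset.b_y
    w = 1.0 / hset.se_y ** 2
    j = len(hset)
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    denom = sw * swxx - swx ** 2
    if denom <= 1e-14 * sw * swxx or np.ptp(x) == 0.0:
        raise InsufficientInstrumentsError(
            "Egger design is rank deficient (no spread in |b_x|)")
    slope = (sw * swxy - swx * swy) / denom
    inter = (swy - slope * swx) / sw
    resid = y - inter - slope * x
    q = float(np.sum(w * resid ** 2))
    infl = max(1.0, np.sqrt(q / (j - 2)))
    se_slope = np.sqrt(sw / denom) * infl
    se_inter = np.sqrt(swxx / denom) * infl

    def _t_result(method, est, se):
        p = float(np.clip(2.0 * sps.t.sf(abs(est) / se, df=j - 2), 1e-300, 1.0))
        tq = sps.t.ppf(0.975, df=j - 2)
        return MRResult(method, float(est), float(se), float(est - tq * se),
                        float(est + tq * se), p, j,
                        float(np.exp(est)) if method == "egger_slope" and _or_ok(hset) else None)

    return _t_result("egger_slope", slope, se_slope), \
        _t_result("egger_intercept", inter, se_inter)


def _ratio_weights(b_x, se_x, b_y, se_y, order: str = "first"):
    """Per-variant ratio estimates and inverse-variance weights."""
    r = b_y / b_x
    if order == "first":
        var = (se_y / np.abs(b_x)) ** 2
    elif order == "second":
        var = se_y ** 2 / b_x ** 2 + b_y ** 2 * se_x ** 2 / b_x ** 4
    else:
        raise ValueError(order)
    return r, 1.0 / var


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation across cumulative
    midpoint weights (equal weights reduce to the plain median)."""
    order = np.argsort(r)
    r, w = r[order], w[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def _mode_bandwidth(r: np.ndarray, w: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the weighted ratio distribution."""
    mu = np.sum(w * r) / np.sum(w)
    sd = np.sqrt(np.sum(w * (r - mu) ** 2) / np.sum(w))
    mad = np.median(np.abs(r - np.median(r))) * 1.4826
    s = min(sd, mad) if mad > 0 else sd
    return factor * 0.9 * s * len(r) ** (-1 / 5)


def _mode_point(r: np.ndarray, w: np.ndarray, h: float, grid_n: int = 512) -> float:
    if h <= 0 or np.ptp(r) == 0.0:
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_n)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2),
                  axis=1)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(hset: HarmonisedSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: redraw b_X, b_Y from Gaussians at their SEs."""
    rng = np.random.default_rng(seed)
    j = len(hset)
    bx = hset.b_x + rng.normal(size=(n_boot, j)) * hset.se_x
    by = hset.b_y + rng.normal(size=(n_boot, j)) * hset.se_y
    ests = np.array([point_fn(bx[i], by[i]) for i in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(hset: HarmonisedSet, n_boot: int = 1000,
                    seed: int = 0, weight_order: str = "first") -> MRResult:
    """Weighted-median estimate; robust to <50% invalid weight."""
    _require(hset, 3, "weighted median")
    r, w = _ratio_weights(hset.b_x, hset.se_x, hset.b_y, hset.se_y, weight_order)
    est = _weighted_median(r, w)

    def point(bx, by):
        rr, ww = _ratio_weights(bx, hset.se_x, by, hset.se_y, weight_order)
        return _weighted_median(rr, ww)

    se = _bootstrap_se(hset, point, n_boot, seed)
    return MRResult.from_normal("weighted_median", est, se, len(hset),
                                or_scale_ok=_or_ok(hset))


def weighted_mode(hset: HarmonisedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0,
                  weight_order: str = "first") -> MRResult:
    """Weighted-mode estimate; robust when the largest cluster is valid."""
    _require(hset, 3, "weighted mode")
    r, w = _ratio_weights(hset.b_x, hset.se_x, hset.b_y, hset.se_y, weight_order)
    h = _mode_bandwidth(r, w, bandwidth_factor)
    est = _mode_point(r, w, h)

    def point(bx, by):
        rr, ww = _ratio_weights(bx, hset.se_x, by, hset.se_y, weight_order)
        return _mode_point(rr, ww, _mode_bandwidth(rr, ww, bandwidth_factor))

    se = _bootstrap_se(hset, point, n_boot, seed)
    return MRResult.from_normal("weighted_mode", est, se, len(hset),
                                or_scale_ok=_or_ok(hset))


def cochran_q(hset: HarmonisedSet) -> tuple[float, int, float]:
    """Heterogeneity of per-variant causal estimates around the IVW fit."""
    _, _, q = ivw_stats(hset.b_x, hset.se_x, hset.b_y, hset.se_y)
    df = len(hset) - 1
    return q, df, float(sps.chi2.sf(q, df))


def i2_gx(hset: HarmonisedSet) -> float:
    """NOME violation statistic for Egger: heterogeneity of |b_X| precision.

    Q_GX is the 1/se_X²-weighted dispersion of the oriented instrument-
    exposure associations; I²_GX = (Q_GX - (J-1))/Q_GX floored at 0.
    Values below 0.9 indicate Egger attenuation towards the null.
    """
    x = np.abs(hset.b_x)
    w = 1.0 / hset.se_x ** 2
    xbar = np.sum(w * x) / np.sum(w)
    q_gx = float(np.sum(w * (x - xbar) ** 2))
    j = len(hset)
    if q_gx <= j - 1:
        return 0.0
    return (q_gx - (j - 1)) / q_gx


def qc_battery(hset: HarmonisedSet, alpha: float = 0.05) -> QCReport:
    """Full diagnostic battery for one exposure-outcome pair."""
    _require(hset, 2, "QC battery")
    f_j = (hset.b_x / hset.se_x) ** 2
    mean_f = float(np.mean(f_j))
    q, df, q_p = cochran_q(hset)
    full = ivw(hset)
    flags: set[str] = set()
    if mean_f <= 10:
        flags.add("weak_instruments")
    if q_p < alpha:
        flags.add("heterogeneous")
    intercept = None
    if len(hset) >= 3:
        try:
            _, intercept = egger(hset)
            if intercept.pvalue < alpha:
                flags.add("pleiotropy_detected")
        except InsufficientInstrumentsError:
            intercept = None
    i2 = i2_gx(hset)
    if i2 < 0.9:
        flags.add("nome_violation")
    loo: list[tuple[str, MRResult]] = []
    if len(hset) >= 3:
        for vid in hset.ids:
            loo.append((vid, ivw(hset.drop([vid]))))
        if full.pvalue < alpha and any(res.pvalue >= alpha for _, res in loo):
            flags.add("loo_unstable")
    return QCReport(q, df, q_p, intercept, i2, mean_f, loo, flags,
                    notes={"i2_gx_form": "1/se_x^2-weighted dispersion of |b_x|",
                           "full_ivw_p": full.pvalue})
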