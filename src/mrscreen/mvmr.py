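"""Multivariable MR: joint estimation for a small set of related exposures.

The design matrix holds, per instrument, the associations with each of K
exposures; the IVW-MVMR estimate is the 1/se_Y²-weighted multiple
regression of the outcome associations on those columns without an
intercept.  Instrument strength is assessed per exposure with the
conditional F-statistic — the measurement-error-weighted heterogeneity of
one exposure's instrument effects that cannot be explained by the other
exposures, divided by J-K+1 (with K=1 this reduces to the mean per-variant
F).  Selection thresholds start at 5e-8 per exposure and are relaxed by
factors of 10, weakest exposures only, until every conditional F exceeds
10 or the 5e-5 floor is reached.

When the adjusted Cochran's Q signals heterogeneity, a Q-minimisation
estimator is available: it minimises

    Q_A(theta) = sum_j (b_Yj - theta' b_Xj)^2 /
                 (se_Yj^2 + sum_k theta_k^2 se_Xjk^2
                  + 2 sum_{k<l} theta_k theta_l rho se_Xjk se_Xjl)

whose denominator propagates exposure measurement error under an assumed
phenotypic correlation rho (the analysis is run at both rho=0.1 and
rho=0.9 to check stability).  Confidence intervals come from inverting the
Q_A profile at the chi-square(1) cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .instruments import LADDER, align_alleles, clump
from .summstats import LDReference, SummaryStats, TraitMeta


class CollinearExposuresError(ValueError):
    """The multivariable design is rank deficient."""


class QMinConvergenceError(RuntimeError):
    def __init__(self, message, best, grad_norm):
        super().__init__(message)
        self.best = best
        self.grad_norm = grad_norm


@dataclass
class MVMRSet:
    """Jointly clumped, harmonised multi-exposure instrument table."""

    variant_ids: list[str]
    b_x: np.ndarray            # J x K
    se_x: np.ndarray           # J x K
    b_y: np.ndarray            # J
    se_y: np.ndarray           # J
    exposures: list[TraitMeta]
    thresholds: list[float]
    ladder_log: list[dict] = field(default_factory=list)
    weak: bool = False

    def __post_init__(self):
        self.b_x = np.atleast_2d(np.asarray(self.b_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        self.b_y = np.asarray(self.b_y, float)
        self.se_y = np.asarray(self.se_y, float)

    @property
    def J(self) -> int:
        return self.b_x.shape[0]

    @property
    def K(self) -> int:
        return self.b_x.shape[1]


@dataclass
class MVMRResult:
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    conditional_f: np.ndarray
    adjusted_q: float
    adjusted_q_pvalue: float
    qmin_estimates: dict = field(default_factory=dict)


def q_a(theta, b_x, se_x, b_y, se_y, rho: float = 0.0) -> float:
    """Heterogeneity statistic with exposure-measurement-error denominator."""
    theta = np.asarray(theta, float)
    resid = b_y - b_x @ theta
    sig = se_x * theta  # J x K
    var = se_y ** 2 + np.sum(sig ** 2, axis=1)
    if rho != 0.0 and theta.size > 1:
        cross = np.sum(sig, axis=1) ** 2 - np.sum(sig ** 2, axis=1)
        var = var + rho * cross
    return float(np.sum(resid ** 2 / var))


def conditional_f(mset: MVMRSet, rho: float = 0.0,
                  tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Per-exposure instrument strength conditional on the other exposures.

    For exposure k, the auxiliary coefficients delta regressing its
    instrument effects on the other exposures' effects are estimated by
    iterated weighted least squares (weights from the delta-method
    residual variance se_k^2 + sum delta^2 se_l^2 + rho cross-terms), and
    F_k = Q_x,k(delta_hat) / (J - K + 1).  With K = 1 this is the mean
    per-variant F.
    """
    J, K = mset.J, mset.K
    out = np.empty(K)
    for k in range(K):
        xk = mset.b_x[:, k]
        sek = mset.se_x[:, k]
        if K == 1:
            q = float(np.sum((xk / sek) ** 2))
        else:
            others = np.delete(mset.b_x, k, axis=1)
            se_others = np.delete(mset.se_x, k, axis=1)

            def _var(delta):
                sig = se_others * delta
                var = sek ** 2 + np.sum(sig ** 2, axis=1)
                if rho != 0.0:
                    # residual error is e_k - delta' e_others: signed loadings
                    s = np.concatenate([sek[:, None], -sig], axis=1)
                    cross = np.sum(s, axis=1) ** 2 - np.sum(s ** 2, axis=1)
                    var = var + rho * cross
                return var

            w = 1.0 / sek ** 2
            delta = np.zeros(K - 1)
            for _ in range(max_iter):
                Xw = others * w[:, None]
                new = np.linalg.lstsq(others.T @ Xw, Xw.T @ xk, rcond=None)[0]
                if np.max(np.abs(new - delta)) < tol:
                    delta = new
                    break
                delta = new
                w = 1.0 / _var(delta)
            q = float(np.sum((xk - others @ delta) ** 2 / _var(delta)))
        out[k] = q / (J - K + 1)
    return out


def mvmr_ivw(mset: MVMRSet, rho: float = 0.0) -> MVMRResult:
    """IVW multivariable MR with conditional F and adjusted Q diagnostics."""
    J, K = mset.J, mset.K
    if J <= K:
        raise ValueError(f"need more instruments ({J}) than exposures ({K})")
    w = 1.0 / mset.se_y ** 2
    Xw = mset.b_x * np.sqrt(w)[:, None]
    yw = mset.b_y * np.sqrt(w)
    XtX = Xw.T @ Xw
    # name offending exposure pairs before numpy raises an anonymous error
    corr = np.corrcoef(mset.b_x, rowvar=False)
    bad = [(mset.exposures[i].trait_id, mset.exposures[j].trait_id)
           for i in range(K) for j in range(i + 1, K)
           if abs(corr[i, j]) > 0.999]
    if bad or np.linalg.matrix_rank(XtX) < K:
        raise CollinearExposuresError(
            f"collinear exposure columns: {bad or 'rank-deficient design'}")
    cov = np.linalg.inv(XtX)
    theta = cov @ Xw.T @ yw
    ses = np.sqrt(np.diag(cov))
    z95 = sps.norm.ppf(0.975)
    pvals = np.clip(2.0 * sps.norm.sf(np.abs(theta) / ses), 1e-300, 1.0)
    adj_q = q_a(theta, mset.b_x, mset.se_x, mset.b_y, mset.se_y, rho=rho)
    adj_q_p = float(sps.chi2.sf(adj_q, df=J - K))
    return MVMRResult(
        estimates=theta, ses=ses,
        ci_low=theta - z95 * ses, ci_high=theta + z95 * ses,
        pvalues=pvals, conditional_f=conditional_f(mset, rho=rho),
        adjusted_q=adj_q, adjusted_q_pvalue=adj_q_p)


def qmin_estimate(mset: MVMRSet, rho: float,
                  ci_level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Minimise Q_A over theta; CIs by profile inversion at chi-square(1).

    Returns (theta_hat, ci) with ci of shape (K, 2).  Starts from the
    IVW-MVMR solution, so the minimised Q never exceeds the IVW Q.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    start = mvmr_ivw(mset).estimates

    def f(theta):
        return q_a(theta, mset.b_x, mset.se_x, mset.b_y, mset.se_y, rho=rho)

    res = optimize.minimize(f, start, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12,
                                     "maxiter": 5000, "maxfev": 5000})
    grad = optimize.approx_fprime(res.x, f, 1e-8)
    if not res.success and float(np.linalg.norm(grad)) > 1e-3:
        raise QMinConvergenceError("Q_A minimisation did not converge",
                                   best=res.x, grad_norm=float(np.linalg.norm(grad)))
    theta_hat = res.x
    q_min = float(res.fun)
    cut = q_min + sps.chi2.ppf(ci_level, df=1)
    K = theta_hat.size
    ci = np.empty((K, 2))
    scale = np.maximum(np.abs(theta_hat), 0.1)
    for k in range(K):
        def profile(t, k=k):
            if K == 1:
                return f(np.array([t]))
            fixed = list(range(K))
            fixed.remove(k)

            def inner(rest):
                th = np.empty(K)
                th[k] = t
                th[fixed] = rest
                return f(th)

            r = optimize.minimize(inner, theta_hat[fixed], method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-10})
            return float(r.fun)

        ci[k, 0] = _invert(profile, theta_hat[k], -scale[k], cut)
        ci[k, 1] = _invert(profile, theta_hat[k], scale[k], cut)
    return theta_hat, ci


def _invert(profile, center: float, step: float, cut: float) -> float:
    """Walk outward from the minimiser until the profile crosses the cut,
    then bisect.  Returns +/-inf when no crossing exists within 64 steps."""
    lo, hi = center, center + step
    for _ in range(64):
        if profile(hi) >= cut:
            return float(optimize.brentq(lambda t: profile(t) - cut, lo, hi,
                                         xtol=1e-8))
        lo, hi = hi, hi + (hi - center)
    return float(np.sign(step) * np.inf)


def _align_to_reference(ref_row, row):
    """Beta/se of ``row`` expressed per copy of the reference effect allele."""
    eaf_r = float(ref_row.eaf) if ref_row.eaf == ref_row.eaf else None
    eaf = float(row.eaf) if row.eaf == row.eaf else None
    action, reason = align_alleles(ref_row.effect_allele, ref_row.other_allele,
                                   row.effect_allele, row.other_allele,
                                   eaf_r, eaf)
    if action == "drop":
        return None
    sign = -1.0 if action == "flip" else 1.0
    return sign * float(row.beta), float(row.se), float(row.pvalue)


def build_mvmr_set(exposures: list[SummaryStats], outcome: SummaryStats,
                   ld: LDReference | None,
                   min_conditional_f: float = 10.0,
                   floor: float = 5e-5,
                   r2_max: float = 0.001, window_kb: int = 10_000,
                   rho: float = 0.0) -> MVMRSet:
    """Union of per-exposure instruments, jointly clumped and harmonised.

    Per-exposure thresholds start at 5e-8 and relax by factors of 10 (only
    for exposures whose conditional F is below ``min_conditional_f``) until
    strength is adequate or the floor is hit; a set that never reaches
    F > 10 is returned flagged ``weak``.
    """
    K = len(exposures)
    if K < 2:
        raise ValueError("multivariable MR needs K >= 2 exposures")
    thresholds = [LADDER[0]] * K
    ladder_log: list[dict] = []
    mset = None
    while True:
        mset = _assemble(exposures, outcome, ld, thresholds, r2_max, window_kb)
        if mset.J > K:
            fs = conditional_f(mset, rho=rho)
        else:
            fs = np.zeros(K)
        ladder_log.append({"thresholds": list(thresholds),
                           "n_instruments": mset.J,
                           "conditional_f": [float(x) for x in fs]})
        weak = [k for k in range(K) if fs[k] < min_conditional_f]
        can_relax = [k for k in weak if thresholds[k] < floor]
        if not weak or not can_relax:
            mset.ladder_log = ladder_log
            mset.weak = bool(weak)
            return mset
        for k in can_relax:
            thresholds[k] = min(thresholds[k] * 10.0, floor)


def _assemble(exposures, outcome, ld, thresholds, r2_max, window_kb) -> MVMRSet:
    K = len(exposures)
    union: set[str] = set()
    for k, stats in enumerate(exposures):
        t = stats.table
        union |= set(t.loc[t["pvalue"] < thresholds[k], "variant_id"])
    union = {v for v in union
             if all(v in x for x in exposures) and v in outcome}
    # clump priority: the best (smallest) p across exposures
    ref = exposures[0]

    def best_p(v):
        return min(x.get(v).pvalue for x in exposures)

    ranked = sorted(union, key=lambda v: (best_p(v), v))
    kept = _joint_clump(ranked, ref, ld, r2_max, window_kb)

    ids, B, SE, by, sey = [], [], [], [], []
    for v in kept:
        ref_row = ref.get(v)
        row_b = [float(ref_row.beta)]
        row_se = [float(ref_row.se)]
        ok = True
        for x in exposures[1:]:
            aligned = _align_to_reference(ref_row, x.get(v))
            if aligned is None:
                ok = False
                break
            row_b.append(aligned[0]); row_se.append(aligned[1])
        if not ok:
            continue
        out_aligned = _align_to_reference(ref_row, outcome.get(v))
        if out_aligned is None:
            continue
        ids.append(v)
        B.append(row_b); SE.append(row_se)
        by.append(out_aligned[0]); sey.append(out_aligned[1])
    return MVMRSet(ids, np.array(B).reshape(-1, K),
                   np.array(SE).reshape(-1, K),
                   np.array(by), np.array(sey),
                   [x.meta for x in exposures], list(thresholds))


def _joint_clump(ranked, ref, ld, r2_max, window_kb):
    window = window_kb * 1000
    kept: list[str] = []
    remaining = list(ranked)
    while remaining:
        index, rest = remaining[0], remaining[1:]
        kept.append(index)
        irow = ref.get(index)
        nxt = []
        for v in rest:
            row = ref.get(v)
            close = (str(row.chrom) == str(irow.chrom)
                     and abs(float(row.pos) - float(irow.pos)) <= window)
            r2 = ld.r2(index, v) if ld is not None else 0.0
            if close and r2 > r2_max:
                continue
            nxt.append(v)
        remaining = nxt
    return kept
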