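"""MR-BMA: Bayesian model averaging over candidate risk factors.

Ranks likely causal traits among many correlated exposures.  Instrument-
level associations are standardised (response y_j = b_Yj/se_Yj, predictors
x_jk = b_Xjk/se_Yj) and every subset S of risk factors is scored by the
marginal likelihood of a conjugate Gaussian linear model — effect prior
N(0, prior_var I), unit residual variance — times an independence model
prior P(S) = prior_p^|S| (1-prior_p)^(K-|S|).  With the defaults used
here, prior_p = 0.1 and prior_var = 0.25.

The marginal inclusion probability (MIP) of a risk factor is the summed
posterior probability of all models containing it; the model-averaged
causal estimate (MACE) is the posterior-weighted average of its
(shrinkage) effect estimate, zero when absent — a deliberately
conservative direct-effect summary on the standardised scale, indicative
of direction more than magnitude.

Model space is explored by a shotgun-style stochastic search (default
10,000 iterations; add/delete/swap proposals accepted by posterior ratio)
that caches every distinct model visited; for K <= 12 exhaustive
enumeration is available and the search is required to agree with it.
Traits correlated at |r| >= 0.99 across instruments are pruned first (one
of each pair removed by seeded RNG, avoiding selection bias).  Per-model
Cook's distances and Q contributions flag influential or outlying
instruments, which are removed and the analysis re-run until clean.
Empirical per-trait p-values come from permutations of the response
(default 100,000), and Benjamini-Hochberg FDR is applied across traits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import linalg as sla, stats as sps

from .screen import bh_fdr
from .summstats import LDReference, SummaryStats

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class BMAInput:
    """Standardised instrument-level design for model averaging."""

    y: np.ndarray                 # J
    X: np.ndarray                 # J x K
    instrument_ids: list[str]
    trait_ids: list[str]
    scales: np.ndarray | None = None   # column scales applied (for reporting)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if self.scales is None:
            self.scales = np.ones(self.X.shape[1])

    @property
    def J(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def correlation(self) -> np.ndarray:
        return np.corrcoef(self.X, rowvar=False)

    def drop_instruments(self, variant_ids) -> "BMAInput":
        gone = set(variant_ids)
        keep = [i for i, v in enumerate(self.instrument_ids) if v not in gone]
        return BMAInput(self.y[keep], self.X[keep],
                        [self.instrument_ids[i] for i in keep],
                        list(self.trait_ids), self.scales)

    def select_traits(self, idx) -> "BMAInput":
        idx = list(idx)
        return BMAInput(self.y, self.X[:, idx], list(self.instrument_ids),
                        [self.trait_ids[i] for i in idx], self.scales[idx])


def make_bma_input(exposures: list[SummaryStats], outcome: SummaryStats,
                   ld: LDReference | None, p_threshold: float = 5e-8,
                   r2_max: float = 0.001, window_kb: int = 10_000,
                   standardise: bool = True) -> BMAInput:
    """Build the standardised design from genome-wide-significant instruments."""
    from .mvmr import _assemble
    mset = _assemble(exposures, outcome, ld,
                     [p_threshold] * len(exposures), r2_max, window_kb)
    y = mset.b_y / mset.se_y
    X = mset.b_x / mset.se_y[:, None]
    scales = np.ones(X.shape[1])
    if standardise:
        scales = X.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        X = X / scales
    return BMAInput(y, X, list(mset.variant_ids),
                    [m.trait_id for m in mset.exposures], scales)


@dataclass
class BMAModel:
    subset: tuple[int, ...]
    posterior_prob: float
    theta: np.ndarray
    diagnostics: dict = field(default_factory=dict)  # variant_id -> (cooks, q)


@dataclass
class BMAConfig:
    prior_p: float = 0.1
    prior_var: float = 0.25
    n_iter: int = 10_000
    n_permutations: int = 100_000
    r_max: float = 0.99
    top_n_models: int = 10
    q_alpha: float = 0.05          # Bonferroni-corrected per instrument
    exhaustive_max_k: int = 12
    seed: int = 0


@dataclass
class BMAResult:
    table: pd.DataFrame            # trait, mip, mace, empirical_p, fdr_p, rank
    models: list[BMAModel]
    outliers_removed: list[tuple[str, str, tuple[float, float]]]
    meta: dict = field(default_factory=dict)


class DegenerateBMAError(RuntimeError):
    """Outlier removal left too few instruments for a meaningful model."""


def log_model_prior(size: int, K: int, prior_p: float) -> float:
    return size * np.log(prior_p) + (K - size) * np.log(1.0 - prior_p)


def model_posterior(input: BMAInput, S, prior_p: float = 0.1,
                    prior_var: float = 0.25) -> tuple[float, np.ndarray]:
    """Closed-form log marginal likelihood and posterior-mean effects of S.

    log ML = -J/2 log 2pi - 1/2 log det(I + tau2 X_S' X_S)
             - 1/2 (y'y - y' X_S A^{-1} X_S' y),  A = X_S'X_S + I/tau2.
    """
    S = tuple(S)
    if len(S) == 0:
        return float(-0.5 * input.J * _LOG2PI - 0.5 * input.y @ input.y), np.array([])
    Xs = input.X[:, S]
    A = Xs.T @ Xs + np.eye(len(S)) / prior_var
    try:
        c, low = sla.cho_factor(A)
    except np.linalg.LinAlgError:
        raise ValueError(f"singular design for model {S}")
    z = Xs.T @ input.y
    theta = sla.cho_solve((c, low), z)
    # det(I + tau2 X'X) = tau2^s det(A)
    logdet = len(S) * np.log(prior_var) + 2.0 * np.sum(np.log(np.diag(c)))
    quad = input.y @ input.y - z @ theta
    logml = -0.5 * input.J * _LOG2PI - 0.5 * logdet - 0.5 * quad
    return float(logml), theta


def _score(input, S, prior_p, prior_var):
    logml, theta = model_posterior(input, S, prior_p, prior_var)
    return logml + log_model_prior(len(S), input.K, prior_p), theta


def enumerate_models(input: BMAInput, prior_p: float = 0.1,
                     prior_var: float = 0.25,
                     max_size: int | None = None) -> dict[tuple, tuple[float, np.ndarray]]:
    """Score every subset (including the empty model) exhaustively."""
    K = input.K
    max_size = K if max_size is None else min(max_size, K)
    cache: dict[tuple, tuple[float, np.ndarray]] = {}
    for s in range(0, max_size + 1):
        for S in itertools.combinations(range(K), s):
            cache[S] = _score(input, S, prior_p, prior_var)
    return cache


def _mip_mace(input: BMAInput, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised posterior over the cache -> (posteriors, MIP, MACE)."""
    subsets = list(cache.keys())
    lp = np.array([cache[S][0] for S in subsets])
    post = np.exp(lp - lp.max())
    post /= post.sum()
    K = input.K
    mip = np.zeros(K)
    mace = np.zeros(K)
    for S, pr in zip(subsets, post):
        theta = cache[S][1]
        for i, k in enumerate(S):
            mip[k] += pr
            mace[k] += pr * theta[i]
    return post, mip, mace


def stochastic_search(input: BMAInput, n_iter: int = 10_000, seed: int = 0,
                      prior_p: float = 0.1, prior_var: float = 0.25
                      ) -> dict[tuple, tuple[float, np.ndarray]]:
    """Shotgun MH over model space; returns the cache of visited models.

    Proposals add, delete or swap one trait; acceptance by posterior
    ratio.  Every distinct model visited (accepted or not) is cached, so
    normalisation over the cache converges to the exhaustive answer.
    """
    if input.K < 2:
        raise ValueError("stochastic search needs K >= 2 candidate traits")
    rng = np.random.default_rng(seed)
    K = input.K
    cache: dict[tuple, tuple[float, np.ndarray]] = {}

    def score(S):
        if S not in cache:
            cache[S] = _score(input, S, prior_p, prior_var)
        return cache[S][0]

    current = tuple(sorted(rng.choice(K, size=1, replace=False)))
    score(()); lp_cur = score(current)
    for _ in range(n_iter):
        inside = list(current)
        outside = [k for k in range(K) if k not in current]
        moves = []
        if outside:
            moves.append("add")
        if len(inside) > 1:
            moves.append("delete")
        if inside and outside:
            moves.append("swap")
        move = moves[rng.integers(len(moves))]
        if move == "add":
            cand = sorted(inside + [outside[rng.integers(len(outside))]])
        elif move == "delete":
            cand = sorted(set(inside) - {inside[rng.integers(len(inside))]})
        else:
            cand = sorted(set(inside) - {inside[rng.integers(len(inside))]}
                          | {outside[rng.integers(len(outside))]})
        cand = tuple(cand)
        lp_new = score(cand)
        if np.log(rng.random()) < lp_new - lp_cur:
            current, lp_cur = cand, lp_new
    return cache


def diagnose_outliers(input: BMAInput, top_models: list[BMAModel],
                      cooks_rule: float | None = None,
                      q_rule: float | None = None,
                      prior_var: float = 0.25) -> list[tuple[str, dict, bool]]:
    """Per-variant Cook's distance and Q contribution across top models.

    Defaults: Cook's distance flagged above the median of an
    F(|S|, J-|S|) reference, Q contribution above the chi-square(1)
    upper point at 0.05/J (Bonferroni across instruments).  A variant is
    flagged when it exceeds a rule in any top model.
    """
    if not top_models:
        raise ValueError("top_models must be non-empty")
    J = input.J
    out = []
    stats_per_variant: dict[str, dict] = {
        v: {"cooks": [], "q": []} for v in input.instrument_ids}
    for model in top_models:
        S = model.subset
        if len(S) == 0:
            continue
        Xs = input.X[:, S]
        A = Xs.T @ Xs + np.eye(len(S)) / prior_var
        Ainv = np.linalg.inv(A)
        theta = Ainv @ Xs.T @ input.y
        fitted = Xs @ theta
        resid = input.y - fitted
        q_j = resid ** 2
        H = Xs @ Ainv @ Xs.T
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
        s = len(S)
        sigma2 = float(np.sum(resid ** 2) / max(J - s, 1))
        if sigma2 <= 1e-12 * float(input.y @ input.y) / J:
            cooks = np.zeros(J)  # numerically exact fit: no influence signal
        else:
            cooks = resid ** 2 * h / (sigma2 * s * (1.0 - h) ** 2)
        model.diagnostics = {
            v: (float(c), float(q))
            for v, c, q in zip(input.instrument_ids, cooks, q_j)}
        for v, c, q in zip(input.instrument_ids, cooks, q_j):
            stats_per_variant[v]["cooks"].append(float(c))
            stats_per_variant[v]["q"].append(float(q))
    q_cut = q_rule if q_rule is not None else sps.chi2.ppf(1.0 - 0.05 / J, df=1)
    for v, st in stats_per_variant.items():
        if not st["cooks"]:
            continue
        flagged = False
        for model in top_models:
            if not model.subset or v not in model.diagnostics:
                continue
            c, q = model.diagnostics[v]
            s = len(model.subset)
            c_cut = cooks_rule if cooks_rule is not None else \
                sps.f.ppf(0.5, s, max(J - s, 1))
            if c > c_cut or q > q_cut:
                flagged = True
        out.append((v, {"cooks_range": (min(st["cooks"]), max(st["cooks"])),
                        "q_range": (min(st["q"]), max(st["q"]))}, flagged))
    return out


def _top_models(cache, post_subsets, n) -> list[BMAModel]:
    subsets = list(cache.keys())
    lp = np.array([cache[S][0] for S in subsets])
    post = np.exp(lp - lp.max()); post /= post.sum()
    order = np.argsort(-post)
    models = []
    for i in order:
        S = subsets[i]
        if len(S) == 0:
            continue
        models.append(BMAModel(S, float(post[i]), cache[S][1]))
        if len(models) >= n:
            break
    return models


def _observed_scores(input, cfg):
    if input.K <= cfg.exhaustive_max_k:
        return enumerate_models(input, cfg.prior_p, cfg.prior_var)
    return stochastic_search(input, cfg.n_iter, cfg.seed,
                             cfg.prior_p, cfg.prior_var)


def prune_correlated(input: BMAInput, r_max: float = 0.99,
                     seed: int = 0) -> BMAInput:
    """Remove one member of each trait pair with |corr| >= r_max (seeded RNG
    picks which, avoiding manual-selection bias); iterates until clean."""
    rng = np.random.default_rng(seed)
    keep = list(range(input.K))
    while len(keep) > 1:
        C = np.corrcoef(input.X[:, keep], rowvar=False)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
        if abs(C[i, j]) < r_max:
            break
        drop = keep[i] if rng.random() < 0.5 else keep[j]
        keep.remove(drop)
    return input.select_traits(keep)


def _permutation_mips(input: BMAInput, models: dict, n_perm: int,
                      rng: np.random.Generator, cfg: BMAConfig) -> np.ndarray:
    """MIP per trait for each permuted response, vectorised over permutations.

    Permuting y leaves y'y unchanged, so each model's log posterior differs
    across permutations only through the quadratic form y'X_S A^{-1} X_S'y,
    computable from z = X'y alone.
    """
    J, K = input.J, input.K
    perm_idx = np.array([rng.permutation(J) for _ in range(n_perm)])
    Y = input.y[perm_idx].T                      # J x P
    Z = input.X.T @ Y                            # K x P
    subsets = list(models.keys())
    lp = np.empty((len(subsets), n_perm))
    yty = float(input.y @ input.y)
    base = -0.5 * J * _LOG2PI - 0.5 * yty
    incl = np.zeros((len(subsets), K))
    for i, S in enumerate(subsets):
        prior = log_model_prior(len(S), K, cfg.prior_p)
        if len(S) == 0:
            lp[i] = base + prior
            continue
        incl[i, list(S)] = 1.0
        Xs = input.X[:, S]
        A = Xs.T @ Xs + np.eye(len(S)) / cfg.prior_var
        c, low = sla.cho_factor(A)
        logdet = len(S) * np.log(cfg.prior_var) + 2.0 * np.sum(np.log(np.diag(c)))
        quad = np.sum(Z[list(S), :] * sla.cho_solve((c, low), Z[list(S), :]), axis=0)
        lp[i] = base + prior - 0.5 * logdet + 0.5 * quad
    lp -= lp.max(axis=0, keepdims=True)
    post = np.exp(lp)
    post /= post.sum(axis=0, keepdims=True)
    return incl.T @ post                          # K x P


def run_bma(input: BMAInput, cfg: BMAConfig | None = None) -> BMAResult:
    """Prune, search, remove outlier instruments iteratively, rank traits."""
    cfg = cfg or BMAConfig()
    if input.K < 2:
        raise ValueError("MR-BMA needs K >= 2 candidate risk factors")
    if input.J <= 2:
        raise ValueError("MR-BMA needs J > 2 instruments")
    work = prune_correlated(input, r_max=cfg.r_max, seed=cfg.seed)
    outliers_removed: list[tuple[str, str, tuple[float, float]]] = []
    while True:
        if work.J <= 2:
            raise DegenerateBMAError(
                "outlier removal left too few instruments for analysis")
        cache = _observed_scores(work, cfg)
        tops = _top_models(cache, None, cfg.top_n_models)
        diag = diagnose_outliers(work, tops, prior_var=cfg.prior_var)
        flagged = [(v, st) for v, st, f in diag if f]
        if not flagged:
            break
        if len(flagged) >= work.J:
            raise DegenerateBMAError("every instrument was flagged as outlying")
        for v, st in flagged:
            outliers_removed.append((v, "cooks_or_q", st["q_range"]))
        work = work.drop_instruments([v for v, _ in flagged])

    post, mip, mace = _mip_mace(work, cache)
    rng = np.random.default_rng(cfg.seed + 1)
    n_perm = cfg.n_permutations
    perm_mips = _permutation_mips(work, cache, n_perm, rng, cfg)
    emp_p = (1.0 + np.sum(perm_mips >= mip[:, None], axis=1)) / (n_perm + 1.0)
    fdr_p = bh_fdr(emp_p)
    order = np.argsort(-mip, kind="stable")
    table = pd.DataFrame({
        "rank": np.arange(1, work.K + 1),
        "trait": [work.trait_ids[i] for i in order],
        "mip": mip[order],
        "mace": mace[order],
        "empirical_p": emp_p[order],
        "fdr_p": fdr_p[order],
    })
    return BMAResult(table, tops, outliers_removed,
                     meta={"n_models_scored": len(cache),
                           "n_permutations": n_perm,
                           "seed": cfg.seed,
                           "n_instruments": work.J,
                           "pruned_traits": [t for t in input.trait_ids
                                             if t not in work.trait_ids]})
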