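"""Synthetic GWAS summary statistics with known ground truth.

Emulates the two-sample MR setting: per-variant effects on an exposure are
drawn from a zero-centred Gaussian, outcome effects are theta * b_X plus a
per-variant direct (pleiotropic) effect alpha, and both cohorts observe the
truth through Gaussian sampling noise whose standard error follows the
standardised-trait approximation se = (2 n eaf (1-eaf))^(-1/2).

Pleiotropy modes for the invalid-variant fraction:

* ``none``       alpha = 0 everywhere.
* ``balanced``   alpha ~ N(0, pleiotropy_sd) — InSIDE holds, mean zero.
* ``directional``alpha ~ N(pleiotropy_mean, pleiotropy_sd).
* ``correlated`` a latent confounder u_j ~ N(0,1) loads on both the
  exposure (u_j * pleiotropy_sd added to b_X) and the outcome
  (alpha = u_j * pleiotropy_mean), violating InSIDE; this reproduces the
  mediated/correlated-pleiotropy structure multivariable MR is meant to
  resolve.

Variants are laid out in LD blocks on one chromosome; within a block the
marginal exposure effect of a non-index member is sqrt(r2) times the index
effect plus an independent residual, and blocks are separated by more than
the clumping window so cross-block variants are truly independent.
Sampling noise is drawn independently per variant (LD propagates the
marginal effects, not their estimation errors).

A configurable fraction of variants is palindromic (A/T or G/C) and a
fraction is re-encoded on the opposite strand in the outcome file, so the
harmonisation path is exercised end to end.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .summstats import COMPLEMENT, LDReference, SummaryStats, TraitMeta

_P_FLOOR = 1e-300  # p-values are clamped into (0, 1]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated")


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for one exposure/outcome pair.

    Defaults describe the reference study conditions used throughout the
    test battery: ~50 independent instruments, 50k samples per cohort,
    per-variant exposure effects with SD 0.05 (instrument F-statistics in
    the tens to hundreds), 15% palindromic variants, 5% strand re-encoding.
    """

    n_variants: int = 50
    n_blocks: int = 50
    block_r2: tuple[float, float] = (0.2, 0.9)
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    theta_true: float | Sequence[float] = 0.0
    effect_sd: float = 0.05
    #: orient true effects to the exposure-raising allele (half-normal draws);
    #: the convention under which directional pleiotropy is defined
    positive_effects: bool = False
    #: multi-exposure designs only: give each exposure its own dedicated
    #: variants (round-robin) instead of dense shared effects — the
    #: architecture of a phenome-wide screen where traits are instrumented
    #: by distinct loci.  Ignores off-diagonal exposure_corr.
    sparse_effects: bool = False
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    prop_invalid: float = 0.0
    prop_palindromic: float = 0.15
    prop_palindromic_ambiguous: float = 0.3
    prop_strand_flipped: float = 0.05
    prop_missing_outcome: float = 0.0
    exposure_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_invalid", "prop_palindromic", "prop_strand_flipped",
                     "prop_missing_outcome", "prop_palindromic_ambiguous"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_blocks > self.n_variants:
            self.n_blocks = self.n_variants
        if self.exposure_corr is not None:
            C = np.asarray(self.exposure_corr, float)
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError("exposure_corr must be square")
            if not np.allclose(C, C.T):
                raise ValueError("exposure_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("exposure_corr must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("exposure_corr must be positive semidefinite")
            self.exposure_corr = C


@dataclass
class SimTruth:
    """What the generator actually planted, for recovery checks."""

    theta_true: np.ndarray
    invalid_variant_ids: set[str]
    b_x_true: pd.DataFrame          # variants x exposures, true marginal effects
    alpha: pd.Series                # direct (pleiotropic) outcome effects
    causal_exposures: list[int]     # indices k with theta_k != 0


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.clip(p, _P_FLOOR, 1.0)


def _layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Variant ids, blocks, positions, alleles, frequencies, LD reference."""
    m = cfg.n_variants
    ids = [f"rs{i + 1}" for i in range(m)]
    block_of = np.sort(np.arange(m) % cfg.n_blocks)
    # blocks 20 Mb apart (>> the 10,000 kb clumping window); members 10 kb apart
    within = np.concatenate([np.arange(np.sum(block_of == b))
                             for b in range(cfg.n_blocks)])
    pos = 1 + block_of.astype(np.int64) * 20_000_000 + within * 10_000

    pal = rng.random(m) < cfg.prop_palindromic
    ea = np.empty(m, dtype="U1")
    oa = np.empty(m, dtype="U1")
    bases = np.array(list("ACGT"))
    for j in range(m):
        if pal[j]:
            ea[j] = rng.choice(["A", "G"])
            oa[j] = COMPLEMENT[ea[j]]
            if rng.random() < 0.5:
                ea[j], oa[j] = oa[j], ea[j]
        else:
            while True:
                a, b = rng.choice(bases, size=2, replace=False)
                if COMPLEMENT[a] != b:
                    ea[j], oa[j] = a, b
                    break
    eaf = rng.uniform(0.05, 0.95, size=m)
    amb = pal & (rng.random(m) < cfg.prop_palindromic_ambiguous)
    eaf[amb] = rng.uniform(0.44, 0.56, size=int(amb.sum()))
    nonamb = pal & ~amb
    lo = rng.uniform(0.05, 0.40, size=int(nonamb.sum()))
    flip = rng.random(int(nonamb.sum())) < 0.5
    eaf[nonamb] = np.where(flip, 1.0 - lo, lo)

    ld = LDReference(dict(zip(ids, block_of.astype(int))))
    r2_within = np.ones(m)
    for b in range(cfg.n_blocks):
        members = np.flatnonzero(block_of == b)
        if len(members) < 2:
            continue
        idx = members[0]
        for j in members[1:]:
            r2 = rng.uniform(*cfg.block_r2)
            r2_within[j] = r2
            # phase: effect allele of the index co-occurs with EA of member
            ld.add_pair(ids[idx], ea[idx], ids[j], ea[j], float(r2))
    return ids, block_of, pos, ea, oa, eaf, pal, ld, r2_within


def _observe(truth: np.ndarray, n: int, eaf: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    beta = truth + rng.normal(0.0, se)
    return beta, se, _pvalue(beta, se)


def _outcome_encoding(cfg, rng, ids, ea, oa, eaf_true):
    """Allele labels and frequencies as the outcome cohort reports them."""
    m = len(ids)
    flipped = rng.random(m) < cfg.prop_strand_flipped
    ea_o, oa_o = ea.copy(), oa.copy()
    for j in np.flatnonzero(flipped):
        ea_o[j] = COMPLEMENT[ea[j]]
        oa_o[j] = COMPLEMENT[oa[j]]
    return ea_o, oa_o, flipped


def _build_stats(meta, ids, block_of, pos, ea, oa, eaf, beta, se, pval, n):
    df = pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": pval, "n": n,
    })
    return SummaryStats(meta, df, validate=False)


def simulate_pair(config: SimulationConfig
                  ) -> tuple[SummaryStats, SummaryStats, LDReference, SimTruth]:
    """One exposure/outcome pair with known causal effect and pleiotropy."""
    cfg = config
    theta = np.atleast_1d(np.asarray(cfg.theta_true, float))
    if theta.size != 1:
        raise ValueError("simulate_pair takes a scalar theta_true; "
                         "use simulate_multi_exposure for vectors")
    rng = np.random.default_rng(cfg.seed)
    ids, block_of, pos, ea, oa, eaf, pal, ld, r2w = _layout(cfg, rng)
    m = cfg.n_variants

    # true marginal effects: index variants get fresh draws, LD partners a
    # sqrt(r2)-attenuated copy plus independent residual
    raw = rng.normal(0.0, cfg.effect_sd, size=m)
    b_x = np.empty(m)
    for b in range(cfg.n_blocks):
        members = np.flatnonzero(block_of == b)
        idx = members[0]
        b_x[idx] = raw[idx]
        for j in members[1:]:
            r = np.sqrt(r2w[j])
            b_x[j] = r * raw[idx] + np.sqrt(1 - r * r) * raw[j]
    if cfg.positive_effects:
        b_x = np.abs(b_x)

    n_invalid = int(round(cfg.prop_invalid * m))
    invalid = rng.choice(m, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(m)
    if n_invalid and cfg.pleiotropy_mode != "none":
        if cfg.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "directional":
            alpha[invalid] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd,
                                        size=n_invalid)
        else:  # correlated: latent confounder loads on exposure and outcome
            u = rng.normal(0.0, 1.0, size=n_invalid)
            b_x[invalid] = b_x[invalid] + u * cfg.pleiotropy_sd
            alpha[invalid] = u * cfg.pleiotropy_mean
    b_y = theta[0] * b_x + alpha

    beta_x, se_x, p_x = _observe(b_x, cfg.n_exposure, eaf, rng)
    beta_y, se_y, p_y = _observe(b_y, cfg.n_outcome, eaf, rng)

    ea_o, oa_o, flipped = _outcome_encoding(cfg, rng, ids, ea, oa, eaf)

    exp_meta = TraitMeta("sim-exp", "simulated exposure", cfg.n_exposure)
    out_meta = TraitMeta("sim-out", "simulated outcome", cfg.n_outcome)
    exposure = _build_stats(exp_meta, ids, block_of, pos, ea, oa, eaf,
                            beta_x, se_x, p_x, cfg.n_exposure)
    keep = np.ones(m, bool)
    if cfg.prop_missing_outcome > 0:
        keep = rng.random(m) >= cfg.prop_missing_outcome
    outcome = _build_stats(out_meta, np.asarray(ids)[keep], block_of[keep],
                           pos[keep], ea_o[keep], oa_o[keep], eaf[keep],
                           beta_y[keep], se_y[keep], p_y[keep], cfg.n_outcome)

    truth = SimTruth(
        theta_true=theta,
        invalid_variant_ids={ids[j] for j in invalid},
        b_x_true=pd.DataFrame({"exp0": b_x}, index=ids),
        alpha=pd.Series(alpha, index=ids),
        causal_exposures=[0] if theta[0] != 0 else [],
    )
    return exposure, outcome, ld, truth


def simulate_multi_exposure(config: SimulationConfig
                            ) -> tuple[list[SummaryStats], SummaryStats,
                                       LDReference, SimTruth]:
    """K correlated exposures and one outcome generated from theta' b_X."""
    cfg = config
    theta = np.atleast_1d(np.asarray(cfg.theta_true, float))
    K = theta.size
    if K < 2:
        raise ValueError("multi-exposure design needs K >= 2 exposures")
    C = cfg.exposure_corr if cfg.exposure_corr is not None else np.eye(K)
    if C.shape != (K, K):
        raise ValueError(f"exposure_corr shape {C.shape} != ({K},{K})")
    rng = np.random.default_rng(cfg.seed)
    ids, block_of, pos, ea, oa, eaf, pal, ld, r2w = _layout(cfg, rng)
    m = cfg.n_variants

    # eigen square root tolerates exactly-singular correlation (duplicated traits)
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    raw = rng.normal(0.0, cfg.effect_sd, size=(m, K)) @ L.T
    B = np.empty((m, K))
    for b in range(cfg.n_blocks):
        members = np.flatnonzero(block_of == b)
        idx = members[0]
        B[idx] = raw[idx]
        for j in members[1:]:
            r = np.sqrt(r2w[j])
            B[j] = r * raw[idx] + np.sqrt(1 - r * r) * raw[j]
    if cfg.positive_effects:
        B = np.abs(B)
    if cfg.sparse_effects:
        owner = np.arange(m) % K
        mask = np.zeros((m, K))
        mask[np.arange(m), owner] = 1.0
        B = B * mask

    n_invalid = int(round(cfg.prop_invalid * m))
    invalid = rng.choice(m, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(m)
    if n_invalid and cfg.pleiotropy_mode != "none":
        if cfg.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "directional":
            alpha[invalid] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd,
                                        size=n_invalid)
        else:
            u = rng.normal(0.0, 1.0, size=n_invalid)
            B[invalid, 0] = B[invalid, 0] + u * cfg.pleiotropy_sd
            alpha[invalid] = u * cfg.pleiotropy_mean
    b_y = B @ theta + alpha

    exposures = []
    for k in range(K):
        beta_x, se_x, p_x = _observe(B[:, k], cfg.n_exposure, eaf, rng)
        meta = TraitMeta(f"sim-exp{k}", f"simulated exposure {k}", cfg.n_exposure)
        exposures.append(_build_stats(meta, ids, block_of, pos, ea, oa, eaf,
                                      beta_x, se_x, p_x, cfg.n_exposure))
    beta_y, se_y, p_y = _observe(b_y, cfg.n_outcome, eaf, rng)
    ea_o, oa_o, _ = _outcome_encoding(cfg, rng, ids, ea, oa, eaf)
    out_meta = TraitMeta("sim-out", "simulated outcome", cfg.n_outcome)
    outcome = _build_stats(out_meta, ids, block_of, pos, ea_o, oa_o, eaf,
                           beta_y, se_y, p_y, cfg.n_outcome)

    truth = SimTruth(
        theta_true=theta,
        invalid_variant_ids={ids[j] for j in invalid},
        b_x_true=pd.DataFrame(B, index=ids,
                              columns=[f"exp{k}" for k in range(K)]),
        alpha=pd.Series(alpha, index=ids),
        causal_exposures=[k for k in range(K) if theta[k] != 0],
    )
    return exposures, outcome, ld, truth
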