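"""Phenome-wide screening: per-trait pipeline, FDR, composite significance.

For every exposure trait the full univariable pipeline runs — batch
exclusion, adaptive instrument selection, clumping, harmonisation, the
outcome-significance and radial outlier filters, the estimator battery and
QC — and Benjamini-Hochberg FDR is applied across the MRE IVW p-values of
all analysed traits.  A trait is called significant only under the
composite criteria: FDR-adjusted IVW p below alpha, nominal significance
of both weighted median and weighted mode, and nominal significance of
every leave-one-out refit.  Estimator failures downgrade a trait to
``excluded`` with the error recorded; they never abort the screen.

Duplicate traits (same normalised name) are reduced to a primary analysis
before screening: largest sample size wins, ties by largest mean
F-statistic, then lexicographic id.  Replication re-runs significant
traits against a second outcome without touching primary verdicts, and
``reverse_mr`` swaps exposure and outcome to probe reverse causation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from . import instruments as ins
from .instruments import HarmonisedSet, InsufficientInstrumentsError, SelectionResult
from .summstats import LDReference, SummaryStats, TraitMeta


@dataclass
class ScreenConfig:
    fdr_alpha: float = 0.05
    nominal_alpha: float = 0.05
    excluded_batches: frozenset[str] = frozenset({"ukb", "met-d"})
    min_instruments: int = 6
    ladder: tuple = ins.LADDER
    r2_max: float = 0.001
    window_kb: int = 10_000
    proxy_r2_min: float = 0.9
    palindrome_maf: float = 0.42
    radial_alpha: float = 0.05
    outcome_filter_first: bool = True
    apply_outcome_filter: bool = True
    apply_radial_filter: bool = True
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_alpha < 1 and 0 < self.nominal_alpha < 1):
            raise ValueError("alphas must lie in (0,1)")


@dataclass
class ScreenRecord:
    trait: TraitMeta
    selection: SelectionResult | None
    primary: est.MRResult | None
    robust: dict[str, est.MRResult] = field(default_factory=dict)
    qc: est.QCReport | None = None
    fdr_p: float | None = None
    verdict: str = "excluded"
    exclusion_reason: str | None = None
    replication: dict[str, est.MRResult] | None = None
    log: list[dict] = field(default_factory=list)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dedup_traits(traits) -> list[TraitMeta]:
    """Reduce duplicate GWAS of one trait to a single primary analysis.

    ``traits`` is a collection of (TraitMeta, mean_f) pairs.  Grouping key
    is the case-folded, whitespace-collapsed trait name; largest sample
    size wins, ties by largest mean F, then lexicographic trait_id.
    """
    groups: dict[str, list] = {}
    for meta, mean_f in traits:
        key = " ".join(meta.trait_name.casefold().split())
        groups.setdefault(key, []).append((meta, mean_f))
    kept = []
    for key in groups:
        group = sorted(groups[key],
                       key=lambda t: (-t[0].sample_size, -t[1], t[0].trait_id))
        kept.append(group[0][0])
    kept.sort(key=lambda m: m.trait_id)
    return kept


def _trait_seed(base_seed: int, trait_id: str) -> int:
    """Per-trait bootstrap seed independent of input order."""
    return (base_seed * 1_000_003 + zlib.crc32(trait_id.encode())) % (2 ** 31)


def analyse_pair(exposure: SummaryStats, outcome: SummaryStats,
                 ld: LDReference | None, cfg: ScreenConfig):
    """Selection → harmonisation → filters → estimators → QC for one pair.

    Returns a ScreenRecord with verdict unset (fdr_p is filled by the
    caller once the whole family is known).
    """
    rec = ScreenRecord(trait=exposure.meta, selection=None, primary=None)
    if exposure.meta.batch in cfg.excluded_batches:
        rec.exclusion_reason = "batch"
        return rec
    sel = ins.select_instruments(exposure, ld, min_count=cfg.min_instruments,
                                 r2_max=cfg.r2_max, window_kb=cfg.window_kb,
                                 ladder=cfg.ladder)
    rec.selection = sel
    if not sel.sufficient:
        rec.exclusion_reason = "insufficient_instruments"
        return rec
    try:
        hset = ins.harmonise(exposure, outcome, sel, ld,
                             palindrome_maf=cfg.palindrome_maf,
                             proxy_r2_min=cfg.proxy_r2_min)
        filters = []
        if cfg.apply_outcome_filter:
            filters.append("outcome")
        if cfg.apply_radial_filter:
            filters.append("radial")
        if not cfg.outcome_filter_first:
            filters.reverse()
        for f in filters:
            if f == "outcome":
                hset = ins.filter_outcome_significance(hset)
            else:
                hset, _ = ins.radial_outlier_filter(hset, alpha=cfg.radial_alpha)
        if len(hset) < cfg.min_instruments:
            rec.exclusion_reason = "insufficient_instruments_after_filtering"
            rec.log = hset.log
            return rec
        seed = _trait_seed(cfg.seed, exposure.meta.trait_id)
        rec.primary = est.ivw(hset, effects="multiplicative_random")
        slope, intercept = est.egger(hset)
        rec.robust = {
            "weighted_median": est.weighted_median(hset, n_boot=cfg.n_boot, seed=seed),
            "weighted_mode": est.weighted_mode(hset, n_boot=cfg.n_boot, seed=seed + 1),
            "egger_slope": slope,
            "egger_intercept": intercept,
        }
        rec.qc = est.qc_battery(hset, alpha=cfg.nominal_alpha)
        rec.verdict = "not_significant"  # provisional until FDR is applied
        rec.log = hset.log
    except (InsufficientInstrumentsError, ValueError) as exc:
        rec.exclusion_reason = f"estimator_error: {exc}"
        rec.verdict = "excluded"
    return rec


def _composite_verdict(rec: ScreenRecord, cfg: ScreenConfig) -> str:
    if rec.fdr_p is None or rec.fdr_p >= cfg.fdr_alpha:
        return "not_significant"
    if rec.robust["weighted_median"].pvalue >= cfg.nominal_alpha:
        return "not_significant"
    if rec.robust["weighted_mode"].pvalue >= cfg.nominal_alpha:
        return "not_significant"
    if any(res.pvalue >= cfg.nominal_alpha for _, res in rec.qc.loo):
        return "not_significant"
    return "significant"


def run_screen(exposures, outcome: SummaryStats, ld: LDReference | None,
               cfg: ScreenConfig | None = None) -> list[ScreenRecord]:
    """Screen many exposures against one outcome with composite criteria.

    The FDR family is all traits analysed in this invocation; excluded
    traits do not enter the correction.  Output order follows trait_id, so
    verdicts are invariant to the order exposures are supplied.
    """
    cfg = cfg or ScreenConfig()
    records = [analyse_pair(x, outcome, ld, cfg)
               for x in sorted(exposures, key=lambda s: s.meta.trait_id)]
    analysed = [r for r in records if r.primary is not None]
    if analysed:
        adj = bh_fdr([r.primary.pvalue for r in analysed])
        for r, a in zip(analysed, adj):
            r.fdr_p = float(a)
            r.verdict = _composite_verdict(r, cfg)
    return records


def replicate(records, second_outcome: SummaryStats, ld: LDReference | None,
              cfg: ScreenConfig | None = None,
              exposures_by_id: dict[str, SummaryStats] | None = None
              ) -> list[ScreenRecord]:
    """Re-run significant traits against a second outcome.

    Results land in ``record.replication``; primary verdicts are never
    altered (failure to replicate does not disprove causality).
    ``exposures_by_id`` maps trait_id to the exposure SummaryStats.
    """
    cfg = cfg or ScreenConfig()
    exposures_by_id = exposures_by_id or {}
    for rec in records:
        if rec.verdict != "significant":
            continue
        exposure = exposures_by_id.get(rec.trait.trait_id)
        if exposure is None:
            rec.replication = None
            continue
        rep = analyse_pair(exposure, second_outcome, ld, cfg)
        if rep.primary is not None:
            rec.replication = {"ivw_mre": rep.primary, **rep.robust}
        else:
            rec.replication = {}
    return records


def reverse_mr(exposure: SummaryStats, outcome: SummaryStats,
               ld: LDReference | None,
               cfg: ScreenConfig | None = None) -> est.MRResult:
    """Probe reverse causation: instrument the outcome, estimate on the
    original exposure, and return the MRE IVW result."""
    cfg = cfg or ScreenConfig()
    sel = ins.select_instruments(outcome, ld, min_count=cfg.min_instruments,
                                 r2_max=cfg.r2_max, window_kb=cfg.window_kb,
                                 ladder=cfg.ladder)
    if not sel.sufficient:
        raise InsufficientInstrumentsError(
            f"outcome trait has only {sel.n_selected} selectable instruments")
    hset = ins.harmonise(outcome, exposure, sel, ld,
                         palindrome_maf=cfg.palindrome_maf,
                         proxy_r2_min=cfg.proxy_r2_min)
    if cfg.apply_outcome_filter:
        hset = ins.filter_outcome_significance(hset)
    if cfg.apply_radial_filter:
        hset, _ = ins.radial_outlier_filter(hset, alpha=cfg.radial_alpha)
    return est.ivw(hset, effects="multiplicative_random")
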