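"""Instrument selection, clumping, proxy substitution and harmonisation.

Turns a pair of :class:`~mrscreen.summstats.SummaryStats` into the
analysis-ready :class:`HarmonisedSet` every estimator operates on.

Selection walks an adaptive p-value ladder 5e-8, 5e-7, 5e-6, 5e-5 and stops
at the first rung where more than five (by default) post-clumping
instruments are available; traits that never reach the count are flagged
insufficient rather than analysed underpowered.  Clumping is the standard
greedy procedure: lowest p first, discard correlated neighbours (r² above
0.001 within 10,000 kb).  Instruments absent from the outcome can be
replaced by a proxy in high LD (r² >= 0.9) whose allele phase is known.

Harmonisation expresses both betas per additional copy of the same allele:
swapped allele labels flip the outcome beta sign, strand-complement
encodings are complemented first, and palindromic (A/T, G/C) variants are
frequency-aligned — or dropped when the minor allele frequency exceeds 0.42
in either dataset, where strand cannot be resolved reliably.

Two instrument filters follow: removal of variants more significant for
the outcome than the exposure (a directionality guard against reverse
causation and pleiotropy), and iterative radial-MR outlier removal using
modified second-order weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .summstats import (COMPLEMENT, LDReference, SummaryStats, TraitMeta,
                        is_palindromic)

#: adaptive selection ladder, each rung a factor of 10 above the last
LADDER = (5e-8, 5e-7, 5e-6, 5e-5)

HARM_COLUMNS = ["variant_id", "effect_allele", "other_allele",
                "b_x", "se_x", "p_x", "eaf_x",
                "b_y", "se_y", "p_y", "eaf_y", "proxy_id", "proxy_r2"]


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested operation."""


@dataclass
class SelectionResult:
    threshold_used: float
    selected_ids: list[str]
    n_selected: int
    ladder_log: list[tuple[float, int]]
    sufficient: bool = True

    def __post_init__(self):
        assert self.n_selected == len(self.selected_ids)


@dataclass
class HarmonisedSet:
    """Aligned exposure-outcome instrument table.

    All rows share one effect-allele convention: flipping any row's alleles
    flips the sign of both betas.  ``log`` records every drop, flip and
    proxy substitution with its reason.
    """

    table: pd.DataFrame
    exposure_meta: TraitMeta
    outcome_meta: TraitMeta
    log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def __getattr__(self, name):
        if name in HARM_COLUMNS:
            return self.table[name].to_numpy()
        raise AttributeError(name)

    @property
    def ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def drop(self, variant_ids, reason: str = "dropped") -> "HarmonisedSet":
        gone = set(variant_ids)
        keep = ~self.table["variant_id"].isin(gone)
        new_log = self.log + [{"variant_id": v, "action": "drop", "reason": reason}
                              for v in gone]
        return HarmonisedSet(self.table[keep].reset_index(drop=True),
                             self.exposure_meta, self.outcome_meta, new_log)

    def subset(self, variant_ids) -> "HarmonisedSet":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return HarmonisedSet(self.table[keep].reset_index(drop=True),
                             self.exposure_meta, self.outcome_meta, list(self.log))


def clump(candidates, exposure: SummaryStats, ld: LDReference | None,
          r2_max: float = 0.001, window_kb: int = 10_000) -> list[str]:
    """Greedy LD clumping: lowest-p index first, discard correlated neighbours.

    A remaining candidate is discarded when it lies within ``window_kb`` of
    the index on the same chromosome and r² with the index exceeds
    ``r2_max``.  Variants absent from the LD reference are treated as
    independent.  Returns retained ids in order of retention.
    """
    cand = [c for c in candidates if c in exposure]
    cand.sort(key=lambda v: (exposure.get(v).pvalue, v))
    window = window_kb * 1000
    retained: list[str] = []
    remaining = cand
    while remaining:
        index, rest = remaining[0], remaining[1:]
        retained.append(index)
        irow = exposure.get(index)
        keep = []
        for v in rest:
            row = exposure.get(v)
            same_chr = str(row.chrom) == str(irow.chrom)
            close = same_chr and abs(float(row.pos) - float(irow.pos)) <= window
            r2 = ld.r2(index, v) if ld is not None else 0.0
            if close and r2 > r2_max:
                continue
            keep.append(v)
        remaining = keep
    return retained


def select_instruments(exposure: SummaryStats, ld: LDReference | None = None,
                       min_count: int = 6, r2_max: float = 0.001,
                       window_kb: int = 10_000,
                       ladder=LADDER) -> SelectionResult:
    """Walk the p-value ladder until enough post-clumping instruments exist.

    Returns the smallest rung with >= ``min_count`` clumped instruments; if
    none suffices the final rung's selection is returned flagged
    insufficient (a flag, never an error).
    """
    if len(exposure) == 0:
        raise ValueError("exposure has no records")
    pv = exposure.table["pvalue"].to_numpy()
    ids = np.asarray(exposure.ids)
    ladder_log: list[tuple[float, int]] = []
    last: list[str] = []
    for thr in ladder:
        cand = ids[pv < thr]
        last = clump(list(cand), exposure, ld, r2_max=r2_max, window_kb=window_kb)
        ladder_log.append((thr, len(last)))
        if len(last) >= min_count:
            return SelectionResult(thr, last, len(last), ladder_log, True)
    return SelectionResult(ladder[-1], last, len(last), ladder_log, False)


def find_proxy(missing_id: str, outcome: SummaryStats, ld: LDReference,
               r2_min: float = 0.9):
    """Best available LD proxy present in the outcome, or None.

    Highest r² wins; ties break by smallest outcome p-value, then
    lexicographic id.  Returns (proxy_id, r2, (index_allele, proxy_allele)).
    """
    cands = [(pid, r2) for pid, r2 in ld.partners(missing_id)
             if r2 >= r2_min and pid in outcome]
    if not cands:
        return None
    cands.sort(key=lambda t: (-t[1], outcome.get(t[0]).pvalue, t[0]))
    pid, r2 = cands[0]
    return pid, r2, ld.phase(missing_id, pid)


def align_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str,
                  eaf_x, eaf_y, palindrome_maf: float = 0.42):
    """Decide how an outcome row maps onto the exposure allele convention.

    Returns (action, reason) where action is "keep" (signs agree), "flip"
    (negate outcome beta) or "drop".  Palindromic variants are resolved by
    allele frequency and dropped inside the ambiguity zone
    min(eaf, 1-eaf) > palindrome_maf, or when frequency is missing.
    """
    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "drop", "irreconcilable_alleles"
        if eaf_x is None or eaf_y is None or \
                (isinstance(eaf_x, float) and math.isnan(eaf_x)) or \
                (isinstance(eaf_y, float) and math.isnan(eaf_y)):
            return "drop", "palindromic_missing_eaf"
        if min(eaf_x, 1 - eaf_x) > palindrome_maf or \
                min(eaf_y, 1 - eaf_y) > palindrome_maf:
            return "drop", "palindromic_ambiguous"
        # strand labels are uninformative: the outcome effect allele is the
        # exposure effect allele iff both frequencies fall on the same side
        return ("keep", "palindromic_freq_aligned") \
            if (eaf_x < 0.5) == (eaf_y < 0.5) else ("flip", "palindromic_freq_flipped")
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "keep", "direct"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flip", "swapped"
    cea, coa = COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)
    if (cea, coa) == (ea_x, oa_x):
        return "keep", "strand_complement"
    if (cea, coa) == (oa_x, ea_x):
        return "flip", "strand_complement_swapped"
    return "drop", "irreconcilable_alleles"


def _proxy_aligned_outcome(ea_x, oa_x, prow, phase):
    """Outcome beta/se/p/eaf of a proxy expressed per copy of the index EA.

    ``phase`` is (index_allele, proxy_allele): those two co-occur.  Returns
    (b_y, se_y, p_y, eaf_y) or None when the phase cannot be reconciled.
    """
    a_idx, a_prox = phase
    if a_idx not in (ea_x, oa_x):
        a_idx, a_prox = COMPLEMENT.get(a_idx), COMPLEMENT.get(a_prox)
        if a_idx not in (ea_x, oa_x):
            return None
    # allele of the proxy that tracks the index effect allele
    p_ea, p_oa = prow.effect_allele, prow.other_allele
    if a_prox not in (p_ea, p_oa):
        a_prox = COMPLEMENT.get(a_prox)
        if a_prox not in (p_ea, p_oa):
            return None
    if a_idx == ea_x:
        track = a_prox
    else:
        track = p_oa if a_prox == p_ea else p_ea
    eaf = float(prow.eaf) if prow.eaf == prow.eaf else float("nan")
    if track == p_ea:
        return float(prow.beta), float(prow.se), float(prow.pvalue), eaf
    return -float(prow.beta), float(prow.se), float(prow.pvalue), 1.0 - eaf


def harmonise(exposure: SummaryStats, outcome: SummaryStats,
              selection: SelectionResult, ld: LDReference | None = None,
              palindrome_maf: float = 0.42,
              proxy_r2_min: float = 0.9) -> HarmonisedSet:
    """Align selected instruments to the exposure effect-allele convention.

    Instruments absent from the outcome are proxied when ``ld`` allows;
    every drop, flip and substitution is logged with its reason.
    """
    rows, log = [], []
    for vid in selection.selected_ids:
        xrow = exposure.get(vid)
        eaf_x = float(xrow.eaf) if xrow.eaf == xrow.eaf else None
        proxy_id, proxy_r2 = None, np.nan
        if vid in outcome:
            yrow = outcome.get(vid)
            eaf_y = float(yrow.eaf) if yrow.eaf == yrow.eaf else None
            action, reason = align_alleles(
                xrow.effect_allele, xrow.other_allele,
                yrow.effect_allele, yrow.other_allele,
                eaf_x, eaf_y, palindrome_maf)
            if action == "drop":
                log.append({"variant_id": vid, "action": "drop", "reason": reason})
                continue
            sign = -1.0 if action == "flip" else 1.0
            b_y = sign * float(yrow.beta)
            se_y, p_y = float(yrow.se), float(yrow.pvalue)
            eaf_out = (eaf_y if action == "keep" else
                       (1.0 - eaf_y if eaf_y is not None else None))
            if action == "flip":
                log.append({"variant_id": vid, "action": "flip", "reason": reason})
        else:
            if ld is None:
                log.append({"variant_id": vid, "action": "drop",
                            "reason": "missing_in_outcome"})
                continue
            hit = find_proxy(vid, outcome, ld, r2_min=proxy_r2_min)
            if hit is None:
                log.append({"variant_id": vid, "action": "drop",
                            "reason": "missing_in_outcome_no_proxy"})
                continue
            proxy_id, proxy_r2, phase = hit
            aligned = _proxy_aligned_outcome(
                xrow.effect_allele, xrow.other_allele, outcome.get(proxy_id), phase)
            if aligned is None:
                log.append({"variant_id": vid, "action": "drop",
                            "reason": "proxy_phase_irreconcilable"})
                continue
            b_y, se_y, p_y, eaf_out = aligned
            log.append({"variant_id": vid, "action": "proxy",
                        "reason": f"{proxy_id}:r2={proxy_r2:.3f}"})
        rows.append({
            "variant_id": vid,
            "effect_allele": xrow.effect_allele, "other_allele": xrow.other_allele,
            "b_x": float(xrow.beta), "se_x": float(xrow.se),
            "p_x": float(xrow.pvalue),
            "eaf_x": np.nan if eaf_x is None else eaf_x,
            "b_y": b_y, "se_y": se_y, "p_y": p_y,
            "eaf_y": np.nan if eaf_out is None else eaf_out,
            "proxy_id": proxy_id, "proxy_r2": proxy_r2,
        })
    table = pd.DataFrame(rows, columns=HARM_COLUMNS)
    return HarmonisedSet(table, exposure.meta, outcome.meta, log)


def filter_outcome_significance(hset: HarmonisedSet) -> HarmonisedSet:
    """Remove instruments more significant for the outcome than the exposure.

    Guards against reverse causation and gross pleiotropy: a valid
    instrument acts on the outcome only through the exposure, so it cannot
    associate more strongly with the outcome.  Idempotent.
    """
    bad = hset.table.loc[hset.table["p_y"] < hset.table["p_x"], "variant_id"]
    return hset.drop(list(bad), reason="outcome_more_significant") if len(bad) else hset


def radial_fit(b_x, se_x, b_y, se_y, tol: float = 1e-10, max_iter: int = 200):
    """Radial IVW slope with modified second-order weights.

    Weights w_j = b_x² / (se_y² + θ² se_x²) depend on the slope, so the fit
    iterates weight and slope updates to convergence.  Returns
    (theta, se_theta, per-variant Q contributions).
    """
    b_x = np.asarray(b_x, float); se_x = np.asarray(se_x, float)
    b_y = np.asarray(b_y, float); se_y = np.asarray(se_y, float)
    ratio = b_y / b_x
    w = b_x ** 2 / se_y ** 2  # first-order start
    theta = float(np.sum(w * ratio) / np.sum(w))
    for _ in range(max_iter):
        w = b_x ** 2 / (se_y ** 2 + theta ** 2 * se_x ** 2)
        new = float(np.sum(w * ratio) / np.sum(w))
        if abs(new - theta) < tol:
            theta = new
            break
        theta = new
    q_j = w * (ratio - theta) ** 2
    se_theta = float(1.0 / np.sqrt(np.sum(w)))
    return theta, se_theta, q_j


def radial_outlier_filter(hset: HarmonisedSet, alpha: float = 0.05
                          ) -> tuple[HarmonisedSet, list[str]]:
    """Iteratively remove instruments with outlying radial Q contributions.

    Per-variant contributions are referred to the chi-square(1) upper-tail
    critical value at ``alpha``; the slope is refitted after each removal
    round until no contribution exceeds the cut-off.  Fewer than three
    instruments: returned unchanged with a log warning.
    """
    if len(hset) < 3:
        hset.log.append({"variant_id": "", "action": "skip",
                         "reason": "radial_filter_needs_3_instruments"})
        return hset, []
    crit = sps.chi2.ppf(1.0 - alpha, df=1)
    removed: list[str] = []
    current = hset
    while len(current) >= 3:
        _, _, q_j = radial_fit(current.b_x, current.se_x,
                               current.b_y, current.se_y)
        mask = q_j > crit
        if not mask.any():
            break
        gone = [current.ids[i] for i in np.flatnonzero(mask)]
        removed.extend(gone)
        current = current.drop(gone, reason="radial_outlier")
    return current, removed
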