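"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrscreen.instruments import HARM_COLUMNS, HarmonisedSet, SelectionResult
from mrscreen.summstats import SummaryStats, TraitMeta


def make_summary(ids, beta, se, pvalue, ea=None, oa=None, eaf=None,
                 chrom="1", pos=None, n=50_000, meta=None,
                 trait_id="trait", validate=False) -> SummaryStats:
    m = len(ids)
    df = pd.DataFrame({
        "variant_id": ids,
        "chrom": chrom if np.ndim(chrom) else [chrom] * m,
        "pos": pos if pos is not None else np.arange(m) * 20_000_000 + 1,
        "effect_allele": ea if ea is not None else ["A"] * m,
        "other_allele": oa if oa is not None else ["G"] * m,
        "eaf": eaf if eaf is not None else [0.3] * m,
        "beta": beta, "se": se, "pvalue": pvalue,
        "n": n,
    })
    meta = meta or TraitMeta(trait_id, trait_id, int(np.max(n)))
    return SummaryStats(meta, df, validate=validate)


def make_hset(b_x, se_x, b_y, se_y, ids=None, exposure_type="continuous",
              p_x=None, p_y=None) -> HarmonisedSet:
    from scipy import stats as sps
    b_x = np.asarray(b_x, float); se_x = np.asarray(se_x, float)
    b_y = np.asarray(b_y, float); se_y = np.asarray(se_y, float)
    j = len(b_x)
    ids = ids if ids is not None else [f"rs{i+1}" for i in range(j)]
    p_x = p_x if p_x is not None else np.clip(2 * sps.norm.sf(np.abs(b_x) / se_x), 1e-300, 1)
    p_y = p_y if p_y is not None else np.clip(2 * sps.norm.sf(np.abs(b_y) / se_y), 1e-300, 1)
    df = pd.DataFrame({
        "variant_id": ids, "effect_allele": "A", "other_allele": "G",
        "b_x": b_x, "se_x": se_x, "p_x": p_x, "eaf_x": 0.3,
        "b_y": b_y, "se_y": se_y, "p_y": p_y, "eaf_y": 0.3,
        "proxy_id": None, "proxy_r2": np.nan,
    })[HARM_COLUMNS]
    exp = TraitMeta("exp", "exposure", 50_000, exposure_type)
    out = TraitMeta("out", "outcome", 50_000, "binary")
    return HarmonisedSet(df, exp, out)


def full_selection(stats: SummaryStats) -> SelectionResult:
    ids = stats.ids
    return SelectionResult(5e-8, ids, len(ids), [(5e-8, len(ids))], True)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
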