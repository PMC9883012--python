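"""Screen orchestration: dedup, FDR, composite verdicts, replication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen.instruments import InsufficientInstrumentsError
from mrscreen.screen import (ScreenConfig, bh_fdr, dedup_traits, replicate,
                             reverse_mr, run_screen)
from mrscreen.summstats import TraitMeta
from mrscreen.synthdata import SimulationConfig, simulate_multi_exposure, simulate_pair

from conftest import make_summary


def _bh_oracle(p):
    """Textbook step-up BH: p(i) * m / i with running minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_matches_spec_example():
    adj = bh_fdr([0.001, 0.01, 0.02, 0.8])
    np.testing.assert_allclose(adj, [0.004, 0.02, 0.02 * 4 / 3, 0.8])
    assert (adj[:3] < 0.05).all() and adj[3] >= 0.05


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                max_size=50))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_bh_matches_bruteforce_oracle(pvals):
    np.testing.assert_allclose(bh_fdr(pvals), _bh_oracle(pvals), rtol=1e-12)


def test_bh_adjusted_monotone_in_rank(rng):
    p = rng.random(30)
    adj = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# ------------------------------------------------------------------- dedup

def _meta(tid, name, n):
    return TraitMeta(tid, name, n)


def test_dedup_keeps_largest_sample_size():
    kept = dedup_traits([(_meta("a", "LDL cholesterol", 10_000), 30.0),
                         (_meta("b", "ldl  Cholesterol", 50_000), 20.0)])
    assert [m.trait_id for m in kept] == ["b"]


def test_dedup_ties_break_by_f_then_id():
    kept = dedup_traits([(_meta("a", "CRP", 10_000), 30.0),
                         (_meta("b", "CRP", 10_000), 80.0)])
    assert [m.trait_id for m in kept] == ["b"]
    kept2 = dedup_traits([(_meta("b", "CRP", 10_000), 30.0),
                          (_meta("a", "CRP", 10_000), 30.0)])
    assert [m.trait_id for m in kept2] == ["a"]


def test_dedup_unique_names_identity():
    metas = [(_meta("a", "one", 1000), 1.0), (_meta("b", "two", 1000), 1.0)]
    assert {m.trait_id for m in dedup_traits(metas)} == {"a", "b"}


# ------------------------------------------------------------------ screen

def _screen_inputs(seed, theta=(0.3, 0.0, 0.0)):
    cfg = SimulationConfig(theta_true=list(theta),
                           exposure_corr=np.eye(len(theta)), seed=seed,
                           prop_palindromic=0.0, prop_strand_flipped=0.0)
    exps, outcome, ld, truth = simulate_multi_exposure(cfg)
    for k, e in enumerate(exps):
        e.meta = TraitMeta(f"trait-{k}", f"trait {k}", cfg.n_exposure)
    return exps, outcome, ld, truth


def test_screen_flags_planted_effect_and_not_nulls():
    exps, outcome, ld, _ = _screen_inputs(seed=42)
    records = run_screen(exps, outcome, ld, ScreenConfig(n_boot=200))
    by_id = {r.trait.trait_id: r for r in records}
    assert by_id["trait-0"].verdict == "significant"
    assert by_id["trait-1"].verdict in ("not_significant", "excluded")
    sig = by_id["trait-0"]
    assert sig.fdr_p < 0.05
    assert sig.robust["weighted_median"].pvalue < 0.05
    assert all(res.pvalue < 0.05 for _, res in sig.qc.loo)


def test_batch_exclusion():
    exps, outcome, ld, _ = _screen_inputs(seed=1)
    exps[0].meta = TraitMeta("trait-0", "trait 0", 50_000, "continuous", "ukb")
    records = run_screen(exps, outcome, ld, ScreenConfig(n_boot=50))
    by_id = {r.trait.trait_id: r for r in records}
    assert by_id["trait-0"].verdict == "excluded"
    assert by_id["trait-0"].exclusion_reason == "batch"
    # excluded traits do not enter the FDR family
    assert by_id["trait-0"].fdr_p is None


def test_verdicts_invariant_to_input_order():
    exps, outcome, ld, _ = _screen_inputs(seed=7)
    cfg = ScreenConfig(n_boot=100)
    fwd = run_screen(exps, outcome, ld, cfg)
    rev = run_screen(exps[::-1], outcome, ld, cfg)
    assert [(r.trait.trait_id, r.verdict) for r in fwd] == \
           [(r.trait.trait_id, r.verdict) for r in rev]
    assert [r.primary.estimate if r.primary else None for r in fwd] == \
           [r.primary.estimate if r.primary else None for r in rev]


def test_excluded_plus_analysed_equals_input():
    exps, outcome, ld, _ = _screen_inputs(seed=3)
    exps[2].meta = TraitMeta("trait-2", "trait 2", 50_000, "continuous", "met-d")
    records = run_screen(exps, outcome, ld, ScreenConfig(n_boot=50))
    excluded = sum(r.verdict == "excluded" for r in records)
    analysed = sum(r.primary is not None for r in records)
    assert excluded + analysed == len(exps)


def test_underpowered_trait_excluded_not_fatal():
    weak = make_summary([f"rs{i}" for i in range(5)], 0.01, 0.01,
                        [0.2, 0.3, 0.4, 0.5, 0.6], trait_id="weak")
    exps, outcome, ld, _ = _screen_inputs(seed=9)
    records = run_screen([weak] + exps, outcome, ld, ScreenConfig(n_boot=50))
    by_id = {r.trait.trait_id: r for r in records}
    assert by_id["weak"].verdict == "excluded"
    assert by_id["weak"].exclusion_reason == "insufficient_instruments"
    assert by_id["trait-0"].verdict == "significant"


def test_self_replication_reproduces_primary():
    exps, outcome, ld, _ = _screen_inputs(seed=11)
    cfg = ScreenConfig(n_boot=100)
    records = run_screen(exps, outcome, ld, cfg)
    sig = [r for r in records if r.verdict == "significant"]
    assert sig
    replicate(records, outcome, ld, cfg,
              exposures_by_id={e.meta.trait_id: e for e in exps})
    for r in sig:
        assert r.replication["ivw_mre"].estimate == pytest.approx(r.primary.estimate)
        assert r.verdict == "significant"  # replication never alters verdicts


def test_replicate_with_no_significant_records_is_noop():
    exps, outcome, ld, _ = _screen_inputs(seed=13, theta=(0.0, 0.0, 0.0))
    records = run_screen(exps, outcome, ld, ScreenConfig(n_boot=50))
    out = replicate(records, outcome, ld, ScreenConfig(n_boot=50),
                    exposures_by_id={e.meta.trait_id: e for e in exps})
    assert all(r.replication is None for r in out)


def test_reverse_mr_on_self_is_degenerate_unity():
    cfg = SimulationConfig(theta_true=0.3, seed=5, prop_palindromic=0.0,
                           prop_strand_flipped=0.0)
    exp, outcome, ld, _ = simulate_pair(cfg)
    res = reverse_mr(exp, exp, ld, ScreenConfig(apply_outcome_filter=False))
    assert res.estimate == pytest.approx(1.0, abs=1e-9)


def test_reverse_mr_attenuated_for_forward_causal_pair():
    from scipy import stats as sps
    from mrscreen.screen import analyse_pair

    fwd, rev = [], []
    for seed in range(6):
        r_ = np.random.default_rng(seed)
        # 50 exposure loci propagate to the outcome (theta = 0.4); 50 loci
        # affect only the outcome, giving the reverse direction instruments
        m, se, theta = 100, 0.0063, 0.4
        bx_true = np.r_[r_.normal(0, 0.05, 50), np.zeros(50)]
        by_true = theta * bx_true
        by_true[50:] = r_.normal(0, 0.05, 50)
        obs_x = bx_true + r_.normal(0, se, m)
        obs_y = by_true + r_.normal(0, se, m)
        p_x = np.clip(2 * sps.norm.sf(np.abs(obs_x) / se), 1e-300, 1)
        p_y = np.clip(2 * sps.norm.sf(np.abs(obs_y) / se), 1e-300, 1)
        ids = [f"rs{i}" for i in range(m)]
        exp = make_summary(ids, obs_x, se, p_x, trait_id="X")
        outcome = make_summary(ids, obs_y, se, p_y, trait_id="Y")
        scfg = ScreenConfig(n_boot=50)
        f = analyse_pair(exp, outcome, None, scfg)
        try:
            rv = reverse_mr(exp, outcome, None, scfg)
        except InsufficientInstrumentsError:
            continue
        fwd.append(abs(f.primary.estimate)); rev.append(abs(rv.estimate))
    assert rev and np.mean(rev) < 0.5 * np.mean(fwd)
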