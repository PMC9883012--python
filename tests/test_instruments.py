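"""Selection ladder, clumping, proxies, harmonisation and instrument filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrscreen.instruments import (align_alleles, clump, filter_outcome_significance,
                                  find_proxy, harmonise, radial_fit,
                                  radial_outlier_filter, select_instruments)
from mrscreen.summstats import COMPLEMENT, LDReference, SummaryStats, TraitMeta

from conftest import full_selection, make_hset, make_summary


# ---------------------------------------------------------------- selection

def test_ladder_stops_at_first_sufficient_rung():
    stats = make_summary([f"rs{i}" for i in range(10)],
                         beta=0.1, se=0.01, pvalue=[1e-9] * 10)
    sel = select_instruments(stats, ld=None)
    assert sel.threshold_used == 5e-8
    assert sel.n_selected == 10 and sel.sufficient
    assert sel.ladder_log == [(5e-8, 10)]


def test_ladder_relaxes_until_enough_instruments():
    pv = [1e-10] * 3 + [1e-6] * 4
    stats = make_summary([f"rs{i}" for i in range(7)], 0.1, 0.01, pv)
    sel = select_instruments(stats, ld=None)
    assert sel.threshold_used == 5e-6
    assert sel.n_selected == 7
    assert [t for t, _ in sel.ladder_log] == [5e-8, 5e-7, 5e-6]
    assert [c for _, c in sel.ladder_log] == [3, 3, 7]


def test_insufficient_selection_is_flagged_not_raised():
    stats = make_summary(["rs1", "rs2"], 0.1, 0.1, [0.3, 0.6])
    sel = select_instruments(stats, ld=None)
    assert not sel.sufficient and sel.n_selected == 0
    assert sel.threshold_used == 5e-5


# ---------------------------------------------------------------- clumping

def _ld_from_matrix(ids, r2):
    ld = LDReference({v: 0 for v in ids})
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if r2[i, j] > 0:
                ld.add_pair(ids[i], "A", ids[j], "A", r2[i, j])
    return ld


def test_clump_discards_correlated_higher_p_variant():
    ids = ["rs1", "rs2"]
    stats = make_summary(ids, 0.1, 0.01, [1e-10, 1e-8], pos=[100, 200])
    ld = _ld_from_matrix(ids, np.array([[1, 0.5], [0.5, 1]], float))
    assert clump(ids, stats, ld) == ["rs1"]
    ld2 = _ld_from_matrix(ids, np.array([[1, 0.0005], [0.0005, 1]], float))
    assert clump(ids, stats, ld2) == ["rs1", "rs2"]


def test_clump_respects_distance_window():
    ids = ["rs1", "rs2"]
    stats = make_summary(ids, 0.1, 0.01, [1e-10, 1e-8],
                         pos=[1, 20_000_000])  # 20 Mb apart > 10,000 kb window
    ld = _ld_from_matrix(ids, np.array([[1, 0.9], [0.9, 1]], float))
    assert clump(ids, stats, ld) == ["rs1", "rs2"]


def _clump_oracle(ids, pvals, pos, r2, r2_max=0.001, window=10_000_000):
    """Matrix-based greedy reference implementation."""
    order = sorted(range(len(ids)), key=lambda i: (pvals[i], ids[i]))
    alive = set(order)
    kept = []
    for i in order:
        if i not in alive:
            continue
        kept.append(ids[i])
        for j in list(alive):
            if j != i and abs(pos[j] - pos[i]) <= window and r2[i, j] > r2_max:
                alive.discard(j)
        alive.discard(i)
    return kept


def test_clump_matches_bruteforce_oracle_on_random_instances(rng):
    for _ in range(40):
        m = int(rng.integers(2, 31))
        ids = [f"rs{i}" for i in range(m)]
        pv = 10.0 ** rng.uniform(-12, -2, m)
        pos = np.sort(rng.integers(1, 40_000_000, m))
        r2 = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if rng.random() < 0.3:
                    r2[i, j] = r2[j, i] = rng.random()
        stats = make_summary(ids, 0.1, 0.01, pv, pos=pos)
        ld = _ld_from_matrix(ids, r2)
        got = clump(ids, stats, ld)
        assert got == _clump_oracle(ids, pv, pos, r2)
        # retained set is pairwise below threshold within the window
        for a, b in itertools.combinations(got, 2):
            ia, ib = ids.index(a), ids.index(b)
            if abs(pos[ia] - pos[ib]) <= 10_000_000:
                assert r2[ia, ib] <= 0.001


# ---------------------------------------------------------------- proxies

def test_proxy_picks_highest_r2_above_threshold():
    out = make_summary(["rsA", "rsB"], 0.05, 0.01, [1e-4, 1e-5])
    ld = LDReference({"rsX": 0, "rsA": 0, "rsB": 0})
    ld.add_pair("rsX", "A", "rsA", "A", 0.91)
    ld.add_pair("rsX", "A", "rsB", "G", 0.99)
    pid, r2, phase = find_proxy("rsX", out, ld)
    assert (pid, r2) == ("rsB", 0.99)
    assert phase == ("A", "G")


def test_proxy_below_threshold_returns_none():
    out = make_summary(["rsA"], 0.05, 0.01, [1e-4])
    ld = LDReference({"rsX": 0, "rsA": 0})
    ld.add_pair("rsX", "A", "rsA", "A", 0.85)
    assert find_proxy("rsX", out, ld) is None


def test_proxy_tie_breaks_by_outcome_pvalue_then_id():
    out = make_summary(["rsB", "rsA"], 0.05, 0.01, [1e-8, 1e-8])
    ld = LDReference({"rsX": 0, "rsA": 0, "rsB": 0})
    ld.add_pair("rsX", "A", "rsA", "A", 0.95)
    ld.add_pair("rsX", "A", "rsB", "A", 0.95)
    pid, _, _ = find_proxy("rsX", out, ld)
    assert pid == "rsA"


def test_harmonise_substitutes_proxy_with_phase():
    exp = make_summary(["rsX"], beta=[0.1], se=[0.01], pvalue=[1e-10],
                       ea=["A"], oa=["G"])
    # proxy rsP in outcome: its C allele tracks rsX's A allele
    out = make_summary(["rsP"], beta=[0.04], se=[0.01], pvalue=[1e-3],
                       ea=["T"], oa=["C"], eaf=[0.7])
    ld = LDReference({"rsX": 0, "rsP": 0})
    ld.add_pair("rsX", "A", "rsP", "C", 0.95)
    h = harmonise(exp, out, full_selection(exp), ld)
    assert len(h) == 1
    assert h.table.loc[0, "proxy_id"] == "rsP"
    # outcome beta was per T copy; the tracking allele is C, so sign flips
    assert h.table.loc[0, "b_y"] == pytest.approx(-0.04)


# ------------------------------------------------------------ harmonisation

def test_swapped_alleles_flip_outcome_beta():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["G"])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["G"], oa=["A"],
                       eaf=[0.7])
    h = harmonise(exp, out, full_selection(exp))
    assert h.table.loc[0, "b_y"] == pytest.approx(-0.05)
    assert h.table.loc[0, "eaf_y"] == pytest.approx(0.3)


def test_strand_complement_keeps_sign():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["G"])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["T"], oa=["C"],
                       eaf=[0.3])
    h = harmonise(exp, out, full_selection(exp))
    assert h.table.loc[0, "b_y"] == pytest.approx(0.05)


def test_ambiguous_palindrome_is_dropped():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["T"],
                       eaf=[0.50])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["A"], oa=["T"],
                       eaf=[0.50])
    h = harmonise(exp, out, full_selection(exp))
    assert len(h) == 0
    assert h.log[0]["reason"] == "palindromic_ambiguous"


def test_palindrome_outside_ambiguity_zone_is_frequency_aligned():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["T"],
                       eaf=[0.2])
    same = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["T"], oa=["A"],
                        eaf=[0.25])  # same side of 0.5 -> same allele
    h = harmonise(exp, same, full_selection(exp))
    assert h.table.loc[0, "b_y"] == pytest.approx(0.05)
    other = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["A"], oa=["T"],
                         eaf=[0.8])  # opposite side -> flip
    h2 = harmonise(exp, other, full_selection(exp))
    assert h2.table.loc[0, "b_y"] == pytest.approx(-0.05)


def test_palindrome_missing_eaf_is_dropped():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["G"], oa=["C"],
                       eaf=[np.nan])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["G"], oa=["C"],
                       eaf=[0.2])
    h = harmonise(exp, out, full_selection(exp))
    assert len(h) == 0 and h.log[0]["reason"] == "palindromic_missing_eaf"


def test_irreconcilable_alleles_dropped():
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["G"])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["A"], oa=["C"])
    h = harmonise(exp, out, full_selection(exp))
    assert len(h) == 0 and h.log[0]["reason"] == "irreconcilable_alleles"


def test_align_alleles_exhaustive_over_configurations():
    """Every outcome re-encoding of every valid exposure pair resolves to the
    action that preserves effect direction (or drops when irresolvable)."""
    bases = "ACGT"
    for ea_x, oa_x in itertools.permutations(bases, 2):
        pal = COMPLEMENT[ea_x] == oa_x
        encodings = {
            "direct": (ea_x, oa_x, "keep"),
            "swapped": (oa_x, ea_x, "flip"),
            "complement": (COMPLEMENT[ea_x], COMPLEMENT[oa_x], "keep"),
            "complement_swapped": (COMPLEMENT[oa_x], COMPLEMENT[ea_x], "flip"),
        }
        for name, (ea_y, oa_y, expect) in encodings.items():
            action, _ = align_alleles(ea_x, oa_x, ea_y, oa_y, 0.2, 0.2,
                                      palindrome_maf=0.42)
            if pal:
                # frequency on the same side of 0.5 always means "keep"
                assert action == "keep"
                action2, _ = align_alleles(ea_x, oa_x, ea_y, oa_y, 0.2, 0.8)
                assert action2 == "flip"
                action3, reason = align_alleles(ea_x, oa_x, ea_y, oa_y, 0.5, 0.5)
                assert action3 == "drop" and reason == "palindromic_ambiguous"
            else:
                assert action == expect, (ea_x, oa_x, name)


def test_harmonisation_is_idempotent():
    cfgd = dict(beta=[0.1, -0.2], se=[0.01, 0.02], pvalue=[1e-10, 1e-9])
    exp = make_summary(["rs1", "rs2"], ea=["A", "C"], oa=["G", "T"],
                       eaf=[0.3, 0.6], **cfgd)
    out = make_summary(["rs1", "rs2"], beta=[0.05, 0.04], se=[0.01, 0.01],
                       pvalue=[1e-3, 1e-2], ea=["G", "C"], oa=["A", "T"],
                       eaf=[0.7, 0.6])
    h1 = harmonise(exp, out, full_selection(exp))
    # feed the harmonised outcome back through as an already-aligned dataset
    realigned = make_summary(h1.ids, beta=list(h1.b_y), se=list(h1.se_y),
                             pvalue=list(h1.p_y),
                             ea=list(h1.table["effect_allele"]),
                             oa=list(h1.table["other_allele"]),
                             eaf=list(h1.eaf_y))
    h2 = harmonise(exp, realigned, full_selection(exp))
    np.testing.assert_allclose(h1.b_y, h2.b_y)
    np.testing.assert_allclose(h1.b_x, h2.b_x)


def test_allele_flip_equivariance():
    """Flipping EA/OA and the beta sign of an exposure row yields the same
    harmonised set up to the row's sign convention."""
    exp = make_summary(["rs1"], [0.1], [0.01], [1e-10], ea=["A"], oa=["G"],
                       eaf=[0.3])
    out = make_summary(["rs1"], [0.05], [0.01], [1e-4], ea=["A"], oa=["G"],
                       eaf=[0.3])
    flipped_exp = make_summary(["rs1"], [-0.1], [0.01], [1e-10], ea=["G"],
                               oa=["A"], eaf=[0.7])
    h = harmonise(exp, out, full_selection(exp))
    hf = harmonise(flipped_exp, out, full_selection(flipped_exp))
    # ratio estimates (the estimand) are identical
    assert h.b_y[0] / h.b_x[0] == pytest.approx(hf.b_y[0] / hf.b_x[0])
    assert hf.b_x[0] == pytest.approx(-h.b_x[0])
    assert hf.b_y[0] == pytest.approx(-h.b_y[0])


# ------------------------------------------------------------------ filters

def test_outcome_significance_filter_removes_and_is_idempotent():
    h = make_hset(b_x=[0.1, 0.1], se_x=[0.01, 0.01],
                  b_y=[0.3, 0.01], se_y=[0.01, 0.01],
                  p_x=[1e-9, 1e-9], p_y=[1e-12, 0.3])
    f1 = filter_outcome_significance(h)
    assert f1.ids == ["rs2"]
    f2 = filter_outcome_significance(f1)
    assert f2.ids == f1.ids and len(f2) <= len(h)


def test_radial_homogeneous_set_has_zero_q_and_no_removals():
    b_x = np.array([0.1, 0.2, 0.05, 0.15])
    h = make_hset(b_x, 0.01 * np.ones(4), 0.5 * b_x, 0.01 * np.ones(4))
    theta, _, q_j = radial_fit(h.b_x, h.se_x, h.b_y, h.se_y)
    assert theta == pytest.approx(0.5)
    np.testing.assert_allclose(q_j, 0.0, atol=1e-20)
    filtered, removed = radial_outlier_filter(h)
    assert removed == [] and len(filtered) == 4


def test_radial_planted_outlier_carries_max_q_and_is_removed(rng):
    j = 20
    b_x = rng.normal(0.08, 0.02, j)
    se_y = np.full(j, 0.004)
    b_y = 0.3 * b_x + rng.normal(0, se_y)
    b_y[7] += 10 * se_y[7]  # 10-SD outlying ratio
    h = make_hset(b_x, np.full(j, 0.005), b_y, se_y)
    _, _, q_j = radial_fit(h.b_x, h.se_x, h.b_y, h.se_y)
    assert np.argmax(q_j) == 7
    filtered, removed = radial_outlier_filter(h)
    assert "rs8" in removed
    # total Q decomposes into per-variant contributions by construction
    theta, _, q_full = radial_fit(h.b_x, h.se_x, h.b_y, h.se_y)
    w = h.b_x ** 2 / (h.se_y ** 2 + theta ** 2 * h.se_x ** 2)
    total = np.sum(w * (h.b_y / h.b_x - theta) ** 2)
    assert total == pytest.approx(np.sum(q_full))


def test_radial_filter_skips_small_sets():
    h = make_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.2], [0.01, 0.01])
    filtered, removed = radial_outlier_filter(h)
    assert len(filtered) == 2 and removed == []


def test_reverse_causal_instruments_are_filtered(rng):
    """Variants whose primary effect is on the outcome associate more
    strongly with it and are caught by the significance comparison."""
    removed = total = 0
    n_rep = 50
    for rep in range(n_rep):
        r = np.random.default_rng(rep)
        se = 0.006
        # reverse contamination comes from genuine outcome loci: draw effects
        # at clearly detectable magnitude with random sign
        b_out = r.uniform(0.04, 0.12, 5) * r.choice([-1, 1], 5)
        b_exp = 0.3 * b_out                     # leak back to the exposure
        obs_x = b_exp + r.normal(0, se, 5)
        obs_y = b_out + r.normal(0, se, 5)
        p_x = 2 * sps.norm.sf(np.abs(obs_x) / se)
        p_y = 2 * sps.norm.sf(np.abs(obs_y) / se)
        h = make_hset(obs_x, np.full(5, se), obs_y, np.full(5, se),
                      p_x=np.clip(p_x, 1e-300, 1), p_y=np.clip(p_y, 1e-300, 1))
        kept = filter_outcome_significance(h)
        removed += 5 - len(kept)
        total += 5
    assert removed / total >= 0.95
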