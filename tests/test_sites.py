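"""Seed-site enumeration and duplex-energy DP against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cernet.sites import (DEFAULT_ENERGY_MODEL, InvalidAlphabetError,
                          MiRNASite, SITE_CLASSES, duplex_energy,
                          find_seed_sites, rank_sponged_mirnas, revcomp,
                          seed_pattern, annotate_site_energies, SpongedMiRNA)
from conftest import random_rna

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# independent brute-force site scanner
# ---------------------------------------------------------------------------

def _matches_at(mirna, target, pos, cls):
    """Per-base complement check of one class definition at one offset."""
    if cls in ("8mer", "7mer-m8"):
        seed = mirna[1:8]
    else:
        seed = mirna[1:7]
    need_a = cls in ("8mer", "7mer-A1")
    length = len(seed) + (1 if need_a else 0)
    if pos + length > len(target):
        return False
    # seed pairs the target antiparallel: target[pos + k] must complement
    # seed base len(seed)-1-k
    for k in range(len(seed)):
        if target[pos + k] != _COMP[seed[len(seed) - 1 - k]]:
            return False
    if need_a and target[pos + len(seed)] != "A":
        return False
    return True


def brute_force_sites(mirna, target):
    raw = []
    for pos in range(len(target)):
        for cls in SITE_CLASSES:  # best class first
            if _matches_at(mirna, target, pos, cls):
                length = 8 if cls == "8mer" else 6 if cls == "6mer" else 7
                raw.append((pos, pos + length, SITE_CLASSES.index(cls)))
                break
    kept = []
    for s, e, r in raw:
        if not any(r2 < r and s2 <= s and e2 >= e
                   for s2, e2, r2 in raw if (s2, e2, r2) != (s, e, r)):
            kept.append((s, e, SITE_CLASSES[r]))
    return kept


def test_constructed_8mer_found_at_known_offset():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    site = seed_pattern(mirna, "8mer")
    target = "C" * 20 + site + "C" * 20
    found = [s for s in find_seed_sites(mirna, target) if s.site_class == "8mer"]
    assert [(s.start, s.end) for s in found] == [(20, 28)]
    # the reported subsequence re-validates against its class definition
    assert target[20:28] == seed_pattern(mirna, "8mer")


def test_poly_a_target_with_gc_seed_is_empty():
    assert find_seed_sites("UGCGGUAGUAGGUUGUAUAGUU", "A" * 100) == []


def test_each_start_reported_once_under_highest_class():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    target = "G" * 5 + seed_pattern(mirna, "8mer") + "G" * 5
    found = find_seed_sites(mirna, target)
    assert len(found) == 1 and found[0].site_class == "8mer"


def test_brute_force_oracle_on_random_targets(rng):
    """Site lists identical to the per-offset brute-force scanner."""
    for _ in range(40):
        mirna = random_rna(rng, 22)
        target = random_rna(rng, 1000)
        got = [(s.start, s.end, s.site_class)
               for s in find_seed_sites(mirna, target)]
        assert got == brute_force_sites(mirna, target)


def test_invalid_alphabet_lists_offenders():
    with pytest.raises(InvalidAlphabetError, match="T"):
        find_seed_sites("UGAGGUAGUAGGUUGUAUAGUU", "ACGT")


def test_site_span_class_consistency():
    with pytest.raises(ValueError):
        MiRNASite("m", "t", 0, 7, "8mer")


# ---------------------------------------------------------------------------
# duplex energy: hand-summed and exhaustive oracles
# ---------------------------------------------------------------------------

def _oracle_pairings(x, y):
    """All non-crossing antiparallel pairings (i ascending, j descending)."""
    valid = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
             ("G", "U"), ("U", "G")}
    out = []

    def rec(i_min, j_max, cur):
        out.append(list(cur))
        for i in range(i_min, len(x)):
            for j in range(j_max, -1, -1):
                if (x[i], y[j]) in valid:
                    cur.append((i, j))
                    rec(i + 1, j - 1, cur)
                    cur.pop()

    rec(0, len(y) - 1, [])
    return out


def _oracle_score(pairs, x, y, model):
    if not pairs:
        return 0.0
    e = model.end_penalty(x[pairs[0][0]], y[pairs[0][1]])
    e += model.end_penalty(x[pairs[-1][0]], y[pairs[-1][1]])
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        gx, gy = i2 - i1 - 1, j1 - j2 - 1
        if gx == 0 and gy == 0:
            e += model.stack_energy(x[i1], y[j1], x[i2], y[j2])
        else:
            if gx > model.max_loop or gy > model.max_loop:
                return None
            e += model.loop_open + model.loop_extend * (gx + gy)
    return e


def exhaustive_duplex_energy(x, y, model=DEFAULT_ENERGY_MODEL):
    best = 0.0
    for pairs in _oracle_pairings(x, y):
        s = _oracle_score(pairs, x, y, model)
        if s is not None and s < best:
            best = s
    return best


def test_fully_complementary_equals_hand_summation():
    """A perfect 10-mer duplex scores the sum of its 9 stacks plus the two
    terminal penalties, summed by hand over the model table."""
    m = DEFAULT_ENERGY_MODEL
    x = "GGCAUCCGAU"
    y = revcomp(x)
    expected = m.end_penalty(x[0], y[-1]) + m.end_penalty(x[-1], y[0])
    for i in range(9):
        expected += m.stack_energy(x[i], y[-1 - i], x[i + 1], y[-2 - i])
    assert duplex_energy(x, y) == pytest.approx(expected, abs=1e-9)


def test_no_complementarity_gives_zero():
    assert duplex_energy("AAAA", "AAAA") == 0.0
    assert duplex_energy("CCCC", "CCCC") == 0.0


def test_exhaustive_oracle_short_sequences(rng):
    """DP equals exhaustive enumeration over all non-crossing pairings for
    1000 random pairs of length <= 6."""
    for _ in range(1000):
        x = random_rna(rng, int(rng.integers(1, 7)))
        y = random_rna(rng, int(rng.integers(1, 7)))
        assert duplex_energy(x, y) == pytest.approx(
            exhaustive_duplex_energy(x, y), abs=1e-9)


def test_window_limit_enforced():
    with pytest.raises(ValueError, match="window"):
        duplex_energy("ACGU", "A" * 41)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_monotone_under_complementary_extension(seed):
    """Appending a complementary base pair never raises the optimum."""
    r = np.random.default_rng(seed)
    x = random_rna(r, int(r.integers(3, 15)))
    y = random_rna(r, int(r.integers(3, 15)))
    base = duplex_energy(x, y)
    b = "ACGU"[int(r.integers(0, 4))]
    assert duplex_energy(x + b, _COMP[b] + y) <= base + 1e-9


# ---------------------------------------------------------------------------
# sponge ranking
# ---------------------------------------------------------------------------

def _fake_sites(mirna_id, lnc_id, n, energy):
    return [MiRNASite(mirna_id, lnc_id, 10 * i, 10 * i + 7, "7mer-m8", energy)
            for i in range(n)]


def test_rank_sponged_filters(default_cohort):
    matrix, truth = default_cohort
    lnc, mi, _ = truth.planted_triplets[0]
    pos_mi = "MIR0030"  # unplanted: independent noise, not anticorrelated
    sites = {mi: _fake_sites(mi, lnc, 3, -15.0),
             pos_mi: _fake_sites(pos_mi, lnc, 5, -20.0)}
    out = rank_sponged_mirnas(lnc, [mi, pos_mi], matrix, sites)
    assert [s.mirna_id for s in out] == [mi]
    # positively/un-correlated miRNA excluded regardless of sites
    assert pos_mi not in {s.mirna_id for s in out}


def test_rank_sponged_top_k_zero(default_cohort):
    matrix, truth = default_cohort
    lnc, mi, _ = truth.planted_triplets[0]
    assert rank_sponged_mirnas(lnc, [mi], matrix, {}, top_k=0) == []


def test_rank_sponged_min_sites_and_energy(default_cohort):
    matrix, truth = default_cohort
    lnc, mi, _ = truth.planted_triplets[0]
    # one site only -> excluded
    assert rank_sponged_mirnas(lnc, [mi], matrix,
                               {mi: _fake_sites(mi, lnc, 1, -15.0)}) == []
    # weak energy -> excluded
    assert rank_sponged_mirnas(lnc, [mi], matrix,
                               {mi: _fake_sites(mi, lnc, 3, -1.0)}) == []


def test_annotate_site_energies_strongly_negative_on_planted(default_sequences,
                                                             default_cohort):
    matrix, truth = default_cohort
    mirnas, lnc_seqs, _ = default_sequences
    lnc, mi, _ = truth.planted_triplets[0]
    sites = find_seed_sites(mirnas[mi], lnc_seqs[lnc], mi, lnc)
    ann = annotate_site_energies(sites, mirnas[mi], lnc_seqs[lnc])
    implanted = set(truth.site_positions[(mi, lnc)])
    hit = [s for s in ann if s.start in implanted]
    assert len(hit) == len(implanted)
    assert all(s.duplex_energy < -5 for s in hit)
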