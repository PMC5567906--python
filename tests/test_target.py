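"""Duplex alignment, the six-rule filter, energy ratio, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protomir._seq import random_seq, revcomp
from protomir.target import (WEIGHTS, DuplexAlignment, apply_rules,
                             duplex_align, duplex_energy, evaluate_hit,
                             predict_targets)
from protomir.thermo import get_engine

ENGINE = get_engine()
MIRNA = "TGGAGCTCCCTTCATTCCGAT"  # 21 nt, with a G in the 3' half


def _aln(classes):
    return DuplexAlignment(
        mirna="A" * len(classes), mirna_name="m", transcript_id="t",
        window_start=0, window_end=len(classes),
        target_window="T" * len(classes), classes=classes)


def _embed(site, flank=40, seed=0):
    rng = np.random.default_rng(seed)
    return random_seq(rng, flank) + site + random_seq(rng, flank)


def oracle_align(mirna, transcript, max_score=4.0):
    """Exhaustive window-by-window scoring, fully independent of the
    implementation's shortcuts: returns {(start, end): best_score}."""
    wc = {"AT", "TA", "GC", "CG"}
    gu = {"GT", "TG"}

    def klass(m, t):
        p = m + t
        return "W" if p in wc else ("G" if p in gu else "M")

    L = len(mirna)
    bulge_ok = [b for b in range(1, L) if not (2 <= b <= 12)]
    results = {}
    for s in range(len(transcript) - L + 1):  # ungapped
        w = transcript[s : s + L]
        sc = sum(WEIGHTS[klass(mirna[i], w[L - 1 - i])] for i in range(L))
        if sc <= max_score:
            results[(s, s + L)] = min(results.get((s, s + L), 99), sc)
    for b in bulge_ok:  # miRNA-side bulge, window one shorter
        if b < 2:
            continue
        for s in range(len(transcript) - (L - 1) + 1):
            w = transcript[s : s + L - 1]
            sc = 1.0
            for i in range(1, L + 1):
                if i == b:
                    continue
                widx = (L - 1 - i) if i < b else (L - i)
                sc += WEIGHTS[klass(mirna[i - 1], w[widx])]
                if sc > max_score:
                    break
            if sc <= max_score:
                key = (s, s + L - 1)
                results[key] = min(results.get(key, 99), sc)
    for b in bulge_ok:  # target-side bulge, window one longer
        for s in range(len(transcript) - (L + 1) + 1):
            w = transcript[s : s + L + 1]
            sc = 1.0
            for i in range(1, L + 1):
                if i == b:
                    continue
                widx = (L + 1 - i) if i < b else (L - i)
                sc += WEIGHTS[klass(mirna[i - 1], w[widx])]
                if sc > max_score:
                    break
            if sc <= max_score:
                key = (s, s + L + 1)
                results[key] = min(results.get(key, 99), sc)
    return results


class TestDuplexAlign:
    def test_perfect_complement_is_all_wc(self):
        tx = _embed(revcomp(MIRNA))
        hits = duplex_align(MIRNA, tx)
        exact = [h for h in hits if h.window_start == 40 and h.bulge is None]
        assert len(exact) == 1
        assert exact[0].classes == "W" * 21
        assert exact[0].mismatch_score == 0

    def test_single_gu_scores_half(self):
        site = revcomp(MIRNA)
        # miRNA position 15 (1-based) is G -> target C at site index L-15
        i = next(i for i in range(13, 20) if MIRNA[i] == "G")
        sidx = len(MIRNA) - 1 - i
        site = site[:sidx] + "T" + site[sidx + 1:]
        hits = duplex_align(MIRNA, _embed(site))
        exact = [h for h in hits if h.window_start == 40 and h.bulge is None]
        assert exact[0].mismatch_score == 0.5
        assert exact[0].classes.count("G") == 1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        mirna = random_seq(rng, 21)
        tx = random_seq(rng, 1000) + revcomp(mirna) + random_seq(rng, 200)
        got = {(h.window_start, h.window_end): h.mismatch_score
               for h in duplex_align(mirna, tx)}
        assert got == oracle_align(mirna, tx)

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            duplex_align("ACGTNACGTACGTACGTACGT", "ACGT" * 30)


class TestRules:
    def test_all_wc_passes_positional_rules(self):
        assert apply_rules(_aln("W" * 21))[:5] == [True] * 5

    def test_mismatch_at_position_ten_fails_rule_four(self):
        cls = "W" * 9 + "M" + "W" * 11
        flags = apply_rules(_aln(cls))
        assert flags[3] is False

    def test_adjacent_gu_in_seed_fails_rule_three(self):
        cls = "WWGG" + "W" * 17  # G.U wobbles at positions 3 and 4
        flags = apply_rules(_aln(cls))
        assert flags[2] is False
        # but their combined weight (1.0) keeps the score rules alive
        assert flags[0] is True and flags[4] is True

    def test_gu_not_event_when_switched_off(self):
        cls = "WWGG" + "W" * 17
        flags = apply_rules(_aln(cls), gu_is_mismatch_event=False)
        assert flags[2] is True

    def test_long_mismatch_run_fails_rule_two(self):
        cls = "W" * 13 + "MMM" + "W" * 5
        assert apply_rules(_aln(cls))[1] is False

    def test_seed_score_rule_five(self):
        cls = "MMM" + "W" * 18          # 3.0 in positions 1-12
        assert apply_rules(_aln(cls))[4] is False
        cls = "MM" + "W" * 19           # 2.0 in positions 1-12
        assert apply_rules(_aln(cls))[4] is True

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("WGMB"), min_size=18, max_size=24),
           st.integers(0, 23))
    def test_improving_a_position_is_monotone(self, classes, pos):
        """Upgrading any position (M/B -> G -> W) never turns a passing
        rule into a failing one."""
        pos = pos % len(classes)
        before = apply_rules(_aln("".join(classes)))
        order = {"B": "G", "M": "G", "G": "W", "W": "W"}
        classes[pos] = order[classes[pos]]
        after = apply_rules(_aln("".join(classes)))
        for b, a in zip(before[:5], after[:5]):
            assert not (b and not a)


class TestEnergy:
    def test_perfect_complement_ratio_one(self):
        d, perfect, ratio = duplex_energy(MIRNA, revcomp(MIRNA), ENGINE)
        assert ratio == pytest.approx(1.0)
        assert d < 0 and perfect < 0

    def test_unpaired_window_ratio_zero(self):
        _, _, ratio = duplex_energy("G" * 21, "G" * 21, ENGINE)
        assert ratio == 0.0

    def test_trimmed_duplex_keeps_most_energy(self):
        # losing only terminal pairs leaves the ratio high
        site = revcomp(MIRNA)
        trimmed = "AA" + site[2:-2] + "AA"
        _, _, r_full = duplex_energy(MIRNA, site, ENGINE)
        _, _, r_trim = duplex_energy(MIRNA, trimmed, ENGINE)
        assert r_trim < r_full == pytest.approx(1.0)
        assert r_trim > 0.5


class TestPrediction:
    def test_planted_sites_all_recovered(self, bundle):
        mirnas = {name: next(m.sequence for m in bundle.mirnas if m.name == name)
                  for name, _, _ in bundle.target_truth}
        hits, _ = predict_targets(mirnas, bundle.transcripts, ENGINE)
        found = {(h.alignment.mirna_name, h.alignment.transcript_id,
                  h.alignment.window_start) for h in hits}
        for key in bundle.target_truth:
            assert tuple(key) in found

    def test_scrambled_mirna_loses_its_site(self, bundle):
        name, tid, _ = bundle.target_truth[0]
        seq = next(m.sequence for m in bundle.mirnas if m.name == name)
        rng = np.random.default_rng(4)
        scrambled = "".join(rng.permutation(list(seq)))
        hits, targetless = predict_targets(
            {"scr": scrambled}, {tid: bundle.transcripts[tid]}, ENGINE)
        assert hits == [] and targetless == ["scr"]

    def test_no_antisense_similarity_empty(self):
        hits, targetless = predict_targets(
            {"m": "A" * 21}, {"t": "A" * 200}, ENGINE)
        assert hits == [] and targetless == ["m"]

    def test_accepted_hits_pass_all_six_rules(self, bundle):
        name, tid, _ = bundle.target_truth[0]
        seq = next(m.sequence for m in bundle.mirnas if m.name == name)
        hits, _ = predict_targets({name: seq}, {tid: bundle.transcripts[tid]},
                                  ENGINE)
        assert hits
        for h in hits:
            assert all(h.rule_flags)
            assert h.mfe_ratio >= 0.75

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            predict_targets({}, {"t": "ACGT" * 10})
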