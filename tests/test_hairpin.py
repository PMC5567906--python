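"""Hairpin excision, plant-miRNA criteria, novel catalog naming."""

import numpy as np
import pytest

from protomir._seq import random_seq, revcomp
from protomir.annotate import Locus
from protomir.hairpin import (HairpinCandidate, HairpinThresholds,
                              PrecursorWindow, Rejection, evaluate_hairpin,
                              excise_candidates, name_novel)
from protomir.thermo import get_engine

ENGINE = get_engine()


def _window(seq, start=0, strand="+"):
    return PrecursorWindow("chr1", start, start + len(seq), strand, seq)


def _planted(bundle, name):
    return next(m for m in bundle.mirnas if m.name == name)


class TestExcision:
    def test_window_arithmetic(self):
        genome = "A" * 2000
        wins = excise_candidates(Locus("chr1", 500, 522, "+"), genome, flank=150)
        assert (wins[0].start, wins[0].end) == (350, 672)

    def test_clipping_at_contig_start(self):
        genome = "A" * 2000
        wins = excise_candidates(Locus("chr1", 10, 32, "+"), genome, flank=150)
        assert wins[0].start == 0 and wins[0].end == 182

    def test_minus_strand_is_transcribed_orientation(self):
        rng = np.random.default_rng(2)
        genome = random_seq(rng, 1000)
        wins = excise_candidates(Locus("chr1", 400, 422, "-"), genome, flank=50)
        assert wins[0].sequence == revcomp(genome[350:472])

    def test_out_of_bounds_locus_raises(self):
        with pytest.raises(IndexError):
            excise_candidates(Locus("chr1", 1990, 2012, "+"), "A" * 2000)

    def test_planted_precursor_contained_in_a_window(self, bundle):
        m = _planted(bundle, "planted_novel_01")
        gstart = bundle.genome.find(m.precursor)
        rc = gstart == -1
        if rc:
            gstart = bundle.genome.find(revcomp(m.precursor))
        # read locus = mature position within the genome
        mat = m.sequence if m.locus.strand == "+" else revcomp(m.sequence)
        pos = bundle.genome.find(mat, m.locus.start, m.locus.end)
        wins = excise_candidates(
            Locus("chr1", pos, pos + len(m.sequence), m.locus.strand),
            bundle.genome)
        assert any(w.start <= gstart and w.end >= gstart + len(m.precursor)
                   for w in wins)


class TestCriteria:
    def _perfect_window(self, rng, mature=None):
        mature = mature or random_seq(rng, 21)
        stem = random_seq(rng, 8) + mature + random_seq(rng, 8)
        precursor = stem + random_seq(rng, 10) + revcomp(stem)
        pad5, pad3 = random_seq(rng, 30), random_seq(rng, 30)
        return _window(pad5 + precursor + pad3), mature

    def test_planted_hairpin_accepted(self):
        rng = np.random.default_rng(21)
        window, mature = self._perfect_window(rng)
        res = evaluate_hairpin(window, {mature: {"calli": 6}}, ENGINE)
        assert isinstance(res, HairpinCandidate)
        assert res.duplex_mismatches <= 4
        assert res.mfe <= -18
        assert res.arm in {"5p", "3p"}
        assert res.mature == mature
        assert res.mature in res.precursor

    def test_loop_spanning_read_rejected_as_arm_failure(self):
        rng = np.random.default_rng(22)
        mature = random_seq(rng, 21)
        stem = random_seq(rng, 2) + mature + random_seq(rng, 2)
        precursor = stem + "ACAACA" + revcomp(stem)
        # a read centered on the terminal loop
        mid = len(precursor) // 2
        loop_read = precursor[mid - 10 : mid + 10]
        res = evaluate_hairpin(_window(precursor), {loop_read: {"calli": 9}},
                               ENGINE)
        assert isinstance(res, Rejection) and res.reason == "arm"

    def test_low_read_support_rejected_last(self):
        rng = np.random.default_rng(23)
        window, mature = self._perfect_window(rng)
        res = evaluate_hairpin(window, {mature: {"calli": 2}}, ENGINE)
        assert isinstance(res, Rejection) and res.reason == "reads"

    def test_weak_fold_rejected_by_mfe(self):
        rng = np.random.default_rng(24)
        window, mature = self._perfect_window(rng)
        th = HairpinThresholds(mfe_max=-1000.0)
        res = evaluate_hairpin(window, {mature: {"calli": 9}}, ENGINE, th)
        assert isinstance(res, Rejection) and res.reason == "mfe"

    def test_acceptance_monotone_in_mfe(self):
        """Deepening the fold energy can never flip accept to reject."""
        rng = np.random.default_rng(25)
        window, mature = self._perfect_window(rng)

        class ShiftedEngine:
            def __init__(self, shift):
                self.shift = shift

            def fold(self, seq):
                s, e = ENGINE.fold(seq)
                return s, e + self.shift

        base = evaluate_hairpin(window, {mature: {"calli": 9}}, ENGINE)
        assert isinstance(base, HairpinCandidate)
        for shift in (-5.0, -20.0, -100.0):
            res = evaluate_hairpin(window, {mature: {"calli": 9}},
                                   ShiftedEngine(shift))
            assert isinstance(res, HairpinCandidate)

    def test_mature_length_bounds(self):
        rng = np.random.default_rng(26)
        window, mature = self._perfect_window(rng, mature=random_seq(rng, 28))
        th = HairpinThresholds(max_duplex_mismatch=28)
        res = evaluate_hairpin(window, {mature: {"calli": 9}}, ENGINE, th)
        assert isinstance(res, Rejection) and res.reason == "length"

    def test_decoy_windows_rarely_accepted(self, bundle):
        """Shuffled-genome windows with a planted abundant read stay
        below a 5% false-positive budget."""
        rng = np.random.default_rng(27)
        shuffled = "".join(
            rng.permutation(list(bundle.genome[:40_000])))
        accepted = 0
        n_decoys = 60
        for _ in range(n_decoys):
            start = int(rng.integers(0, len(shuffled) - 340))
            wseq = shuffled[start : start + 340]
            r0 = int(rng.integers(150, 170))
            read = wseq[r0 : r0 + 21]
            res = evaluate_hairpin(_window(wseq), {read: {"calli": 50}},
                                   ENGINE)
            accepted += isinstance(res, HairpinCandidate)
        assert accepted <= 0.05 * n_decoys


class TestNaming:
    def _cand(self, mature, start):
        locus = Locus("chr1", start, start + 80, "+")
        return HairpinCandidate(
            locus=locus, precursor="N", structure=".", mfe=-30.0,
            mature=mature, mature_interval=(0, len(mature)),
            star_interval=(40, 61), arm="5p", counts={"calli": 9},
            duplex_mismatches=0)

    def test_dedup_by_mature_collects_loci(self):
        cat = name_novel([self._cand("ACGT" * 5, 100),
                          self._cand("ACGT" * 5, 900)])
        assert len(cat) == 1
        assert len(cat[0].loci) == 2
        assert cat[0].name == "novel_mir_1"

    def test_stable_order_by_locus(self):
        cat = name_novel([self._cand("TTTT" * 5, 900),
                          self._cand("ACGT" * 5, 100)])
        assert [c.name for c in cat] == ["novel_mir_1", "novel_mir_2"]
        assert cat[0].locus.start == 100

    def test_empty(self):
        assert name_novel([]) == []


class TestRoundTrip:
    def test_planted_novel_recovered(self, pipeline_run):
        s = pipeline_run
        planted = {m.sequence for m in s.bundle.mirnas if not m.known}
        found = {c.mature for c in s.novel_catalog}
        recall = len(planted & found) / len(planted)
        assert recall >= 0.9

    def test_no_known_matures_in_novel_catalog(self, pipeline_run):
        known = set(pipeline_run.bundle.mature_mirnas.values())
        assert not ({c.mature for c in pipeline_run.novel_catalog} & known)

    def test_accepted_matures_lie_in_their_precursors(self, pipeline_run):
        for c in pipeline_run.novel_catalog:
            assert c.mature in c.precursor
            assert c.mfe <= -18.0
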