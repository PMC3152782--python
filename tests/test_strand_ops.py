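"""Read mapping, coverage-based splitting, orientation and polishing."""

import numpy as np
import pytest

import bruteforce
from conftest import random_reads
from denovotx import Contig, Read, map_reads, orient_contig, polish_consensus
from denovotx.io_formats import revcomp
from denovotx.strand_ops import (
    StrandCoverage,
    revcomp_base_counts,
    split_low_coverage,
    split_strand_transitions,
)


def _random_seq(rng, n):
    return np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, n)].tobytes().decode()


class TestMapReads:
    def test_exact_substring_maps_forward(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 200))
        read = Read(id="r", sequence=contig.sequence[50:84], stranded=True)
        result = map_reads([read], [contig])
        (hit,) = result.hits
        assert (hit.strand, hit.mismatches, hit.blocks) == ("+", 0, [(0, 34, 50, 84)])

    def test_revcomp_substring_maps_reverse(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 200))
        read = Read(id="r", sequence=revcomp(contig.sequence[50:84]), stranded=True)
        result = map_reads([read], [contig])
        assert result.hits[0].strand == "-"
        assert result.coverage["c"].rev[50:84].min() == 1
        assert result.coverage["c"].fwd.sum() == 0

    def test_mismatches_tolerated_up_to_limit(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 200))
        seq = list(contig.sequence[50:84])
        for pos in (5, 20):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        result = map_reads([Read(id="r", sequence="".join(seq))], [contig])
        assert result.hits[0].mismatches == 2
        seq[28] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[28]]
        result3 = map_reads([Read(id="r3", sequence="".join(seq))], [contig])
        assert result3.hits == [] and result3.n_unmapped == 1

    def test_ambiguous_reads_excluded_from_coverage(self, rng):
        repeat = _random_seq(rng, 60)
        contig = Contig(id="c", sequence=repeat + _random_seq(rng, 80) + repeat)
        read = Read(id="r", sequence=repeat[10:44], stranded=True)
        result = map_reads([read], [contig])
        assert result.n_ambiguous == 1
        assert len(result.hits) == 1  # tie-broken hit still reported
        assert result.hits[0].blocks[0][2] == 10  # leftmost position
        assert result.total_depth["c"].sum() == 0

    def test_pileup_matches_bruteforce(self, rng):
        """Coverage tracks equal a brute-force full-scan pileup on 200 reads."""
        contigs = [Contig(id=f"c{i}", sequence=_random_seq(rng, 300)) for i in range(3)]
        reads = []
        for i in range(200):
            ci = int(rng.integers(0, 3))
            start = int(rng.integers(0, 267))
            seq = contigs[ci].sequence[start : start + 34]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(
                Read(
                    id=f"r{i}",
                    sequence=seq,
                    stranded=bool(rng.random() < 0.7),
                    multiplicity=int(rng.integers(1, 4)),
                )
            )
        result = map_reads(reads, contigs, max_mismatches=2)
        placements = []
        for read in reads:
            best = bruteforce.best_placements(read.sequence, contigs, 2)
            if len(best) == 1:
                _, cid, start, strand = best[0]
                placements.append((read, cid, start, strand))
        fwd, rev, total = bruteforce.pileup(placements, {c.id: 300 for c in contigs})
        for c in contigs:
            np.testing.assert_array_equal(result.total_depth[c.id], total[c.id])
            np.testing.assert_array_equal(result.coverage[c.id].fwd, fwd[c.id])
            np.testing.assert_array_equal(result.coverage[c.id].rev, rev[c.id])

    def test_base_counts_column_sums_equal_depth(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 150))
        reads = []
        for i in range(50):
            start = int(rng.integers(0, 117))
            seq = list(contig.sequence[start : start + 34])
            if rng.random() < 0.3:
                pos = int(rng.integers(0, 34))
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            reads.append(Read(id=f"r{i}", sequence="".join(seq)))
        result = map_reads(reads, [contig])
        np.testing.assert_array_equal(
            result.base_counts["c"].sum(axis=0), result.total_depth["c"]
        )


class TestSplitLowCoverage:
    def test_uniform_depth_unchanged(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 300))
        out = split_low_coverage(contig, np.full(300, 10), min_reads=3, read_length=34)
        assert out == [(contig, (0, 300))]

    def test_long_zero_run_excised_at_definition_positions(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 500))
        depth = np.full(500, 10)
        depth[200:301] = 0  # run of 101 > read_length 34
        out = split_low_coverage(contig, depth, min_reads=3, read_length=34)
        assert [iv for _, iv in out] == [(0, 200), (301, 500)]
        assert out[0][0].sequence == contig.sequence[:200]
        assert out[1][0].sequence == contig.sequence[301:]

    def test_run_of_exactly_read_length_not_split(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 300))
        depth = np.full(300, 10)
        depth[100:134] = 0  # exactly one read length: "longer than" is strict
        out = split_low_coverage(contig, depth, min_reads=3, read_length=34)
        assert [iv for _, iv in out] == [(0, 300)]

    def test_fragment_conservation(self, rng):
        """Fragments plus excised gaps reconstruct the contig exactly."""
        contig = Contig(id="c", sequence=_random_seq(rng, 600))
        depth = np.array(rng.integers(0, 6, 600))
        out = split_low_coverage(contig, depth, min_reads=3, read_length=34)
        pieces = sorted([iv for _, iv in out])
        rebuilt = []
        cursor = 0
        for (s, e), (frag, _) in zip(pieces, sorted(out, key=lambda x: x[1])):
            rebuilt.append(contig.sequence[cursor:s])
            rebuilt.append(frag.sequence)
            cursor = e
        rebuilt.append(contig.sequence[cursor:])
        assert "".join(rebuilt) == contig.sequence


class TestSplitStrandTransitions:
    def test_pure_forward_single_segment(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 300))
        cov = StrandCoverage("c", np.full(300, 8), np.zeros(300, dtype=int))
        assert split_strand_transitions(contig, cov) == [((0, 300), "+")]

    def test_no_stranded_evidence_returns_none_strand(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 300))
        cov = StrandCoverage("c", np.zeros(300, dtype=int), np.zeros(300, dtype=int))
        assert split_strand_transitions(contig, cov) == [((0, 300), None)]

    def test_sharp_transition_cuts_at_boundary(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 1000))
        fwd = np.zeros(1000, dtype=int)
        rev = np.zeros(1000, dtype=int)
        fwd[:500] = 10
        rev[500:] = 10
        out = split_strand_transitions(contig, StrandCoverage("c", fwd, rev), window=50)
        assert [s for _, s in out] == ["+", "-"]
        (lo1, hi1), (lo2, hi2) = (iv for iv, _ in out)
        assert lo1 == 0 and hi2 == 1000
        assert abs(hi1 - 500) <= 25 and abs(lo2 - 500) <= 25  # within half a window

    def test_antisense_overlap_retained_on_both_strands(self, rng):
        """fwd over [0,600), rev over [400,1000): both outputs keep the
        shared [400,600) region."""
        contig = Contig(id="c", sequence=_random_seq(rng, 1000))
        fwd = np.zeros(1000, dtype=int)
        rev = np.zeros(1000, dtype=int)
        fwd[:600] = 10
        rev[400:] = 10
        out = split_strand_transitions(contig, StrandCoverage("c", fwd, rev), window=50)
        by_strand = {s: iv for iv, s in out}
        assert set(by_strand) == {"+", "-"}
        plo, phi = by_strand["+"]
        mlo, mhi = by_strand["-"]
        assert plo == 0 and mhi == 1000
        assert phi >= 575 and mlo <= 425  # each keeps (nearly) all of its transcript
        assert phi > mlo  # overlap region present in both

    def test_entirely_mixed_emitted_twice(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 200))
        cov = StrandCoverage("c", np.full(200, 5), np.full(200, 5))
        out = split_strand_transitions(contig, cov)
        assert out == [((0, 200), "+"), ((0, 200), "-")]


class TestOrientAndPolish:
    def test_plus_segment_unchanged(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 100))
        out = orient_contig(contig, "+")
        assert out.sequence == contig.sequence and out.oriented

    def test_minus_segment_reverse_complemented(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 100))
        out = orient_contig(contig, "-")
        assert out.sequence == revcomp(contig.sequence) and out.oriented

    def test_no_evidence_keeps_orientation_unoriented(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 100))
        out = orient_contig(contig, None)
        assert out.sequence == contig.sequence and not out.oriented

    def test_unanimous_counts_unchanged(self, rng):
        contig = Contig(id="c", sequence=_random_seq(rng, 60))
        counts = np.zeros((5, 60), dtype=int)
        for i, b in enumerate(contig.sequence):
            counts["ACGT".index(b), i] = 10
        polished, n = polish_consensus(contig, counts)
        assert n == 0 and polished.sequence == contig.sequence

    def test_plurality_base_replaces_contig_base(self):
        contig = Contig(id="c", sequence="AAAA")
        counts = np.zeros((5, 4), dtype=int)
        counts[0, :] = 10  # A everywhere
        counts[0, 2] = 1
        counts[1, 2] = 9  # position 2: A:1, C:9
        polished, n = polish_consensus(contig, counts, min_depth=3)
        assert (polished.sequence, n) == ("AACA", 1)

    def test_ties_and_shallow_positions_keep_original(self):
        contig = Contig(id="c", sequence="AAAA")
        counts = np.zeros((5, 4), dtype=int)
        counts[0, 0] = 5  # agrees
        counts[1, 1] = 5
        counts[3, 1] = 5  # tie C/T -> keep A
        counts[1, 2] = 2  # depth 2 < min_depth -> keep A
        polished, n = polish_consensus(contig, counts, min_depth=3)
        assert polished.sequence == "AAAA" and n == 0

    def test_planted_assembly_errors_all_corrected(self, rng):
        """Mapping error-free reads to a contig with planted errors fixes
        every planted position and nothing else."""
        truth = _random_seq(rng, 400)
        broken = list(truth)
        planted = sorted(rng.choice(np.arange(40, 360), size=5, replace=False))
        for pos in planted:
            broken[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[broken[pos]]
        contig = Contig(id="c", sequence="".join(broken))
        reads = [
            Read(id=f"r{i}", sequence=truth[s : s + 34])
            for i, s in enumerate(list(rng.integers(0, 367, 600)) + [0, 366])
        ]
        result = map_reads(reads, [contig], max_mismatches=2)
        polished, n = polish_consensus(contig, result.base_counts["c"], min_depth=3)
        assert polished.sequence == truth
        assert n == len(planted)
        assert len(polished.sequence) == len(contig.sequence)

    def test_revcomp_base_counts_consistency(self, rng):
        seq = _random_seq(rng, 80)
        contig = Contig(id="c", sequence=seq)
        reads = [Read(id=f"r{i}", sequence=seq[s : s + 30]) for i, s in enumerate(range(0, 51, 5))]
        result = map_reads(reads, [contig])
        flipped = revcomp_base_counts(result.base_counts["c"])
        rc_contig = Contig(id="c", sequence=revcomp(seq))
        polished, n = polish_consensus(rc_contig, flipped, min_depth=1)
        assert n == 0 and polished.sequence == rc_contig.sequence
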