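"""Seed-and-extend nucleotide aligner and protein alignment."""

from functools import lru_cache

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from mitoscreen import (AlignParams, Genome, evalue, global_align_protein,
                        local_align, local_align_protein)
from mitoscreen.genome_io import revcomp


def _sw_oracle_score(q: str, s: str) -> float:
    """Independent Smith-Waterman optimum under the aligner's scheme."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -7   # gap of length g costs 5 + 2g
    al.extend_gap_score = -2
    return al.score(q, s)


def _mutated_copy(rng, s, n_subs=4, indel=False):
    q = list(s)
    for _ in range(n_subs):
        i = rng.integers(2, len(q) - 2)
        q[i] = rng.choice([c for c in "ACGT" if c != q[i]])
    if indel:
        j = rng.integers(10, len(q) - 10)
        q = q[:j] + q[j + 3:]
    return "".join(q)


class TestLocalAlign:
    def test_self_alignment_full_identity(self, rng):
        s = "".join(rng.choice(list("ACGT"), 1000))
        (hit,) = local_align(Genome("q", s), Genome("s", s))
        assert (hit.q.start, hit.q.end) == (1, 1000)
        assert (hit.s.start, hit.s.end) == (1, 1000)
        assert hit.identity == 1.0 and hit.strand == 1

    def test_reverse_complement_hit(self, rng):
        s = "".join(rng.choice(list("ACGT"), 600))
        (hit,) = local_align(Genome("q", s), Genome("s", revcomp(s)))
        assert hit.strand == -1 and hit.identity == 1.0
        assert (hit.q.start, hit.q.end) == (1, 600)

    def test_no_shared_word_gives_empty(self):
        q = Genome("q", "A" * 200)
        s = Genome("s", "C" * 200)
        assert local_align(q, s) == []

    def test_query_shorter_than_word_size(self):
        assert local_align(Genome("q", "ACGTACG"), Genome("s", "ACGT" * 50)) == []

    @pytest.mark.parametrize("indel", [False, True])
    def test_score_matches_smith_waterman_oracle(self, rng, indel):
        """On <= 200 bp mutated copies the chained-seed score equals the
        full dynamic-programming optimum."""
        for _ in range(15):
            s = "".join(rng.choice(list("ACGT"), 200))
            q = _mutated_copy(rng, s, n_subs=4, indel=indel)
            hits = local_align(Genome("q", q), Genome("s", s))
            best = max(h.raw_score for h in hits)
            assert best == _sw_oracle_score(q, s)

    def test_symmetry_of_best_hit(self, rng):
        s = "".join(rng.choice(list("ACGT"), 300))
        q = _mutated_copy(rng, s, n_subs=3)
        fwd = local_align(Genome("a", q), Genome("b", s))
        rev = local_align(Genome("b", s), Genome("a", q))
        assert max(h.raw_score for h in fwd) == max(h.raw_score for h in rev)
        hf = max(fwd, key=lambda h: h.raw_score)
        hr = max(rev, key=lambda h: h.raw_score)
        assert (hf.q.start, hf.q.end) == (hr.s.start, hr.s.end)

    def test_identity_consistent_with_columns(self, rng):
        s = "".join(rng.choice(list("ACGT"), 400))
        q = _mutated_copy(rng, s, n_subs=5, indel=True)
        for h in local_align(Genome("q", q), Genome("s", s)):
            assert h.identity == pytest.approx(h.matches / h.columns, abs=1e-12)
            assert h.columns >= h.matches + h.gap_columns

    def test_circular_subject_hit_wraps_origin(self, rng):
        s = "".join(rng.choice(list("ACGT"), 2000))
        # query matches the subject across its origin
        q = s[1700:] + s[:300]
        hits = local_align(Genome("q", q), Genome("s", s, circular=True))
        best = max(hits, key=lambda h: h.raw_score)
        assert best.raw_score == 600
        assert best.s.start == 1701 and best.s.end == 300  # wrapping interval


class TestEvalue:
    P = AlignParams(K=0.46, lam=1.28)

    def test_closed_form_at_zero_score(self):
        assert evalue(0, 1000, 1000, self.P) == pytest.approx(460000.0)

    def test_monotone_decreasing_in_score(self):
        vals = [evalue(s, 1000, 1000, self.P) for s in range(0, 100, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert evalue(1000, 1000, 1000, self.P) < 1e-300

    def test_linear_in_subject_length(self):
        assert evalue(30, 500, 2000, self.P) == pytest.approx(
            2 * evalue(30, 500, 1000, self.P))


BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _nw_oracle_score(a: str, b: str, go: int = 11, ge: int = 1) -> int:
    """Exhaustive affine-gap global alignment recursion (independent of the
    implementation); gap of length g costs go + g*ge."""
    NEG = -(10 ** 9)

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0 and j == 0:
            return 0
        if i == 0 or j == 0:
            return NEG
        return (max(M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))
                + int(BLOSUM62[a[i - 1], b[j - 1]]))

    @lru_cache(maxsize=None)
    def X(i, j):
        if i == 0:
            return NEG
        return max(M(i - 1, j) - go - ge, X(i - 1, j) - ge)

    @lru_cache(maxsize=None)
    def Y(i, j):
        if j == 0:
            return NEG
        return max(M(i, j - 1) - go - ge, Y(i, j - 1) - ge)

    return max(M(len(a), len(b)), X(len(a), len(b)), Y(len(a), len(b)))


AA = "ACDEFGHIKLMNPQRSTVWY"


class TestProteinAlignment:
    def test_identical_sequences(self):
        aln = global_align_protein("MKVLF" * 4, "MKVLF" * 4)
        assert aln.identity == 1.0
        assert all(lab == "match" for lab in aln.labels)

    def test_two_deletions_reported(self):
        a = "MKVLFAENWQRSTGHI"
        b = a[:5] + a[7:]  # two residues removed
        aln = global_align_protein(a, b)
        assert aln.labels.count("gap_b") == 2
        assert aln.labels.count("gap_a") == 0

    def test_score_matches_bruteforce_recursion(self, rng):
        """Global affine score equals an exhaustive recursion on <= 30 aa."""
        for _ in range(10):
            a = "".join(rng.choice(list(AA), rng.integers(8, 30)))
            b = "".join(rng.choice(list(AA), rng.integers(8, 30)))
            assert global_align_protein(a, b).score == _nw_oracle_score(a, b)

    def test_local_alignment_of_embedded_segment(self, rng):
        core = "".join(rng.choice(list(AA), 40))
        a = "".join(rng.choice(list(AA), 20)) + core
        b = core + "".join(rng.choice(list(AA), 15))
        aln = local_align_protein(a, b)
        assert aln.identity == 1.0
        assert (aln.a_start, aln.b_start) == (21, 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align_protein("", "MKV")
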