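"""Maximal exact repeat finding."""

import numpy as np
import pytest

from mitoscreen import Genome, find_repeats, group_families
from mitoscreen.genome_io import revcomp
from mitoscreen.simulate import random_seq


def _oracle_repeats(seq: str, min_len: int) -> set[tuple]:
    """Independent O(n^2) shift-compare oracle for linear genomes:
    (a_start, a_end, b_start, b_end, orientation), 1-based."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    out = set()
    for d in range(1, n):  # direct repeats at shift d
        eq = arr[d:] == arr[:-d]
        for a, ln in _true_runs(eq):
            if ln >= min_len:
                out.add((a + 1, a + ln, a + d + 1, a + d + ln, "direct"))
    for dd in range(-(n - 1), n):  # inverted: seq vs its reverse complement
        if dd >= 0:
            eq = arr[: n - dd] == rc[dd:]
            off_a, off_r = 0, dd
        else:
            eq = arr[-dd:] == rc[: n + dd]
            off_a, off_r = -dd, 0
        for a, ln in _true_runs(eq):
            ai = off_a + a
            rj = off_r + a
            b0 = n - (rj + ln)  # map rc run back to forward coordinates
            locus_a = (ai + 1, ai + ln)
            locus_b = (b0 + 1, b0 + ln)
            if locus_a == locus_b:
                continue  # palindromic self-image
            pair = tuple(sorted([locus_a, locus_b]))
            if ln >= min_len:
                out.add((pair[0][0], pair[0][1], pair[1][0], pair[1][1],
                         "inverted"))
    return out


def _true_runs(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e - s)


def _as_set(pairs):
    return {(p.locus_a.start, p.locus_a.end, p.locus_b.start, p.locus_b.end,
             p.orientation) for p in pairs}


class TestFindRepeats:
    def test_planted_direct_repeat(self, rng):
        s = list(random_seq(rng, 10000))
        # force mismatching flanks so the planted pair is maximal at 2000
        if s[5999] == s[999]:
            s[5999] = "A" if s[999] != "A" else "C"
        if s[6000] == s[3000]:
            s[6000] = "A" if s[3000] != "A" else "C"
        s = "".join(s)
        unit = s[1000:3000]
        g = Genome("g", s[:6000] + unit + s[6000:])
        pairs = [p for p in find_repeats(g, 1000) if p.orientation == "direct"]
        assert len(pairs) == 1
        p = pairs[0]
        assert p.length == 2000
        assert (p.locus_a.start, p.locus_a.end) == (1001, 3000)
        assert (p.locus_b.start, p.locus_b.end) == (6001, 8000)

    def test_no_repeat_above_threshold(self, rng):
        g = Genome("g", random_seq(rng, 10000))
        assert find_repeats(g, 1000) == []

    def test_planted_inverted_repeat(self, rng):
        s = random_seq(rng, 8000)
        unit = s[500:2000]
        g = Genome("g", s + revcomp(unit))
        pairs = find_repeats(g, 1000)
        assert len(pairs) == 1
        assert pairs[0].orientation == "inverted"
        assert pairs[0].length == 1500

    def test_repeated_substrings_verified_identical(self, rng):
        s = random_seq(rng, 5000)
        g = Genome("g", s[:2500] + s[800:2000] + s[2500:] + revcomp(s[100:1400]))
        for p in find_repeats(g, 1000):
            sa = g.fetch(p.locus_a)
            sb = g.fetch(p.locus_b)
            assert sa == (sb if p.orientation == "direct" else revcomp(sb))

    def test_equals_quadratic_oracle(self, rng):
        """Exact pair-set equality with a shift-compare oracle on <= 2 kb."""
        for _ in range(4):
            base = random_seq(rng, 1600)
            # plant a direct and an inverted copy below/above the threshold
            seq = (base[:400] + base[1000:1100] + base[400:1000]
                   + revcomp(base[200:330]) + base[1000:])
            got = _as_set(find_repeats(Genome("g", seq), min_repeat_len=20))
            assert got == _oracle_repeats(seq, 20)

    def test_rotation_invariance_on_circle(self, rng):
        s = random_seq(rng, 9000)
        seq = s[:4000] + s[1000:2500] + s[4000:]  # 1500 bp duplicate
        g1 = Genome("g", seq, circular=True)
        shift = 3000
        g2 = Genome("g", seq[shift:] + seq[:shift], circular=True)
        l1 = sorted((p.length, p.orientation) for p in find_repeats(g1, 1000))
        l2 = sorted((p.length, p.orientation) for p in find_repeats(g2, 1000))
        assert l1 == l2

    def test_family_grouping_of_three_copies(self, rng):
        s = random_seq(rng, 12000)
        unit = s[0:1500]
        g = Genome("g", s + unit + random_seq(rng, 200) + unit)
        pairs = [p for p in find_repeats(g, 1000) if p.length >= 1500]
        assert len(pairs) == 3  # C(3,2) pairs
        fams = group_families(pairs)
        assert len(fams) == 1  # one family of three copies
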