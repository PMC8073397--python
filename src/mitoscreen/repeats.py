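"""Maximal exact repeats (direct and inverted) in a circular genome.

Plant mitogenomes carry large (multi-kb) repeats that mediate recombination,
so a CMS mitogenome survey reports every maximal exact repeated pair above a
length threshold (default 1 kb).  Implementation: k-mer anchoring (k = 31)
with per-diagonal merging into maximal exact runs, end extension, and
containment deduplication; circular wrap is handled on the doubled sequence.
A family present in c copies yields C(c,2) maximal pairs; ``group_families``
offers the family view so either counting convention can be read off.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Genome, Interval, revcomp

__all__ = ["RepeatPair", "find_repeats", "group_families"]

ANCHOR_K = 31


@dataclass(frozen=True)
class RepeatPair:
    """A maximal exact repeated pair; ``locus_a.start < locus_b.start`` in
    canonical order.  ``overlapping`` flags self-overlapping tandem repeats."""

    locus_a: Interval
    locus_b: Interval
    length: int
    orientation: str  # "direct" | "inverted"
    overlapping: bool = False


def find_repeats(genome: Genome, min_repeat_len: int = 1000,
                 include_inverted: bool = True,
                 k: int = ANCHOR_K) -> list[RepeatPair]:
    """All maximal exact repeated pairs of length >= min_repeat_len.

    Direct pairs satisfy seq[a] == seq[b]; inverted pairs satisfy
    seq[a] == revcomp(seq[b]).  Each pair is reported once.
    """
    L = len(genome.seq)
    k = min(k, max(4, min_repeat_len // 2))
    seq = genome.seq * 2 if genome.circular else genome.seq
    pairs: dict[tuple, RepeatPair] = {}

    for q0, t0, ln in _self_runs_direct(seq, k):
        if ln < min_repeat_len or ln > L:
            continue
        _add_pair(pairs, genome, q0, t0, ln, "direct")

    if include_inverted:
        rc = revcomp(seq)
        for q0, r0, ln in _runs_between(seq, rc, k):
            if ln < min_repeat_len or ln > L:
                continue
            # map the rc-run back onto forward coordinates
            b0 = len(seq) - (r0 + ln)
            _add_pair(pairs, genome, q0, b0, ln, "inverted")

    out = sorted(pairs.values(),
                 key=lambda r: (r.locus_a.start, r.locus_b.start, -r.length,
                                r.orientation))
    return out


def _self_runs_direct(seq: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact runs (a, b, length), a < b, of seq against itself
    (excluding the trivial diagonal)."""
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - k + 1):
        index.setdefault(seq[j : j + k], []).append(j)
    by_diag: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                i, j = positions[x], positions[y]
                by_diag.setdefault(j - i, []).append(i)
    return _merge_diag_runs(by_diag, k)


def _runs_between(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact runs between two strings via shared k-mers."""
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    return _merge_diag_runs(by_diag, k)


def _merge_diag_runs(by_diag: dict[int, list[int]], k: int
                     ) -> list[tuple[int, int, int]]:
    runs = []
    for d, starts in by_diag.items():
        starts = sorted(set(starts))
        a = prev = starts[0]
        for i in starts[1:]:
            if i == prev + 1:
                prev = i
            else:
                runs.append((a, a + d, prev - a + k))
                a = prev = i
        runs.append((a, a + d, prev - a + k))
    return runs


def _add_pair(pairs: dict, genome: Genome, a0: int, b0: int, ln: int,
              orientation: str) -> None:
    """Canonicalise a run found on the (possibly doubled) sequence and store
    it keyed by its canonical loci."""
    L = len(genome.seq)
    ivs = []
    for s0 in (a0, b0):
        shift = (s0 // L) * L if genome.circular else 0
        f0 = s0 - shift
        f1 = f0 + ln
        if f1 <= L or not genome.circular:
            ivs.append((f0 + 1, f1))
        else:
            ivs.append((f0 + 1, f1 - L))
    ivs.sort()
    (sa, ea), (sb, eb) = ivs
    if (sa, ea) == (sb, eb):
        return  # doubled-sequence image of the same locus
    # overlap check for tandem repeats (linear coordinates only)
    ia, ib = Interval(sa, ea), Interval(sb, eb)
    overlapping = ia.overlaps(ib, L)
    key = (sa, ea, sb, eb, orientation)
    prev = pairs.get(key)
    if prev is None or ln > prev.length:
        pairs[key] = RepeatPair(ia, ib, ln, orientation, overlapping)


def group_families(pairs: list[RepeatPair]) -> dict[int, list[RepeatPair]]:
    """Group pairs into repeat families: pairs sharing a locus belong to the
    same family (union-find over loci)."""
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for p in pairs:
        la = (p.locus_a.start, p.locus_a.end)
        lb = (p.locus_b.start, p.locus_b.end)
        union(la, lb)
    families: dict[tuple, list[RepeatPair]] = {}
    for p in pairs:
        root = find((p.locus_a.start, p.locus_a.end))
        families.setdefault(root, []).append(p)
    return {i + 1: fam for i, fam in enumerate(
        families[r] for r in sorted(families))}
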