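"""Pairwise alignment: a seed-and-extend local nucleotide aligner with
Karlin-Altschul E-values, and affine-gap protein alignment.

The nucleotide aligner plays the role a local BLAST search plays in a
mitogenome comparison: exact ``word_size``-mer seeds are merged into maximal
exact runs per diagonal, nearby runs are chained across small substitutions
and indels (gap sub-alignments scored by an affine Needleman-Wunsch), and the
chain is trimmed to its best-scoring local sub-chain.  On the long,
high-identity hits that dominate mitogenome-vs-mitogenome comparisons this
recovers the Smith-Waterman optimum; exact parity with any particular BLAST
release is not claimed.

Scoring convention: a gap of length *g* costs ``gap_open + g * gap_extend``.

Protein alignment (global and local, BLOSUM62 affine) is delegated to
:class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, Interval, revcomp

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "ProteinAlignment",
    "local_align",
    "evalue",
    "global_align_protein",
    "local_align_protein",
    "hits_to_table",
]


@dataclass(frozen=True)
class AlignParams:
    """Parameters of the seed-and-extend search and its E-value statistics.

    Defaults are the published ungapped Karlin-Altschul constants for the
    +1/-2 nucleotide scheme (lambda = 1.28, K = 0.46) with BLAST-like word
    size 11 and gap costs open 5 / extend 2.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.28
    K: float = 0.46
    evalue_max: float = 1e-5
    band: int = 32  # max diagonal drift bridged when chaining seeds

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment: query/subject intervals, identity and E-value.

    ``identity`` is exact matches over aligned columns (gap columns count
    against it).  Subject coordinates are always on the forward subject
    strand; ``strand == -1`` means the query matches the reverse complement.
    """

    q: Interval
    s: Interval
    strand: int
    identity: float
    raw_score: int
    evalue: float
    matches: int
    columns: int
    gap_columns: int = 0


def evalue(raw_score: int, m: int, n: int, params: AlignParams) -> float:
    """Karlin-Altschul expectation: K * m * n * exp(-lambda * score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * raw_score)


# ---------------------------------------------------------------------------
# seed collection and chaining


def _kmer_codes(s: str, k: int) -> np.ndarray:
    """2-bit integer codes of all k-mers; -1 where the window contains N."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(b"ACGT"):
        lut[c] = i
    vals = lut[arr]
    n = len(s) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    safe = np.where(vals < 0, 0, vals)
    codes = np.zeros(n, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | safe[i : i + n]
    bad = vals < 0
    if bad.any():
        w = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64),
                        "valid") > 0
        codes[w] = -1
    return codes


def _exact_runs(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact match runs (q0, t0, length) of length >= k.

    Exact k-mer matches are collected by an integer-code join and merged per
    diagonal; within a maximal exact stretch every in-stretch k-mer matches,
    so consecutive seed positions differ by 1 and merging is exact.
    """
    qc = _kmer_codes(query, k)
    tc = _kmer_codes(target, k)
    if len(qc) == 0 or len(tc) == 0:
        return []
    qdf = pd.DataFrame({"code": qc, "q": np.arange(len(qc), dtype=np.int64)})
    qdf = qdf[qdf.code >= 0]
    tdf = pd.DataFrame({"code": tc, "t": np.arange(len(tc), dtype=np.int64)})
    tdf = tdf[tdf.code >= 0]
    m = qdf.merge(tdf, on="code", how="inner")
    if m.empty:
        return []
    q = m["q"].to_numpy()
    t = m["t"].to_numpy()
    diag = t - q
    order = np.lexsort((q, diag))
    q, t, diag = q[order], t[order], diag[order]
    new_run = np.ones(len(q), dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (q[1:] != q[:-1] + 1)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(q))
    return [(int(q[s]), int(t[s]), int(q[e - 1] - q[s] + k))
            for s, e in zip(starts, ends)]


def _nw_affine(a: str, b: str, p: AlignParams) -> tuple[int, int, int, int]:
    """Global affine-gap alignment of two short strings.

    Returns (score, matches, columns, gap_columns).  Used to score the bridge
    between two chained exact runs; sequences are at most ~2*band long.
    Tie-break diagonal > up > left.
    """
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return 0, 0, 0, 0
    go, ge = p.gap_open, p.gap_extend
    NEG = -(10 ** 9)
    # three-state DP: M (diagonal), X (gap in b / up), Y (gap in a / left);
    # ptr[state][i][j] records the predecessor state
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    pM = [[""] * (lb + 1) for _ in range(la + 1)]
    pX = [[""] * (lb + 1) for _ in range(la + 1)]
    pY = [[""] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for i in range(1, la + 1):
        X[i][0] = -(go + ge * i)
        pX[i][0] = "M" if i == 1 else "X"
    for j in range(1, lb + 1):
        Y[0][j] = -(go + ge * j)
        pY[0][j] = "M" if j == 1 else "Y"
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = p.match if a[i - 1] == b[j - 1] else p.mismatch
            prev = ((M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"),
                    (Y[i - 1][j - 1], "Y"))
            best = max(prev, key=lambda t: t[0])
            M[i][j] = best[0] + sub
            pM[i][j] = best[1]
            if M[i - 1][j] - go - ge >= X[i - 1][j] - ge:
                X[i][j], pX[i][j] = M[i - 1][j] - go - ge, "M"
            else:
                X[i][j], pX[i][j] = X[i - 1][j] - ge, "X"
            if M[i][j - 1] - go - ge >= Y[i][j - 1] - ge:
                Y[i][j], pY[i][j] = M[i][j - 1] - go - ge, "M"
            else:
                Y[i][j], pY[i][j] = Y[i][j - 1] - ge, "Y"
    i, j = la, lb
    state = max((("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])),
                key=lambda t: t[1])[0]
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    matches = cols = gaps = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            if a[i - 1] == b[j - 1]:
                matches += 1
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            gaps += 1
            state = pX[i][j]
            i -= 1
        else:
            gaps += 1
            state = pY[i][j]
            j -= 1
    return score, matches, cols, gaps


def _chain_runs(runs: list[tuple[int, int, int]], query: str, target: str,
                p: AlignParams) -> list[list[tuple[int, int, int]]]:
    """Greedy chaining of exact runs across small gaps (<= band on both axes).

    Candidate successors are found by bisection on query starts, so chaining
    stays near-linear even when chance word matches are abundant.
    """
    from bisect import bisect_left, bisect_right

    runs = sorted(runs, key=lambda r: (r[0], r[1]))
    q0s = [r[0] for r in runs]
    chains: list[list[tuple[int, int, int]]] = []
    used = [False] * len(runs)
    for idx, r in enumerate(runs):
        if used[idx]:
            continue
        chain = [r]
        used[idx] = True
        qe, te = r[0] + r[2], r[1] + r[2]
        while True:
            nxt = None
            for jdx in range(bisect_left(q0s, qe),
                             bisect_right(q0s, qe + p.band)):
                if used[jdx]:
                    continue
                tgap = runs[jdx][1] - te
                if 0 <= tgap <= p.band:
                    nxt = jdx
                    break
            if nxt is None:
                break
            nq, nt, nl = runs[nxt]
            chain.append(runs[nxt])
            used[nxt] = True
            qe, te = nq + nl, nt + nl
        chains.append(chain)
    return chains


def _best_extension(q: str, t: str, p: AlignParams, xdrop: int = 40,
                    max_ext: int = 2000
                    ) -> tuple[int, int, int, int, int, int]:
    """Best-scoring free-end extension: max over (i, j) of the global
    affine alignment score of q[:i] vs t[:j], within a band and X-drop.

    Returns (i, j, score, matches, columns, gap_columns); all zeros when no
    positive extension exists.  Column statistics are carried through the DP
    so no traceback is needed.
    """
    nq, nt = min(len(q), max_ext), min(len(t), max_ext)
    if nq == 0 or nt == 0:
        return 0, 0, 0, 0, 0, 0
    NEG = -(10 ** 9)
    band = p.band
    go, ge = p.gap_open, p.gap_extend
    zero = (0, 0, 0, 0)  # (score, matches, columns, gap_columns)
    dead = (NEG, 0, 0, 0)
    best = (0, 0) + zero
    prevM: dict[int, tuple] = {0: zero}
    prevX: dict[int, tuple] = {}
    prevY: dict[int, tuple] = {}
    for j in range(1, min(nt, band) + 1):
        prevY[j] = (-(go + ge * j), 0, j, j)
    for i in range(1, nq + 1):
        curM: dict[int, tuple] = {}
        curX: dict[int, tuple] = {}
        curY: dict[int, tuple] = {}
        lo, hi = max(0, i - band), min(nt, i + band)
        row_best = NEG
        for j in range(lo, hi + 1):
            if j == 0:
                curX[0] = (-(go + ge * i), 0, i, i)
                continue
            ismatch = q[i - 1] == t[j - 1]
            sub = p.match if ismatch else p.mismatch
            pm = max(prevM.get(j - 1, dead), prevX.get(j - 1, dead),
                     prevY.get(j - 1, dead), key=lambda s: s[0])
            if pm[0] > NEG // 2:
                curM[j] = (pm[0] + sub, pm[1] + ismatch, pm[2] + 1, pm[3])
            xm = prevM.get(j, dead)
            xx = prevX.get(j, dead)
            if xm[0] - go - ge >= xx[0] - ge:
                if xm[0] > NEG // 2:
                    curX[j] = (xm[0] - go - ge, xm[1], xm[2] + 1, xm[3] + 1)
            elif xx[0] > NEG // 2:
                curX[j] = (xx[0] - ge, xx[1], xx[2] + 1, xx[3] + 1)
            ym = curM.get(j - 1, dead)
            yy = curY.get(j - 1, dead)
            if ym[0] - go - ge >= yy[0] - ge:
                if ym[0] > NEG // 2:
                    curY[j] = (ym[0] - go - ge, ym[1], ym[2] + 1, ym[3] + 1)
            elif yy[0] > NEG // 2:
                curY[j] = (yy[0] - ge, yy[1], yy[2] + 1, yy[3] + 1)
            here = max(curM.get(j, dead)[0], curX.get(j, dead)[0],
                       curY.get(j, dead)[0])
            row_best = max(row_best, here)
            cm = curM.get(j, dead)
            if cm[0] > best[2]:
                best = (i, j) + cm
        prevM, prevX, prevY = curM, curX, curY
        if row_best < best[2] - xdrop:
            break
    return best


@dataclass
class _Hsp:
    q0: int
    q1: int
    t0: int
    t1: int
    score: int
    matches: int
    columns: int
    gaps: int


def _chain_to_hsp(chain: list[tuple[int, int, int]], query: str, target: str,
                  p: AlignParams, extend: bool = True) -> _Hsp | None:
    """Trim a chain to its best local sub-chain (Kadane over run/bridge scores)."""
    m = len(chain)
    bridges: list[tuple[int, int, int, int]] = []
    for a, b in zip(chain, chain[1:]):
        qa, ta = a[0] + a[2], a[1] + a[2]
        bridges.append(_nw_affine(query[qa: b[0]], target[ta: b[1]], p))
    best = None  # (score, start_run, end_run)
    cur_score = 0
    cur_start = 0
    for t in range(m):
        run_score = chain[t][2] * p.match
        if t == 0:
            cur_score, cur_start = run_score, 0
        else:
            bscore = bridges[t - 1][0]
            if cur_score + bscore + run_score >= run_score:
                cur_score = cur_score + bscore + run_score
            else:
                cur_score, cur_start = run_score, t
        if best is None or cur_score > best[0]:
            best = (cur_score, cur_start, t)
    if best is None or best[0] <= 0:
        return None
    score, s, e = best
    q0, t0 = chain[s][0], chain[s][1]
    q1, t1 = chain[e][0] + chain[e][2], chain[e][1] + chain[e][2]
    matches = sum(c[2] for c in chain[s : e + 1])
    cols = matches
    gaps = 0
    for bi in range(s, e):
        _, bm, bc, bg = bridges[bi]
        matches += bm
        cols += bc
        gaps += bg
    if not extend:
        return _Hsp(q0, q1, t0, t1, score, matches, cols, gaps)
    # free-end extension past the terminal seeds (picks up matches that are
    # too short to seed, e.g. behind a substitution near the sequence end)
    li, lj, lsc, lm, lc, lg = _best_extension(query[:q0][::-1],
                                              target[:t0][::-1], p)
    if lsc > 0:
        q0, t0 = q0 - li, t0 - lj
        score += lsc
        matches += lm
        cols += lc
        gaps += lg
    ri, rj, rsc, rm, rc, rg = _best_extension(query[q1:], target[t1:], p)
    if rsc > 0:
        q1, t1 = q1 + ri, t1 + rj
        score += rsc
        matches += rm
        cols += rc
        gaps += rg
    return _Hsp(q0, q1, t0, t1, score, matches, cols, gaps)


def local_align(query: Genome, subject: Genome,
                params: AlignParams | None = None) -> list[AlignmentHit]:
    """Local alignment of ``query`` against both strands of ``subject``.

    Returns hits with ``evalue <= params.evalue_max`` sorted by query start.
    A circular subject is scanned on its doubled sequence so hits may wrap the
    subject origin; duplicates are canonicalised away.  A query shorter than
    ``word_size`` yields an empty result.
    """
    p = params or AlignParams()
    q = query.seq
    if len(q) < p.word_size:
        return []
    Ls = len(subject.seq)
    hits: list[AlignmentHit] = []
    seen: set[tuple] = set()
    for strand in (1, -1):
        target_fwd = subject.seq * 2 if subject.circular and Ls > p.word_size else subject.seq
        target = target_fwd if strand == 1 else revcomp(target_fwd)
        if len(target) < p.word_size:
            continue
        runs = _exact_runs(q, target, p.word_size)
        chains = _chain_runs(runs, q, target, p)
        chains.sort(key=lambda c: -sum(r[2] for r in c))
        accepted_spans: list[tuple[int, int, int, int]] = []
        for chain in chains:
            # chance word collisions between unrelated stretches produce
            # isolated near-word-length seeds; those are scored ungapped-only
            # (they die at the E-value filter), and only substantially
            # seeded chains get the costly gapped end extension.  A chain
            # whose query AND target spans already lie under a larger
            # accepted hit would be pruned later anyway and is skipped up
            # front (distinct target loci are never skipped).
            c0, c1 = chain[0][0], chain[-1][0] + chain[-1][2]
            d0, d1 = chain[0][1], chain[-1][1] + chain[-1][2]
            if any(min(c1, b) - max(c0, a) >= 0.5 * (c1 - c0)
                   and min(d1, tb) > max(d0, ta)
                   for a, b, ta, tb in accepted_spans):
                continue
            seeded = sum(r[2] for r in chain)
            hsp = _chain_to_hsp(chain, q, target, p,
                                extend=seeded >= 2 * p.word_size - 1)
            if hsp is None:
                continue
            if hsp.t1 - hsp.t0 > Ls:
                continue  # doubled-sequence artefact longer than the circle
            ev = evalue(hsp.score, len(q), Ls, p)
            if ev > p.evalue_max:
                continue
            accepted_spans.append((hsp.q0, hsp.q1, hsp.t0, hsp.t1))
            hit = _hsp_to_hit(hsp, strand, len(target_fwd), Ls, ev)
            key = (hit.q.start, hit.q.end, hit.s.start, hit.s.end, hit.strand)
            if key in seen:
                continue
            seen.add(key)
            hits.append(hit)
    hits = _prune_covered(hits)
    hits.sort(key=lambda h: (h.q.start, h.q.end, h.s.start))
    return hits


def _hsp_to_hit(h: _Hsp, strand: int, Lt: int, Ls: int, ev: float) -> AlignmentHit:
    qiv = Interval(h.q0 + 1, h.q1)
    if strand == 1:
        t0, t1 = h.t0, h.t1
    else:
        t0, t1 = Lt - h.t1, Lt - h.t0  # map from reverse-complement coordinates
    # canonicalise onto the first copy of a doubled circular subject
    shift = (t0 // Ls) * Ls
    t0 -= shift
    t1 -= shift
    if t1 <= Ls:
        siv = Interval(t0 + 1, t1, strand)
    else:
        siv = Interval(t0 + 1, t1 - Ls, strand)  # wraps the origin
    return AlignmentHit(
        q=qiv, s=siv, strand=strand,
        identity=h.matches / h.columns, raw_score=h.score, evalue=ev,
        matches=h.matches, columns=h.columns, gap_columns=h.gaps,
    )


def _prune_covered(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep a hit only if < 50% of its query span is covered by a
    higher-scoring kept hit of the same alignment region (same strand and
    overlapping subject interval) — the deterministic maximality rule.
    Hits at distinct subject loci (duplicate copies) are never pruned
    against each other."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.raw_score, h.q.start, h.s.start)):
        span = h.q.end - h.q.start + 1
        covered = 0
        for k in kept:
            if k.strand != h.strand:
                continue
            if min(h.s.end, k.s.end) < max(h.s.start, k.s.start):
                continue
            lo = max(h.q.start, k.q.start)
            hi = min(h.q.end, k.q.end)
            if hi >= lo:
                covered = max(covered, hi - lo + 1)
        if covered < 0.5 * span:
            kept.append(h)
    return kept


def hits_to_table(qid: str, sid: str, hits: Sequence[AlignmentHit]) -> str:
    """Tabular hit report mirroring BLAST outfmt-6 column order
    (raw score in place of bit score)."""
    lines = []
    for h in hits:
        mism = h.columns - h.matches - h.gap_columns
        sstart, send = (h.s.start, h.s.end) if h.strand == 1 else (h.s.end, h.s.start)
        lines.append(
            f"{qid}\t{sid}\t{100 * h.identity:.2f}\t{h.columns}\t{mism}\t"
            f"{h.gap_columns}\t{h.q.start}\t{h.q.end}\t{sstart}\t{send}\t"
            f"{h.evalue:.3g}\t{h.raw_score}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# protein alignment (Biopython-backed)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class ProteinAlignment:
    """A pairwise protein alignment with per-column labels.

    ``labels[i]`` is one of ``match``, ``mismatch``, ``gap_a`` (column absent
    from ``a``) or ``gap_b``.  ``a_start``/``b_start`` are 1-based positions
    of the first aligned residue (relevant for local mode).
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    b_start: int

    @property
    def labels(self) -> list[str]:
        out = []
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-":
                out.append("gap_a")
            elif y == "-":
                out.append("gap_b")
            elif x == y:
                out.append("match")
            else:
                out.append("mismatch")
        return out

    @property
    def identity(self) -> float:
        labs = self.labels
        return labs.count("match") / len(labs) if labs else 0.0

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _protein_aligner(mode: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{name}: illegal residues {sorted(bad)}")


def _first_alignment(aligner: Align.PairwiseAligner, a: str, b: str) -> ProteinAlignment:
    try:
        aln = aligner.align(a, b)[0]  # Biopython's order is deterministic
    except IndexError:
        # local mode with no positive-scoring path yields no alignment
        return ProteinAlignment("", "", 0.0, 1, 1)
    a_start = int(aln.aligned[0][0][0]) + 1 if len(aln.aligned[0]) else 1
    b_start = int(aln.aligned[1][0][0]) + 1 if len(aln.aligned[1]) else 1
    return ProteinAlignment(str(aln[0]), str(aln[1]), float(aln.score), a_start, b_start)


def global_align_protein(a: str, b: str, gap_open: int = 11,
                         gap_extend: int = 1) -> ProteinAlignment:
    """Optimal Needleman-Wunsch alignment under BLOSUM62 with affine gaps
    (gap of length g costs ``gap_open + g * gap_extend``)."""
    _check_protein(a, "a")
    _check_protein(b, "b")
    return _first_alignment(_protein_aligner("global", gap_open, gap_extend), a, b)


def local_align_protein(a: str, b: str, gap_open: int = 11,
                        gap_extend: int = 1) -> ProteinAlignment:
    """Best Smith-Waterman local alignment under BLOSUM62 with affine gaps."""
    _check_protein(a, "a")
    _check_protein(b, "b")
    return _first_alignment(_protein_aligner("local", gap_open, gap_extend), a, b)
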