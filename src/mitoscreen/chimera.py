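"""Chimeric-protein decomposition and domain lifting.

Rice CMS proteins are typically mitochondrial recombination products: the
candidate protein is a mosaic of segments from ancestral ORFs (e.g. a
~312-aa candidate whose N-terminus matches one parent and whose C-terminus
matches another, with a short homologous junction shared by both).  This
module aligns each parent locally to the candidate (BLOSUM62, affine gaps),
keeps segments above an identity threshold (default 0.85, matching the
">85% identity" convention for recombinant detection), selects the segment
set that covers the most of the candidate with the fewest segments, and
lifts parent-domain annotations (e.g. COX11-interaction regions) onto
candidate coordinates through the alignment columns.  Domain coordinates
are supplied by the user, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .align import ProteinAlignment, local_align_protein

__all__ = ["ChimeraSegment", "DomainAnnotation", "decompose", "lift_domains"]


@dataclass
class ChimeraSegment:
    """A candidate interval explained by a parental interval.

    Identity is exact matches over aligned columns (indel columns count
    against it); ``insertions`` are candidate-only columns, ``deletions``
    parent-only columns.  Intervals are 1-based inclusive amino-acid ranges.
    """

    candidate_range: tuple[int, int]
    parent_id: str
    parent_range: tuple[int, int]
    identity: float
    insertions: int
    deletions: int
    # per-column (candidate_pos | None, parent_pos | None), 1-based
    columns: list[tuple[int | None, int | None]] = field(repr=False,
                                                         default_factory=list)

    @property
    def candidate_length(self) -> int:
        return self.candidate_range[1] - self.candidate_range[0] + 1


@dataclass(frozen=True)
class DomainAnnotation:
    """A named region on a parent protein (1-based inclusive)."""

    parent_id: str
    name: str
    parent_range: tuple[int, int]


_TRIM_WINDOW = 6
_TRIM_MIN_MATCHES = 4


def _trim_bounds(match_flags: list[bool]) -> tuple[int, int]:
    """Trim terminal columns until each end opens with a solidly homologous
    window (>= 4 matches in 6 columns) and sits on an exact match.  Chance
    score-positive tails — e.g. a local alignment drifting past a fusion
    junction into the other parent's sequence — are removed; ends of a
    genuinely homologous segment (identity >= 0.85) are left intact."""
    lo, hi = 0, len(match_flags)
    w, need = _TRIM_WINDOW, _TRIM_MIN_MATCHES
    while hi - lo > w and sum(match_flags[lo : lo + w]) < need:
        lo += 1
    while hi - lo > w and sum(match_flags[hi - w : hi]) < need:
        hi -= 1
    while lo < hi and not match_flags[lo]:
        lo += 1
    while hi > lo and not match_flags[hi - 1]:
        hi -= 1
    return lo, hi


def _segment_from_alignment(aln: ProteinAlignment, parent_id: str
                            ) -> ChimeraSegment | None:
    cand_pos = aln.a_start - 1
    par_pos = aln.b_start - 1
    columns: list[tuple[int | None, int | None]] = []
    match_flags: list[bool] = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        c = p = None
        if x != "-":
            cand_pos += 1
            c = cand_pos
        if y != "-":
            par_pos += 1
            p = par_pos
        columns.append((c, p))
        match_flags.append(x != "-" and x == y)
    lo, hi = _trim_bounds(match_flags)
    columns = columns[lo:hi]
    match_flags = match_flags[lo:hi]
    if not columns:
        return None
    matches = sum(match_flags)
    ins = sum(1 for c, p in columns if p is None)
    dels = sum(1 for c, p in columns if c is None)
    cand_cols = [c for c, _ in columns if c is not None]
    par_cols = [p for _, p in columns if p is not None]
    return ChimeraSegment(
        candidate_range=(cand_cols[0], cand_cols[-1]),
        parent_id=parent_id,
        parent_range=(par_cols[0], par_cols[-1]),
        identity=matches / len(columns),
        insertions=ins,
        deletions=dels,
        columns=columns,
    )


def decompose(candidate: str, parents: dict[str, str],
              segment_min_identity: float = 0.85,
              max_rounds: int = 2, min_segment_len: int = 20
              ) -> list[ChimeraSegment]:
    """Decompose ``candidate`` into parental segments.

    For each parent the best local alignment(s) are computed (after the first
    round the already-explained candidate region is masked with X and the
    parent re-aligned, so a parent contributing two blocks is found twice).
    Segments with identity >= ``segment_min_identity`` enter a weighted
    interval-cover selection: maximise candidate positions covered, then
    prefer fewer segments, then lexicographically smaller parent ids.
    Adjacent selected segments may overlap at a homologous junction; the
    overlap is visible in their candidate ranges.  Returns segments ordered
    by candidate start; empty if no parent reaches the threshold.
    """
    if not parents:
        raise ValueError("need at least one parent")
    if not candidate:
        raise ValueError("empty candidate sequence")
    segments: list[ChimeraSegment] = []
    for pid in sorted(parents):
        masked = candidate
        for _ in range(max_rounds):
            aln = local_align_protein(masked, parents[pid])
            if not aln.aligned_a:
                break
            seg = _segment_from_alignment(aln, pid)
            if (seg is None or seg.identity < segment_min_identity
                    or seg.candidate_length < min_segment_len):
                break
            segments.append(seg)
            a, b = seg.candidate_range
            masked = masked[: a - 1] + "X" * (b - a + 1) + masked[b:]
    if not segments:
        return []
    chosen = _select_cover(segments, len(candidate))
    chosen.sort(key=lambda s: (s.candidate_range[0], s.candidate_range[1]))
    return chosen


def _select_cover(segments: list[ChimeraSegment], n: int
                  ) -> list[ChimeraSegment]:
    """Exhaustive weighted cover over <= ~12 segments: maximise covered
    candidate positions; ties -> fewer segments -> lexicographic parent ids."""
    segs = sorted(segments,
                  key=lambda s: -(s.identity * s.candidate_length))[:12]
    best = None
    for r in range(1, len(segs) + 1):
        for combo in combinations(range(len(segs)), r):
            covered = set()
            for i in combo:
                a, b = segs[i].candidate_range
                covered.update(range(a, b + 1))
            pids = tuple(sorted(segs[i].parent_id for i in combo))
            cand = (-len(covered), len(combo), pids)
            if best is None or cand < best[0]:
                best = (cand, combo)
    return [segs[i] for i in best[1]]


def lift_domains(segments: list[ChimeraSegment],
                 domains: list[DomainAnnotation]
                 ) -> list[dict]:
    """Map parent-domain annotations onto candidate coordinates.

    Each domain is mapped column-by-column through the segments of its
    parent.  A domain partially outside its parent's aligned range is
    extended across the junction when an adjacent segment of another parent
    covers the flanking candidate positions — that segment's parent is then
    reported as a second source (the chimeric-domain situation).  A domain
    with no aligned columns at all is reported unmapped.

    Returns dicts: {name, candidate_range (or None), sources, mapped}.
    """
    results = []
    for dom in domains:
        a, b = dom.parent_range
        own = [s for s in segments if s.parent_id == dom.parent_id]
        mapped_cand: list[int] = []
        for seg in own:
            for c, p in seg.columns:
                if p is not None and a <= p <= b and c is not None:
                    mapped_cand.append(c)
        if not mapped_cand:
            results.append({"name": dom.name, "candidate_range": None,
                            "sources": [], "mapped": False})
            continue
        lo, hi = min(mapped_cand), max(mapped_cand)
        sources = {dom.parent_id}
        # parent positions of the domain that did not map through this parent
        mapped_par = {p for seg in own for c, p in seg.columns
                      if p is not None and c is not None and a <= p <= b}
        left_missing = min(mapped_par) - a
        right_missing = b - max(mapped_par)
        if left_missing > 0:
            lo2 = lo - left_missing
            for seg in segments:
                if seg.parent_id == dom.parent_id:
                    continue
                sa, sb = seg.candidate_range
                if sa <= lo - 1 and sb >= lo2:
                    sources.add(seg.parent_id)
                    lo = max(lo2, sa)
                    break
        if right_missing > 0:
            hi2 = hi + right_missing
            for seg in segments:
                if seg.parent_id == dom.parent_id:
                    continue
                sa, sb = seg.candidate_range
                if sb >= hi + 1 and sa <= hi2:
                    sources.add(seg.parent_id)
                    hi = min(hi2, sb)
                    break
        results.append({
            "name": dom.name,
            "candidate_range": (lo, hi),
            "sources": sorted(sources),
            "mapped": True,
        })
    return results
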