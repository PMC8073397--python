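"""Mitotype-specific sequence (MSS) detection.

An MSS is a segment of the query mitogenome with no qualifying alignment to
at least one genome of a comparison panel — the machine that turns a BLAST
coverage profile into the presence/absence matrix used for mitotype
phylogenetics and CMS-candidate screening.  Uniqueness across the whole panel
is *not* required: a segment absent from a single panel genome qualifies.

Default thresholds (all configurable): alignment identity >= 0.90 and
E <= 1e-5 for a hit to confer coverage, gaps <= 50 bp between uncovered runs
are closed, candidates < 100 bp are dropped, and a genome "has" an MSS when
qualifying hits cover >= 80% of its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignParams, local_align
from .genome_io import Genome, Interval
from .orfs import Orf

__all__ = [
    "MssParams",
    "MssRecord",
    "coverage_profile",
    "detect_mss",
    "find_duplicates",
    "annotate_overlaps",
    "presence_matrix_tsv",
]


@dataclass(frozen=True)
class MssParams:
    identity_min: float = 0.90
    min_mss_len: int = 100
    merge_gap: int = 50
    presence_frac: float = 0.8
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class MssRecord:
    """One mitotype-specific segment of the query.

    ``presence`` maps genome id -> bool over query + panel; ``copies`` counts
    occurrences of the segment in the query itself (>= 2 for duplicated MSSs).
    """

    id: str
    location: Interval
    copies: int
    presence: dict[str, bool]

    def length(self, genome_length: int) -> int:
        return self.location.length(genome_length)


def coverage_profile(query: Genome, subject: Genome,
                     params: MssParams | None = None) -> np.ndarray:
    """Boolean vector over query positions: True iff covered by >= 1 hit
    with identity >= identity_min and E <= the aligner threshold."""
    p = params or MssParams()
    covered = np.zeros(len(query.seq), dtype=bool)
    for hit in local_align(query, subject, p.align):
        if hit.identity >= p.identity_min:
            covered[hit.q.start - 1 : hit.q.end] = True
    return covered


def detect_mss(query: Genome, panel: list[Genome],
               params: MssParams | None = None
               ) -> tuple[list[MssRecord], pd.DataFrame]:
    """Detect MSSs of ``query`` against ``panel``.

    Candidate intervals are maximal query runs uncovered in at least one
    panel genome, after closing gaps <= merge_gap and dropping runs shorter
    than min_mss_len; each record's presence vector is then recomputed per
    genome (covered >= presence_frac of the MSS length => present).  Records
    where every genome turns out to carry the segment are discarded (not
    mitotype-specific).  Returns the records (ids M1..Mn in coordinate
    order) and the presence matrix (rows = MSS ids, columns = genome ids,
    query first).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    p = params or MssParams()
    L = len(query.seq)
    profiles = {g.id: coverage_profile(query, g, p) for g in panel}
    uncovered_any = np.zeros(L, dtype=bool)
    for prof in profiles.values():
        uncovered_any |= ~prof
    runs = _runs(uncovered_any)
    runs = _close_gaps(runs, p.merge_gap)
    runs = [(a, b) for a, b in runs if b - a >= p.min_mss_len]

    records: list[MssRecord] = []
    for a, b in runs:
        presence = {query.id: True}
        for g in panel:
            frac = profiles[g.id][a:b].mean()
            presence[g.id] = bool(frac >= p.presence_frac)
        if all(presence.values()):
            continue  # shared after all; not mitotype-specific
        records.append(MssRecord(
            id="", location=Interval(a + 1, b), copies=1, presence=presence))
    records.sort(key=lambda r: (r.location.start, r.location.end))
    for k, rec in enumerate(records, start=1):
        rec.id = f"M{k}"

    find_duplicates(records, query, p)

    cols = [query.id] + [g.id for g in panel]
    matrix = pd.DataFrame(
        [[rec.presence[c] for c in cols] for rec in records],
        index=[rec.id for rec in records], columns=cols, dtype=bool)
    return records, matrix


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 0-based half-open (start, end)."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _close_gaps(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    out = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = out[-1]
        if a - pb <= merge_gap:
            out[-1] = (pa, b)
        else:
            out.append((a, b))
    return out


def find_duplicates(mss: list[MssRecord], query: Genome,
                    params: MssParams | None = None) -> list[MssRecord]:
    """Count additional occurrences of each MSS in the query itself.

    Each MSS sequence is aligned back to the query; hits outside its own
    locus with identity >= identity_min covering >= presence_frac of the MSS
    count as extra copies.  Updates ``copies`` in place and returns the
    records with copies >= 2.
    """
    p = params or MssParams()
    L = len(query.seq)
    dups = []
    for rec in mss:
        seg = query.fetch(rec.location)
        probe = Genome(id=f"{rec.id}_probe", seq=seg)
        extra = 0
        for hit in local_align(probe, query, p.align):
            if hit.identity < p.identity_min:
                continue
            if hit.columns < p.presence_frac * len(seg):
                continue
            if rec.location.overlaps(hit.s, L):
                continue
            extra += 1
        rec.copies = 1 + extra
        if rec.copies >= 2:
            dups.append(rec)
    return dups


def annotate_overlaps(features: list[Orf], mss: list[MssRecord],
                      genome_length: int) -> dict[Orf, list[str]]:
    """Map each ORF to the ids of MSSs it shares >= 1 position with
    (wrap-aware on circular genomes)."""
    out: dict[Orf, list[str]] = {}
    for orf in features:
        ids = [rec.id for rec in mss
               if orf.location.overlaps(rec.location, genome_length)]
        out[orf] = ids
    return out


def presence_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write the presence/absence matrix as 0/1 TSV (rows M1..Mn)."""
    matrix.astype(int).to_csv(path, sep="\t", index_label="mss")
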