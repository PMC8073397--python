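"""End-to-end CMS-candidate screen: ORF scan -> reference discard ->
transmembrane filter -> MSS overlap -> optional chimera decomposition.

The screen mirrors how a chimeric CMS gene is found in practice: predict all
ORFs of >= 70 codons on the sterile line's mitogenome, discard ORFs shared
with the fertile reference mitotype (a hit covering >= 95% of the ORF at
> 99% identity, E <= 1e-5), require a predicted transmembrane segment, and
annotate survivors with overlapping mitotype-specific sequences.  MSS
overlap is reported but not required by default (a candidate can sit in
shared sequence yet still be line-specific at the expression level, which
only wet-lab evidence can decide; the report flags that limitation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import AlignParams, local_align
from .chimera import decompose
from .genome_io import Feature, Genome, write_feature_table
from .mss import MssParams, annotate_overlaps, detect_mss, presence_matrix_tsv
from .orfs import Orf, find_orfs
from .phylo import cse_distance, upgma, write_newick
from .tm import predict_tm

logger = logging.getLogger("mitoscreen")

__all__ = ["ScreenConfig", "CandidateReport", "run_screen", "render_reports"]


@dataclass
class ScreenConfig:
    """Thresholds and inputs of the candidate screen (all configurable)."""

    query: Genome | None = None
    reference: Genome | None = None         # the discard mitotype
    panel: list[Genome] = field(default_factory=list)
    parent_proteins: dict[str, str] = field(default_factory=dict)
    min_codons: int = 70
    identity_discard: float = 0.99
    discard_coverage: float = 0.95
    evalue_max: float = 1e-5
    require_tm: bool = True
    require_mss_overlap: bool = False
    tm_window: int = 19
    tm_threshold: float = 1.6
    mss: MssParams = field(default_factory=MssParams)
    seed: int = 0

    def provenance(self) -> dict:
        return {
            "tool": "mitoscreen",
            "version": __version__,
            "min_codons": self.min_codons,
            "identity_discard": self.identity_discard,
            "discard_coverage": self.discard_coverage,
            "evalue_max": self.evalue_max,
            "require_tm": self.require_tm,
            "require_mss_overlap": self.require_mss_overlap,
            "tm_window": self.tm_window,
            "tm_threshold": self.tm_threshold,
            "mss_identity_min": self.mss.identity_min,
            "mss_min_len": self.mss.min_mss_len,
            "mss_merge_gap": self.mss.merge_gap,
            "mss_presence_frac": self.mss.presence_frac,
            "align_word_size": self.mss.align.word_size,
            "seed": self.seed,
            "note": ("expression-level evidence (RT-PCR) cannot be applied "
                     "computationally; surviving candidates need wet-lab "
                     "confirmation"),
        }


@dataclass
class CandidateRecord:
    orf: Orf
    discarded_by_reference: bool
    tm_segments: list
    mss_ids: list[str]
    duplicate_mss: bool
    chimera_segments: list
    candidate: bool


@dataclass
class CandidateReport:
    records: list[CandidateRecord]
    mss_records: list
    presence_matrix: object
    provenance: dict

    @property
    def candidates(self) -> list[CandidateRecord]:
        return [r for r in self.records if r.candidate]


def run_screen(config: ScreenConfig) -> CandidateReport:
    """Execute the screen; any stage failure aborts with a stage-named error."""
    cfg = config
    if cfg.query is None:
        raise ValueError("screen: query genome required")
    L = len(cfg.query.seq)

    try:
        orfs = find_orfs(cfg.query, min_codons=cfg.min_codons)
        logger.info("orf_scan: %d ORFs >= %d codons", len(orfs), cfg.min_codons)
    except Exception as e:
        raise RuntimeError(f"stage orf_scan failed: {e}") from e

    discarded: dict[Orf, bool] = {}
    try:
        if cfg.reference is not None:
            ap = AlignParams(evalue_max=cfg.evalue_max)
            hits = [h for h in local_align(cfg.query, cfg.reference, ap)
                    if h.identity > cfg.identity_discard]
            for orf in orfs:
                need = cfg.discard_coverage * orf.location.length(L)
                discarded[orf] = any(
                    _cover_len(orf, h, L) >= need for h in hits)
        else:
            discarded = {orf: False for orf in orfs}
        logger.info("reference_discard: %d of %d ORFs discarded",
                    sum(discarded.values()), len(orfs))
    except Exception as e:
        raise RuntimeError(f"stage reference_discard failed: {e}") from e

    try:
        tm = {orf: predict_tm(orf.aa_seq, cfg.tm_window, cfg.tm_threshold)
              for orf in orfs}
    except Exception as e:
        raise RuntimeError(f"stage tm_predict failed: {e}") from e

    mss_records, matrix = [], None
    overlaps: dict[Orf, list[str]] = {orf: [] for orf in orfs}
    try:
        if cfg.panel:
            mss_records, matrix = detect_mss(cfg.query, cfg.panel, cfg.mss)
            overlaps = annotate_overlaps(orfs, mss_records, L)
            logger.info("mss_detect: %d MSSs", len(mss_records))
    except Exception as e:
        raise RuntimeError(f"stage mss_detect failed: {e}") from e

    dup_ids = {r.id for r in mss_records if r.copies >= 2}
    records: list[CandidateRecord] = []
    for orf in orfs:
        surviving = not discarded[orf]
        if cfg.require_tm and not tm[orf]:
            surviving = False
        if cfg.require_mss_overlap and not overlaps[orf]:
            surviving = False
        chim = []
        if surviving and cfg.parent_proteins:
            try:
                chim = decompose(orf.aa_seq, cfg.parent_proteins)
            except Exception as e:
                raise RuntimeError(f"stage chimera failed: {e}") from e
        records.append(CandidateRecord(
            orf=orf,
            discarded_by_reference=discarded[orf],
            tm_segments=tm[orf],
            mss_ids=overlaps[orf],
            duplicate_mss=bool(set(overlaps[orf]) & dup_ids),
            chimera_segments=chim,
            candidate=surviving,
        ))
    return CandidateReport(records=records, mss_records=mss_records,
                           presence_matrix=matrix,
                           provenance=cfg.provenance())


def _cover_len(orf: Orf, hit, L: int) -> int:
    """Query positions of the ORF covered by one hit (wrap-aware)."""
    total = 0
    for a, b in orf.location.to_slices(L):
        c, d = hit.q.start - 1, hit.q.end
        lo, hi = max(a, c), min(b, d)
        if hi > lo:
            total += hi - lo
    return total


def render_reports(report: CandidateReport, outdir: str | Path) -> list[Path]:
    """Write TSV/JSON reports (+ presence matrix and dendrogram when MSSs
    were computed) with stable ordering; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cand_tsv = outdir / "candidates.tsv"
    with open(cand_tsv, "w") as fh:
        fh.write("orf_start\torf_end\tstrand\taa_length\tdiscarded\t"
                 "n_tm_segments\tmss_ids\tduplicate_mss\tn_chimera_segments\t"
                 "candidate\n")
        for r in sorted(report.records,
                        key=lambda r: (r.orf.location.start,
                                       r.orf.location.end)):
            o = r.orf
            fh.write(
                f"{o.location.start}\t{o.location.end}\t"
                f"{'+' if o.location.strand == 1 else '-'}\t{o.aa_length}\t"
                f"{int(r.discarded_by_reference)}\t{len(r.tm_segments)}\t"
                f"{','.join(r.mss_ids)}\t{int(r.duplicate_mss)}\t"
                f"{len(r.chimera_segments)}\t{int(r.candidate)}\n")
    written.append(cand_tsv)

    report_json = outdir / "report.json"
    payload = {
        "provenance": report.provenance,
        "candidates": [
            {
                "start": r.orf.location.start,
                "end": r.orf.location.end,
                "strand": r.orf.location.strand,
                "aa_length": r.orf.aa_length,
                "tm_segments": [[s.start, s.end] for s in r.tm_segments],
                "mss_ids": r.mss_ids,
                "duplicate_mss": r.duplicate_mss,
                "chimera_segments": [
                    {"candidate_range": list(s.candidate_range),
                     "parent": s.parent_id,
                     "parent_range": list(s.parent_range),
                     "identity": s.identity,
                     "insertions": s.insertions,
                     "deletions": s.deletions}
                    for s in r.chimera_segments],
            }
            for r in sorted(report.candidates,
                            key=lambda r: (r.orf.location.start,
                                           r.orf.location.end))
        ],
    }
    with open(report_json, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(report_json)

    if report.presence_matrix is not None and len(report.presence_matrix):
        pm = outdir / "presence_matrix.tsv"
        presence_matrix_tsv(report.presence_matrix, pm)
        written.append(pm)
        if report.presence_matrix.shape[1] >= 2:
            dm = cse_distance(report.presence_matrix)
            tree = upgma(dm)
            nwk = outdir / "mitotypes.nwk"
            write_newick(tree, nwk)
            written.append(nwk)

    mss_tsv = outdir / "mss.tsv"
    feats = [Feature(id=r.id, interval=r.location, type="MSS",
                     attributes=f"copies={r.copies}")
             for r in report.mss_records]
    write_feature_table(feats, mss_tsv)
    written.append(mss_tsv)
    return written
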