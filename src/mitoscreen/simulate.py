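"""Synthetic data with planted truth for every pipeline stage.

The generators emulate the study conditions of a rice CMS mitogenome survey:
a shared circular backbone with mitotype-specific insertions distributed over
a genome panel (optionally duplicated in the query), planted ATG..stop ORFs
with hydrophobic cores, planted exact repeats, protein fusions with a short
homologous junction, and bulk allele-count tables from a segregating
population with one fertility-restorer locus sampled as two bulks of 25
individuals.  Every generator is a pure function of (seed, spec) and returns
a truth dict alongside the data, so recovery can be asserted exactly.

Backbone base composition is uniform (GC 0.5) by default; insertion
sequences are drawn independently of the backbone, which keeps accidental
homology below seed thresholds at the default lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, Interval, revcomp
from .orfs import STOPS

__all__ = [
    "MssSpec", "OrfSpec", "RepeatSpec", "PanelData",
    "gen_panel", "gen_fusion", "gen_bulkseq",
    "random_seq", "make_orf_nt",
]

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# synonymous codon choices per amino acid; varied usage keeps shifted
# reading frames close to random composition (a single fixed codon per
# residue would bias alternative frames toward hydrophobic translations)
_AA_CODONS = {
    "A": ("GCT", "GCA", "GCC"), "C": ("TGT", "TGC"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTT", "TTC"), "G": ("GGT", "GGA"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTA"), "M": ("ATG",), "N": ("AAT", "AAC"),
    "P": ("CCT", "CCA"), "Q": ("CAA", "CAG"), "R": ("CGT", "AGA"),
    "S": ("TCT", "AGT", "TCA"), "T": ("ACT", "ACA"), "V": ("GTT", "GTA"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    return "".join(rng.choice(_NT, size=length, p=[p_at, p_gc, p_gc, p_at]))


def make_orf_nt(rng: np.random.Generator, n_codons: int,
                hydrophobic_core: bool = True, core_len: int = 25) -> str:
    """ATG + (n_codons - 1) sense codons + TAA; optionally a central run of
    leucine codons so the translated protein carries a hydropathy helix."""
    aa = ["M"] + [ _AA20[i] for i in rng.integers(0, 20, size=n_codons - 1) ]
    if hydrophobic_core:
        mid = n_codons // 2
        hydrophobic = "LIVF"
        for i in range(mid, min(mid + core_len, n_codons)):
            aa[i] = hydrophobic[int(rng.integers(0, len(hydrophobic)))]
    nt = "".join(
        _AA_CODONS[a][int(rng.integers(0, len(_AA_CODONS[a])))] for a in aa
    ) + "TAA"
    return nt


@dataclass(frozen=True)
class MssSpec:
    """One planted mitotype-specific insertion: present in the query and in
    the panel genomes listed in ``present_in`` (indices into the panel);
    ``duplicate`` plants a second copy elsewhere in the query."""

    length: int
    present_in: tuple[int, ...] = ()
    duplicate: bool = False


@dataclass(frozen=True)
class OrfSpec:
    """A planted ORF embedded inside the planted insertion ``in_mss``
    (or into the backbone when None); hydrophobic => TM-positive."""

    n_codons: int = 80
    hydrophobic: bool = True
    strand: int = 1
    in_mss: int | None = None


@dataclass(frozen=True)
class RepeatSpec:
    length: int = 2000
    inverted: bool = False


@dataclass
class PanelData:
    query: Genome
    panel: list[Genome]
    truth: dict


def gen_panel(seed: int, backbone_len: int = 100_000, n_genomes: int = 6,
              mss_spec: list[MssSpec] | None = None,
              orf_spec: list[OrfSpec] | None = None,
              repeat_spec: list[RepeatSpec] | None = None,
              gc: float = 0.5, query_id: str = "query") -> PanelData:
    """Generate a circular query + panel sharing a random backbone.

    Planted segments are random sequence inserted at evenly spread backbone
    anchor points; a segment goes into the query and into the panel genomes
    of its presence subset at the homologous anchor.  Truth records every
    planted feature in final query coordinates.
    """
    mss_spec = list(mss_spec or [])
    orf_spec = list(orf_spec or [])
    repeat_spec = list(repeat_spec or [])
    max_ins = max((s.length for s in mss_spec), default=0)
    if max_ins and backbone_len < 10 * max_ins:
        raise ValueError("backbone must be >= 10x the largest insertion")
    rng = np.random.default_rng(seed)
    backbone = random_seq(rng, backbone_len, gc)

    # build insertion sequences; embed planted ORFs inside their MSS
    ins_seqs: list[str] = []
    orf_offsets: dict[int, list[tuple[int, OrfSpec, str]]] = {}
    for i, spec in enumerate(mss_spec):
        s = random_seq(rng, spec.length, gc)
        ins_seqs.append(s)
    for oi, ospec in enumerate(orf_spec):
        nt = make_orf_nt(rng, ospec.n_codons, ospec.hydrophobic)
        if ospec.strand == -1:
            nt = revcomp(nt)
        if ospec.in_mss is None:
            raise ValueError("planted ORFs must sit inside a planted MSS "
                             "(backbone ORFs would be shared by the panel)")
        target = ins_seqs[ospec.in_mss]
        # an in-frame stop guard immediately upstream (in reading direction)
        # pins the ORF start: no chance upstream ATG can extend it
        embed = ("TAA" + nt) if ospec.strand == 1 else (nt + "TTA")
        if len(embed) + 6 > len(target):
            raise ValueError(f"MSS {ospec.in_mss} too short for ORF {oi}")
        off = (len(target) - len(embed)) // 2
        orf_off = off + (3 if ospec.strand == 1 else 0)
        # splice the guarded ORF into the middle of its insertion
        ins_seqs[ospec.in_mss] = (target[:off] + embed
                                  + target[off + len(embed):])
        orf_offsets.setdefault(ospec.in_mss, []).append((orf_off, ospec, nt))

    # anchor points spread over the backbone, in order, non-overlapping
    n_anchors = len(mss_spec) + sum(s.duplicate for s in mss_spec)
    anchors = [int(round(backbone_len * (a + 1) / (n_anchors + 1)))
               for a in range(n_anchors)] if n_anchors else []

    # assemble each genome left-to-right; track query coordinates of inserts
    def build(present: set[int], with_dups: bool) -> tuple[str, list[tuple]]:
        parts = []
        placed = []  # (mss_index, start0, end0, is_duplicate)
        cursor = 0
        a_iter = iter(anchors)
        anchor_jobs = []
        for i, spec in enumerate(mss_spec):
            anchor_jobs.append((next(a_iter), i, False))
        for i, spec in enumerate(mss_spec):
            if spec.duplicate:
                anchor_jobs.append((next(a_iter), i, True))
        anchor_jobs.sort()
        out_len = 0
        for pos, i, is_dup in anchor_jobs:
            take = (i in present) and (not is_dup or with_dups)
            parts.append(backbone[cursor:pos])
            out_len += pos - cursor
            cursor = pos
            if take:
                placed.append((i, out_len, out_len + len(ins_seqs[i]), is_dup))
                parts.append(ins_seqs[i])
                out_len += len(ins_seqs[i])
        parts.append(backbone[cursor:])
        return "".join(parts), placed

    all_idx = set(range(len(mss_spec)))
    qseq, qplaced = build(all_idx, with_dups=True)
    query = Genome(id=query_id, seq=qseq, circular=True)
    panel = []
    for g in range(n_genomes):
        present = {i for i, spec in enumerate(mss_spec) if g in spec.present_in}
        seq, _ = build(present, with_dups=False)
        panel.append(Genome(id=f"panel{g}", seq=seq, circular=True))

    truth_mss = []
    truth_orfs = []
    for i, start0, end0, is_dup in qplaced:
        spec = mss_spec[i]
        truth_mss.append({
            "index": i, "start": start0 + 1, "end": end0,
            "duplicate_copy": is_dup,
            "absent_from": [f"panel{g}" for g in range(n_genomes)
                            if g not in spec.present_in],
        })
        for off, ospec, nt in orf_offsets.get(i, []):
            o0 = start0 + off
            truth_orfs.append({
                "start": o0 + 1, "end": o0 + len(nt),
                "strand": ospec.strand, "aa_length": ospec.n_codons,
                "hydrophobic": ospec.hydrophobic, "in_mss_index": i,
                "duplicate_copy": is_dup,
            })

    # planted repeats: duplicate a backbone slice at the end of the genome
    truth_repeats = []
    qseq2 = query.seq
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def _other(base: str, avoid: str) -> str:
        return base if base != avoid else ("A" if avoid != "A" else "C")

    for rspec in repeat_spec:
        # pick a source slice lying strictly between insertion anchors so it
        # is contiguous in the assembled query
        for _ in range(100):
            src0 = int(rng.integers(1, backbone_len - rspec.length - 1))
            if not any(src0 - 1 < a <= src0 + rspec.length + 1
                       for a in anchors):
                break
        else:
            raise ValueError("could not place planted repeat between anchors")
        unit = backbone[src0: src0 + rspec.length]
        copy = revcomp(unit) if rspec.inverted else unit
        pad = list(random_seq(rng, 97, gc))  # break adjacency
        # flanks of the copy are forced to mismatch the source flanks so the
        # planted pair is maximal at exactly the planted length
        if rspec.inverted:
            left_avoid = comp[backbone[src0 + rspec.length]]
            right_avoid = comp[backbone[src0 - 1]]
        else:
            left_avoid = backbone[src0 - 1]
            right_avoid = backbone[src0 + rspec.length]
        pad[-1] = _other(pad[-1], left_avoid)
        guard = _other("G", right_avoid)
        a0 = qseq2.find(unit)
        qseq2 = qseq2 + "".join(pad) + copy + guard
        b1 = len(qseq2) - 1  # copy ends one base before the trailing guard
        truth_repeats.append({
            "locus_a": (a0 + 1, a0 + rspec.length),
            "locus_b": (b1 - rspec.length + 1, b1),
            "length": rspec.length,
            "orientation": "inverted" if rspec.inverted else "direct",
        })
    if repeat_spec:
        query = Genome(id=query_id, seq=qseq2, circular=True)

    truth = {
        "seed": seed,
        "backbone_len": backbone_len,
        "mss": truth_mss,
        "orfs": truth_orfs,
        "repeats": truth_repeats,
        "genome_ids": [query_id] + [g.id for g in panel],
    }
    return PanelData(query=query, panel=panel, truth=truth)


def gen_fusion(seed: int, parent_lengths: tuple[int, int] = (310, 284),
               breakpoint: int = 202, junction_overlap: int = 6,
               n_indels: int = 0, n_mismatches: int = 0) -> dict:
    """Generate a two-parent protein fusion with a homologous junction.

    Parents P1 and P2 are random proteins sharing ``junction_overlap``
    identical residues immediately before the breakpoint; the candidate is
    ``P1[1..breakpoint] ++ P2[breakpoint+1..]``.  ``n_indels`` extra residues
    are inserted into the candidate's N-segment (candidate-only columns
    relative to P1) and ``n_mismatches`` substitutions are applied to the
    candidate's C-segment (mismatches relative to P2, placed at the terminal
    end first, mirroring a single terminal change).

    Returns {parents: {id: seq}, candidate, truth}.
    """
    l1, l2 = parent_lengths
    if not (junction_overlap < breakpoint < min(l1, l2)):
        raise ValueError("breakpoint must lie inside both parents")
    rng = np.random.default_rng(seed)

    def rand_aa(n):
        return "".join(_AA20[i] for i in rng.integers(0, 20, size=n))

    p1 = list("M" + rand_aa(l1 - 1))
    p2 = list("M" + rand_aa(l2 - 1))
    # homologous junction: P2 agrees with P1 on the overlap window ...
    for k in range(breakpoint - junction_overlap, breakpoint):
        p2[k] = p1[k]
    # ... and the junction boundaries are forced to mismatch so the planted
    # overlap is exactly junction_overlap (no chance extension)
    b0 = breakpoint - junction_overlap - 1
    if b0 >= 0 and p2[b0] == p1[b0]:
        p2[b0] = _AA20[(_AA20.index(p2[b0]) + 1) % 20]
    if p1[breakpoint] == p2[breakpoint]:
        p1[breakpoint] = _AA20[(_AA20.index(p1[breakpoint]) + 1) % 20]
    p1 = "".join(p1)
    p2 = "".join(p2)

    cand = list(p1[:breakpoint] + p2[breakpoint:])
    # substitutions in the C segment, terminal-first
    mism_positions = []
    for m in range(n_mismatches):
        pos = len(cand) - 1 - m
        old = cand[pos]
        choices = [a for a in _AA20 if a != old]
        cand[pos] = choices[int(rng.integers(0, len(choices)))]
        mism_positions.append(pos + 1)
    # insertions in the N segment (shift downstream coordinates)
    indel_positions = []
    for k in range(n_indels):
        pos = int(rng.integers(10, breakpoint - junction_overlap - 10))
        cand.insert(pos, _AA20[int(rng.integers(0, 20))])
        indel_positions.append(pos + 1)
    candidate = "".join(cand)

    bp_cand = breakpoint + n_indels
    truth = {
        "seed": seed,
        "breakpoint_parent": breakpoint,
        "junction_overlap": junction_overlap,
        "n_segment": {"parent": "P1", "candidate_range": (1, bp_cand),
                      "parent_range": (1, breakpoint), "insertions": n_indels},
        "c_segment": {"parent": "P2",
                      "candidate_range": (bp_cand - junction_overlap + 1,
                                          len(candidate)),
                      "parent_range": (breakpoint - junction_overlap + 1, l2),
                      "mismatches": n_mismatches},
        "mismatch_positions": mism_positions,
        "insertion_positions": indel_positions,
    }
    return {"parents": {"P1": p1, "P2": p2}, "candidate": candidate,
            "truth": truth}


def gen_bulkseq(seed: int, n_snps: int = 400, chrom_len: int = 20_000_000,
                depth_mean: float = 50.0, bulk_size: int = 25,
                qtl_pos: int | None = 10_000_000,
                recomb_rate: float = 4e-8, chrom: str = "chr10",
                qtl_effect: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-bulk allele-count table with one planted restorer locus.

    ``bulk_size`` individuals per bulk (default 25).  Bulk 1 is fixed for the
    donor (restorer) allele at ``qtl_pos``, bulk 2 fixed against it, with
    ``qtl_effect`` scaling the selection (0 => null segregation in both
    bulks).  At a marker at genetic distance d Morgans from the locus the
    recombination fraction is c = (1 - exp(-2d))/2 (Haldane), so a selected
    homozygote carries the donor allele on each chromosome with probability
    1 - c.  Read depths are Poisson(depth_mean), counts Binomial(depth, f).

    Returns (AlleleCountTable DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=n_snps,
                             replace=False))
    if qtl_pos is None or qtl_effect == 0.0:
        p_hi = np.full(n_snps, 0.5)
        p_lo = np.full(n_snps, 0.5)
    else:
        d = np.abs(pos - qtl_pos) * recomb_rate  # Morgans
        c = 0.5 * (1.0 - np.exp(-2.0 * d))
        p_sel_hi = 1.0 - c       # donor-allele prob per chromosome, bulk 1
        p_sel_lo = c             # bulk 2
        p_hi = qtl_effect * p_sel_hi + (1 - qtl_effect) * 0.5
        p_lo = qtl_effect * p_sel_lo + (1 - qtl_effect) * 0.5

    n_chrom = 2 * bulk_size
    f1 = rng.binomial(n_chrom, p_hi) / n_chrom
    f2 = rng.binomial(n_chrom, p_lo) / n_chrom
    depth1 = rng.poisson(depth_mean, size=n_snps)
    depth2 = rng.poisson(depth_mean, size=n_snps)
    alt1 = rng.binomial(depth1, f1)
    alt2 = rng.binomial(depth2, f2)
    table = pd.DataFrame({
        "chrom": chrom,
        "pos": pos.astype(int),
        "ref_count_bulk1": (depth1 - alt1).astype(int),
        "alt_count_bulk1": alt1.astype(int),
        "ref_count_bulk2": (depth2 - alt2).astype(int),
        "alt_count_bulk2": alt2.astype(int),
    })
    truth = {
        "seed": seed, "chrom": chrom, "chrom_len": chrom_len,
        "qtl_pos": qtl_pos, "qtl_effect": qtl_effect,
        "bulk_size": bulk_size, "depth_mean": depth_mean,
        "n_snps": n_snps,
    }
    return table, truth
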