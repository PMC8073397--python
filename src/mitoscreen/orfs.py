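"""Six-frame ORF prediction on circular mitochondrial genomes.

An ORF here is a maximal ATG-to-stop reading frame: for every stop codon, the
most upstream ATG downstream of the previous in-frame stop opens the ORF.
Plant mitochondria use the standard genetic code.  The reported interval
includes the stop codon, so a 312-aa protein occupies 939 nt
(3 * (312 + 1)); an ORF crossing the origin of a circular genome is reported
once, with a wrapping interval.  Codons containing N translate to X and N
terminates ORFs conservatively (an ORF whose span contains an N-codon is
still reported only if no stop intervenes; the N codon itself cannot be a
start or stop).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Genome, Interval, revcomp

__all__ = ["Orf", "translate", "find_orfs", "CODON_TABLE"]

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

STOPS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def translate(codons: str) -> str:
    """Standard-code translation; any codon containing N becomes X,
    stop codons become '*'.  Length must be divisible by 3."""
    if len(codons) % 3:
        raise ValueError(f"sequence length {len(codons)} not divisible by 3")
    out = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class Orf:
    """An open reading frame; ``location`` includes the stop codon and
    ``aa_seq`` excludes it (so span = 3 * (len(aa_seq) + 1))."""

    location: Interval
    aa_seq: str
    frame: int

    @property
    def aa_length(self) -> int:
        return len(self.aa_seq)


def find_orfs(genome: Genome, min_codons: int = 70,
              start_codons: tuple[str, ...] = ("ATG",)) -> list[Orf]:
    """All maximal start-to-stop ORFs with >= ``min_codons`` amino acids.

    Both strands are scanned; circular genomes are scanned on the doubled
    sequence and ORFs whose canonical start lies in the second copy are
    deduplicated, so origin-crossing ORFs are reported exactly once with a
    wrapping interval.  For nested starts sharing a stop the most upstream
    start wins.  A stop codon is required (ORFs running off a linear
    sequence end are not reported).
    """
    L = len(genome.seq)
    scan_seq = genome.seq * 2 if genome.circular else genome.seq
    found: dict[tuple[int, int, int], Orf] = {}
    for strand in (1, -1):
        seq = scan_seq if strand == 1 else revcomp(scan_seq)
        for offset in range(3):
            _scan_frame(seq, offset, strand, genome, min_codons,
                        start_codons, found)
    orfs = sorted(found.values(),
                  key=lambda o: (o.location.start, o.location.end,
                                 o.location.strand))
    return orfs


def _scan_frame(seq: str, offset: int, strand: int, genome: Genome,
                min_codons: int, start_codons: tuple[str, ...],
                found: dict) -> None:
    L = len(genome.seq)
    n_codons = (len(seq) - offset) // 3
    open_start: int | None = None  # codon index of most upstream start
    for ci in range(n_codons):
        pos = offset + 3 * ci
        codon = seq[pos : pos + 3]
        if codon in STOPS:
            if open_start is not None:
                start_pos = offset + 3 * open_start
                aa_count = ci - open_start
                if aa_count >= min_codons:
                    _emit(seq, start_pos, pos + 3, strand, genome, found)
            open_start = None
        elif open_start is None and codon in start_codons and "N" not in codon:
            open_start = ci


def _emit(seq: str, a: int, b: int, strand: int, genome: Genome,
          found: dict) -> None:
    """Record the ORF at scan coordinates [a, b) on ``seq`` (which may be the
    doubled and/or reverse-complemented genome)."""
    L = len(genome.seq)
    span = b - a
    if span > len(genome.seq):
        return  # frame circling the whole genome more than once
    nt = seq[a : b - 3]
    aa = translate(nt)
    if "*" in aa:  # cannot happen by construction; defensive
        return
    # map to forward-genome 0-based [f0, f1)
    scan_len = len(seq)
    if strand == 1:
        f0, f1 = a, b
    else:
        f0, f1 = scan_len - b, scan_len - a
    # canonicalise onto the first copy for circular genomes
    shift = (f0 // L) * L
    f0 -= shift
    f1 -= shift
    if not genome.circular and f1 > L:
        return
    if f1 <= L:
        iv = Interval(f0 + 1, f1, strand)
    else:
        iv = Interval(f0 + 1, f1 - L, strand)
    frame = strand * ((f0 % 3) + 1) if strand == 1 else strand * (((L - f1) % 3) + 1)
    # ORFs sharing a stop codon are the same ORF (nested starts); key by the
    # canonical stop position and keep the most upstream start
    stop_anchor = iv.end if strand == 1 else iv.start
    key = (strand, stop_anchor)
    prev = found.get(key)
    if prev is None or len(aa) > len(prev.aa_seq):
        found[key] = Orf(location=iv, aa_seq=aa, frame=frame)
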