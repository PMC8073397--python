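# Methods

This note records the models, defaults and design choices behind each stage,
what the synthetic data does and does not emulate, and the numerical
conventions a maintainer needs.

## Coordinates and circularity

All reported coordinates are 1-based inclusive on the forward strand (the
GenBank convention, so printed gene coordinates such as 259,955–260,893
round-trip unchanged); internal arithmetic is 0-based half-open with a single
conversion layer in `Interval`. Circular genomes are stored linearised at an
arbitrary origin; a wrapping interval has `end < start` and length
`(L − start + 1) + end`. Scanning operations (ORF calling, repeat finding,
alignment against a circular subject) run on the doubled sequence and
canonicalise features whose representative position falls in the second
copy. `N` never matches in alignment and a codon containing `N` translates
to `X`; `N` cannot form a start or stop codon.

## Local nucleotide alignment

The aligner is a seed-and-extend design standing in for a local BLAST
search: exact 11-mer seeds (2-bit integer codes joined vectorially) are
merged into maximal exact runs per diagonal, nearby runs are chained when
the gap on both axes is ≤ 32 (the band), bridges between chained runs are
scored by an affine Needleman–Wunsch (tie-break diagonal > up > left), the
chain is trimmed to its best local sub-chain, and both ends receive a banded
free-end extension (X-drop 40). Scoring is +1/−2 with gap costs
`open 5 + 2·g` per gap of length g; E-values use the ungapped
Karlin–Altschul form `K·m·n·e^(−λS)` with the published constants for +1/−2
(λ = 1.28, K = 0.46) and threshold E ≤ 10⁻⁵. Two heuristics keep the search
near-linear on mitogenome-scale inputs: chains seeded by fewer than
2·word−1 exactly matching bases are scored without gapped extension (chance
word collisions; they cannot reach the E-value threshold), and a chain whose
query *and* subject spans already lie under a larger accepted hit is skipped
(it would be removed by the maximality rule anyway). Overlap pruning keeps a
hit only if < 50 % of its query span is covered by a higher-scoring hit of
the same subject region; hits at distinct subject loci are never pruned
against each other, which is what makes duplicate-copy counting work. On
long, high-identity alignments — the regime of mitogenome comparisons —
the reported score equals the Smith–Waterman optimum (asserted against an
independent dynamic-programming oracle); parity with any particular BLAST
release's hit list is not claimed.

Protein alignment (global and local, BLOSUM62, gap `11 + 1·g`) is delegated
to Biopython's `PairwiseAligner`; an exhaustive affine-gap recursion serves
as its oracle in the tests.

## ORF scanning

Maximal ATG→stop frames with ≥ 70 amino acids are reported on both strands;
70 is interpreted as 70 codons of coding sequence (≥ 70 aa), the
amino-acid unit used by annotation tools in this field. For nested starts
sharing a stop the most upstream ATG wins; ORFs are deduplicated by their
stop codon so an origin-crossing ORF on a circular genome is reported once,
with a wrapping interval. A stop codon is required — an open frame running
off a linear sequence end is not reported; this keeps the invariant
`span = 3·(aa + 1)` unconditional. Alternative start codons are off by
default but configurable.

## Transmembrane calling

A Kyte–Doolittle sliding window (window 19, threshold 1.6 — the values
proposed for membrane-spanning stretches) declares a segment wherever
qualifying windows overlap; the candidate screen uses only presence/absence
of ≥ 1 segment. A merged segment's `mean_hydropathy` is defined as the mean
of its qualifying window means, which guarantees the value is ≥ the calling
threshold (a plain residue mean over a merged segment does not); on a
uniform stretch the two definitions coincide. This is a declared
hydropathy-window substitute for an HMM topology predictor: it reproduces
presence-level calls, not helix counts or sidedness.

## Mitotype-specific sequences

A position of the query is covered with respect to a panel genome if some
alignment hit with identity ≥ 0.90 and E ≤ 10⁻⁵ spans it. Candidate MSS
intervals are maximal runs uncovered in ≥ 1 panel genome, after closing gaps
≤ 50 bp and dropping runs < 100 bp (consistent with the smallest MSS size
the method is expected to resolve); each record's presence vector is then
recomputed per genome — covered ≥ 80 % of the MSS length ⇒ present — and
records present everywhere are discarded. Specificity means *absent from at
least one* panel genome, not unique across all. Duplicate copies are counted
by re-aligning each MSS against the query and counting hits outside its own
locus at the same identity threshold covering ≥ 80 % of its length. All five
thresholds are parameters of `MssParams`. Recovered boundaries sit within a
few tens of bp of planted truth because chance flank matches at insertion
edges extend hits slightly; the tests assert boundaries within the 50 bp
merge tolerance.

## Chord distance and UPGMA

Each MSS is a biallelic locus with allele frequency 0/1 per genome; the
per-locus chord distance is `(2/π)·√(2(1 − cos θ))` with `cos θ = 1` on
agreement and 0 otherwise, averaged over loci — hence
`D = (2√2/π)·Hamming fraction` (≈ 0.9003 at complete disagreement). Any
chord-distance variant on binary profiles is a monotone transform of the
Hamming fraction, so the UPGMA topology is insensitive to the convention.
UPGMA uses proportional (size-weighted) averaging with merge height d/2;
ties are broken by the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest leaf label), making the tree deterministic.
Newick output quotes labels containing characters outside
`[A-Za-z0-9_.\-|]`.

## Repeats

Maximal exact repeated pairs (direct and inverted, default ≥ 1 kb) are found
by 31-mer anchoring with per-diagonal merging — within a maximal exact
stretch every interior k-mer matches, so merged runs are exactly maximal —
plus end extension and canonical deduplication on the doubled sequence for
circular genomes. A family of c copies yields C(c,2) pairs;
`group_families` provides the family view so either counting convention can
be read off. Tandem self-overlapping pairs are flagged. Mismatch-tolerant
repeats are out of scope.

## Chimera decomposition

Each parent is locally aligned to the candidate (two rounds, masking the
explained region with X between rounds, so one parent can contribute two
blocks). Segments must reach 0.85 identity — matches over aligned columns,
indel columns counting against — and ≥ 20 aa. Terminal columns are trimmed
until each end opens with a solidly homologous window (≥ 4 matches in 6
columns) and sits on an exact match: a local alignment can drift past a
fusion junction on chance score-positive columns, and without trimming the
junction overlap would be overstated. Segment selection maximises candidate
positions covered, then prefers fewer segments, then lexicographically
smaller parent ids (exhaustive over the ≤ 12 best-weighted segments).
Domain annotations are user-supplied coordinates on parents, mapped
column-by-column; a domain whose parent range extends beyond the aligned
region is continued across the junction into an adjacent segment of another
parent, which is then reported as a second source — the chimeric-domain
situation. For indel-free fusions the lift returns planted coordinates
exactly (asserted).

## QTL-seq statistics

SNP-index = alt/(ref + alt) per bulk at sites with depth ≥ 10 in both bulks
(lower-depth sites are flagged and excluded, not errors);
ΔSNP-index = index₁ − index₂. Windows of 2 Mb at 50 kb steps average
per-SNP deltas; the window band is the mean of the per-SNP bands, the
convention of QTL-seq software. The null model draws each bulk's allele
frequency as `Binomial(2·25, ½)/(2·25)` — 25 individuals per bulk under
F2-equivalent 1:2:1 segregation — then read counts `Binomial(depth, f)`
independently per bulk, 10,000 simulations per distinct depth, quantiles at
α/2 and 1 − α/2 for α ∈ {0.05, 0.01}; each site's band uses the smaller of
its two bulk depths. QTL regions are maximal runs of windows outside the
95 % band, flagged when any window clears the 99 % band, with the peak
window recorded; localisation is measured at the peak. The windowing values
are package defaults chosen from common QTL-seq practice; the population
model is configurable in principle through the generator but only the
F2-equivalent null is implemented.

## Synthetic data

`gen_panel` builds a uniform-random (GC 0.5, adjustable) circular backbone
shared by the query and panel; each planted insertion is independent random
sequence placed at evenly spread anchor points, inserted into the query and
into its presence subset of panel genomes at the homologous anchor;
duplicates add a second query-only copy. Planted ORFs are spliced into the
middle of an insertion with an in-frame stop guard immediately upstream in
reading direction, which pins the reported start (otherwise a chance
upstream in-frame ATG would legitimately extend the ORF). Codon usage is
randomised over synonymous codons; a fixed one-codon-per-residue table
would bias shifted reading frames toward hydrophobic translations and
create spurious TM-positive ORFs. Planted repeats copy a backbone slice
(placed between anchors so it is contiguous in the assembled query) to the
genome end, with flanking bases forced to mismatch so the planted pair is
maximal at exactly the planted length. `gen_fusion` likewise forces
mismatches at the junction-window boundaries so the planted homologous
overlap is exact. `gen_bulkseq` samples per-marker donor-allele
probabilities under Haldane recombination decay from the planted locus with
complete selection in opposite directions for the two bulks, Poisson depths
and binomial read counts.

What the generators do **not** emulate: real base composition and repeat
structure of plant mitogenomes, sequencing error, alignment ambiguity from
diverged (sub-90 %-identity) homology, structural variation other than clean
insertions, and multi-locus or partially penetrant restoration. Passing the
planted-truth suites therefore demonstrates correctness of the algorithms
under clean study conditions, not robustness to noisy real data; on real
accessions the MSS count is sensitive to the alignment thresholds, which is
why they are all exposed as parameters.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use a 6-genome panel on a 100 kb
backbone (the mitogenome-scale regime at a size where the full suite runs in
well under a minute per stage), ≤ 200 bp / ≤ 30 aa inputs for the
dynamic-programming oracle equivalences, ≤ 5 kb genomes for the ORF-scan
oracle, ≤ 2 kb for the repeat oracle, 2,000 null SNPs × 10,000 simulations
for band coverage, and 10–20 seeded replicates of 400-SNP crosses for
restorer-locus localisation.

## Known limitations

- The aligner's oracle equality holds in the high-identity regime; highly
  diverged pairs (no shared 11-mer near the optimal path) can score below
  the Smith–Waterman optimum, as with any seeded heuristic.
- Wrapping subject intervals are excluded from overlap pruning comparisons
  (kept conservatively).
- The reference-discard rule needs a coverage contract on top of the
  identity threshold; ≥ 95 % of the ORF under a single hit is the default
  and is configurable.
- Helix counts/topology, bootstrap support, mismatch-tolerant repeats,
  nucleotide-level chimera breakpoints and read-level simulation are out of
  scope.
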