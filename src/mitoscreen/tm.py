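"""Transmembrane-segment calling by Kyte-Doolittle hydropathy windows.

A sliding window of 19 residues (the canonical helix-spanning width) is
scored with the Kyte-Doolittle scale; maximal unions of overlapping windows
whose mean hydropathy reaches the threshold (default 1.6, the value Kyte and
Doolittle proposed for membrane-spanning stretches at window 19) are reported
as transmembrane segments.  The candidate screen only uses the
presence/absence of at least one segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["TmSegment", "predict_tm", "hydropathy_profile", "KYTE_DOOLITTLE"]

KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class TmSegment:
    """A called transmembrane segment, 1-based inclusive on the protein.

    ``mean_hydropathy`` is the mean of the qualifying window means inside the
    segment (which is therefore always >= the calling threshold); on a
    uniform stretch it equals the plain residue mean.
    """

    start: int
    end: int
    mean_hydropathy: float


def hydropathy_profile(aa_seq: str, window: int = 19) -> list[float]:
    """Mean Kyte-Doolittle hydropathy of each window; entry i corresponds to
    the window starting at 1-based residue i+1."""
    values = [KYTE_DOOLITTLE.get(c, 0.0) for c in aa_seq]
    if len(values) < window:
        return []
    out = []
    s = sum(values[:window])
    out.append(s / window)
    for i in range(window, len(values)):
        s += values[i] - values[i - window]
        out.append(s / window)
    return out


def predict_tm(aa_seq: str, window: int = 19,
               threshold: float = 1.6) -> list[TmSegment]:
    """Maximal merged runs of windows whose hydropathy mean >= threshold.

    A sequence shorter than the window yields an empty result with a warning.
    """
    if len(aa_seq) < window:
        warnings.warn(
            f"sequence of {len(aa_seq)} aa shorter than window {window}; "
            "no segments called", stacklevel=2)
        return []
    means = hydropathy_profile(aa_seq, window)
    segments: list[TmSegment] = []
    i = 0
    n = len(means)
    while i < n:
        if means[i] < threshold:
            i += 1
            continue
        j = i
        # windows overlap when their starts are < `window` apart; merge any
        # qualifying window that overlaps the growing segment
        seg_end_win = i
        qual = [means[i]]
        j = i + 1
        while j < n:
            if means[j] >= threshold and j <= seg_end_win + window:
                seg_end_win = j
                qual.append(means[j])
                j += 1
            elif j <= seg_end_win + window - 1:
                j += 1  # non-qualifying window inside overlap range; keep looking
            else:
                break
        start = i + 1                     # 1-based residue of first window
        end = seg_end_win + window        # last residue of last window
        segments.append(TmSegment(start, end, sum(qual) / len(qual)))
        i = seg_end_win + window  # restart past the merged segment
    return segments
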