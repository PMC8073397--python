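"""Bulked-segregant (QTL-seq) statistics: SNP-index, delta-SNP-index,
sliding-window smoothing and simulation-based null confidence bands.

The SNP-index of a bulk at a site is alt/(ref+alt), the fraction of reads
carrying the donor-parent allele; delta = index_bulk1 - index_bulk2.  Under
the null of no QTL, both bulks are random draws of ``bulk_size`` individuals
from the segregating population, so per-depth confidence bands are obtained
by Monte Carlo: draw each bulk's allele frequency from the null segregation
model (F2-equivalent 1:2:1 by default, i.e. per-individual allele dose
Binomial(2, 1/2)/2), then draw read counts binomially at the observed depth,
and take the delta quantiles.  A window's band is the mean of the per-SNP
bands of the sites it contains, the convention used by QTL-seq software.

Defaults: minimum depth 10, window 2 Mb, step 50 kb, 10,000 simulations,
bulks of 25 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import Interval

__all__ = [
    "snp_index",
    "compute_snp_stats",
    "null_confidence",
    "delta_windows",
    "call_qtl",
    "QtlRegion",
]

MIN_DEPTH_DEFAULT = 10


def snp_index(ref_count: int, alt_count: int,
              min_depth: int = MIN_DEPTH_DEFAULT) -> float:
    """alt/(ref+alt); NaN (filtered, not an error) below ``min_depth``."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    depth = ref_count + alt_count
    if depth < min_depth:
        return float("nan")
    return alt_count / depth


def compute_snp_stats(table: pd.DataFrame,
                      min_depth: int = MIN_DEPTH_DEFAULT) -> pd.DataFrame:
    """Per-SNP indices and delta from an allele-count table.

    Adds columns index_bulk1, index_bulk2, delta, depth1, depth2 and a
    ``filtered`` flag for sites below ``min_depth`` in either bulk (their
    indices are NaN and they are excluded from window means).
    """
    df = table.copy()
    df["depth1"] = df.ref_count_bulk1 + df.alt_count_bulk1
    df["depth2"] = df.ref_count_bulk2 + df.alt_count_bulk2
    df["filtered"] = (df.depth1 < min_depth) | (df.depth2 < min_depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        i1 = df.alt_count_bulk1 / df.depth1
        i2 = df.alt_count_bulk2 / df.depth2
    df["index_bulk1"] = i1.where(~df.filtered)
    df["index_bulk2"] = i2.where(~df.filtered)
    df["delta"] = df.index_bulk1 - df.index_bulk2
    return df


def null_confidence(depths: np.ndarray | list[int], bulk_size: int = 25,
                    n_sims: int = 10_000, alphas: tuple[float, ...] = (0.05, 0.01),
                    seed: int = 0, population: str = "F2"
                    ) -> dict[int, dict[float, tuple[float, float]]]:
    """Per-depth null quantile bands of delta-SNP-index.

    For every unique depth, ``n_sims`` null draws are simulated: each bulk's
    allele frequency is the mean dose of ``bulk_size`` individuals drawn from
    the segregation model, read counts are Binomial(depth, freq) per bulk,
    and delta = index1 - index2.  Returns
    ``{depth: {alpha: (lo, hi)}}`` with lo/hi the alpha/2 and 1 - alpha/2
    quantiles.  Reproducible under ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if population != "F2":
        raise ValueError(f"unknown population model {population!r}")
    rng = np.random.default_rng(seed)
    uniq = sorted(set(int(d) for d in depths))
    # under 1:2:1 the bulk allele count over 2*bulk_size chromosomes is
    # Binomial(2*bulk_size, 1/2)
    out: dict[int, dict[float, tuple[float, float]]] = {}
    for depth in uniq:
        f1 = rng.binomial(2 * bulk_size, 0.5, size=n_sims) / (2 * bulk_size)
        f2 = rng.binomial(2 * bulk_size, 0.5, size=n_sims) / (2 * bulk_size)
        d1 = rng.binomial(depth, f1) / depth
        d2 = rng.binomial(depth, f2) / depth
        delta = d1 - d2
        bands = {}
        for alpha in alphas:
            lo, hi = np.quantile(delta, [alpha / 2, 1 - alpha / 2])
            bands[alpha] = (float(lo), float(hi))
        out[depth] = bands
    return out


@dataclass(frozen=True)
class SnpWindowStat:
    chrom: str
    window: Interval
    mean_delta: float
    n_snps: int
    ci95: tuple[float, float]
    ci99: tuple[float, float]


def delta_windows(table: pd.DataFrame, window_bp: int = 2_000_000,
                  step_bp: int = 50_000, min_depth: int = MIN_DEPTH_DEFAULT,
                  bulk_size: int = 25, n_sims: int = 10_000, seed: int = 0,
                  chrom_lengths: dict[str, int] | None = None
                  ) -> list[SnpWindowStat]:
    """Sliding-window mean delta with per-window null bands.

    Windows tile each chromosome at ``step_bp``; a window's mean is the
    arithmetic mean of per-SNP deltas of unfiltered sites inside it, and its
    band the mean of those sites' per-depth null bands.  Empty windows are
    reported with n_snps = 0 and NaN statistics.
    """
    stats = compute_snp_stats(table, min_depth)
    usable = stats[~stats.filtered]
    pair_depth = np.minimum(usable.depth1, usable.depth2).astype(int)
    bands = null_confidence(pair_depth.tolist() or [min_depth],
                            bulk_size=bulk_size, n_sims=n_sims, seed=seed)
    out: list[SnpWindowStat] = []
    for chrom, sub in stats.groupby("chrom", sort=False):
        length = (chrom_lengths or {}).get(chrom, int(sub.pos.max()))
        sub_ok = sub[~sub.filtered]
        depths = np.minimum(sub_ok.depth1, sub_ok.depth2).astype(int).to_numpy()
        pos = sub_ok.pos.to_numpy()
        delta = sub_ok.delta.to_numpy()
        start = 1
        while start <= length:
            end = min(start + window_bp - 1, length)
            m = (pos >= start) & (pos <= end)
            n = int(m.sum())
            if n:
                mean_delta = float(delta[m].mean())
                lo95 = float(np.mean([bands[d][0.05][0] for d in depths[m]]))
                hi95 = float(np.mean([bands[d][0.05][1] for d in depths[m]]))
                lo99 = float(np.mean([bands[d][0.01][0] for d in depths[m]]))
                hi99 = float(np.mean([bands[d][0.01][1] for d in depths[m]]))
            else:
                mean_delta = float("nan")
                lo95 = hi95 = lo99 = hi99 = float("nan")
            out.append(SnpWindowStat(
                chrom=chrom, window=Interval(start, end),
                mean_delta=mean_delta, n_snps=n,
                ci95=(lo95, hi95), ci99=(lo99, hi99)))
            if end >= length:
                break
            start += step_bp
    return out


@dataclass(frozen=True)
class QtlRegion:
    chrom: str
    interval: Interval
    peak_delta: float
    peak_window: Interval
    significant_99: bool


def call_qtl(windows: list[SnpWindowStat]) -> list[QtlRegion]:
    """Maximal runs of consecutive windows whose mean delta falls outside
    the 95% band, flagged when any window also clears the 99% band."""
    regions: list[QtlRegion] = []
    by_chrom: dict[str, list[SnpWindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        run: list[SnpWindowStat] = []
        for w in ws + [None]:
            outside = (
                w is not None and w.n_snps > 0
                and not np.isnan(w.mean_delta)
                and (w.mean_delta < w.ci95[0] or w.mean_delta > w.ci95[1])
            )
            if outside:
                run.append(w)
                continue
            if run:
                peak = max(run, key=lambda x: abs(x.mean_delta))
                sig99 = any(x.mean_delta < x.ci99[0] or x.mean_delta > x.ci99[1]
                            for x in run)
                regions.append(QtlRegion(
                    chrom=chrom,
                    interval=Interval(run[0].window.start, run[-1].window.end),
                    peak_delta=peak.mean_delta,
                    peak_window=peak.window,
                    significant_99=sig99))
                run = []
    return regions
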