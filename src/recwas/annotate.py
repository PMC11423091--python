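"""Interval-arithmetic validation of significant peaks.

Once an association scan flags peaks, their biological plausibility is
scored against external evidence layers: GWAS risk regions (SNPs flanked by
a fixed window), disease-susceptibility gene regions, nearest-gene
distances, and enhancer-domain-score (EDS) gene windows.  All coordinates
are BED-style 0-based half-open; risk/susceptibility overlap means any
shared base, while EDS windows count peak *centers* falling inside a
flanked gene window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .genio import PeakRegion

__all__ = ["AnnotationRegion", "expand_to_regions", "overlap_proportion",
           "nearest_feature_distance", "eds_window_counts"]


@dataclass(frozen=True)
class AnnotationRegion:
    """A labelled genomic interval, optionally scored (e.g. EDS)."""
    chrom: str
    start: int
    end: int
    label: str = ""
    score: float = np.nan

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"region {self.label}: start {self.start} >= end {self.end}")


def _as_interval(item) -> tuple[str, int, int, str, float]:
    """Normalize SNP points (chrom, 1-based pos) and intervals."""
    if isinstance(item, (PeakRegion,)):
        return item.chrom, item.start, item.end, item.peak_id, np.nan
    if isinstance(item, AnnotationRegion):
        return item.chrom, item.start, item.end, item.label, item.score
    if len(item) == 2:  # (chrom, 1-based point)
        chrom, pos = item
        return str(chrom), int(pos), int(pos) + 1, f"{chrom}:{pos}", np.nan
    chrom, start, end = item[0], int(item[1]), int(item[2])
    label = str(item[3]) if len(item) > 3 else f"{chrom}:{start}-{end}"
    score = float(item[4]) if len(item) > 4 else np.nan
    return str(chrom), start, end, label, score


def expand_to_regions(points_or_intervals: Iterable,
                      flank_bp: int) -> list[AnnotationRegion]:
    """Flank each input by ``flank_bp`` on both sides, clamping at zero.

    Overlapping same-label regions are deliberately *not* merged: counts
    downstream are per region.  A (chrom, pos) pair is treated as a 1-bp
    point at the given position.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    out = []
    for item in points_or_intervals:
        chrom, start, end, label, score = _as_interval(item)
        out.append(AnnotationRegion(chrom, max(0, start - flank_bp),
                                    end + flank_bp, label, score))
    return out


def _overlaps(p_start, p_end, r_start, r_end) -> bool:
    """Half-open interval intersection is non-empty."""
    return p_start < r_end and r_start < p_end


def overlap_proportion(peaks: Sequence[PeakRegion],
                       regions: Sequence[AnnotationRegion]):
    """Fraction of peaks sharing at least one base with any region.

    Returns ``(fraction, flags)`` with one boolean per peak.
    """
    if len(peaks) == 0:
        raise DegenerateDataError("no peaks: overlap fraction undefined")
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    flags = []
    for p in peaks:
        hits = by_chrom.get(p.chrom, ())
        flags.append(any(_overlaps(p.start, p.end, s, e) for s, e in hits))
    flags = np.array(flags, dtype=bool)
    return float(flags.mean()), flags


def nearest_feature_distance(peaks: Sequence[PeakRegion],
                             features: Sequence[AnnotationRegion]
                             ) -> np.ndarray:
    """Shortest boundary gap from each peak to any same-chromosome feature.

    Overlapping intervals are at distance 0; a chromosome with no features
    yields +inf for its peaks.
    """
    by_chrom: dict[str, list] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    out = np.full(len(peaks), np.inf)
    for i, p in enumerate(peaks):
        best = np.inf
        for s, e in by_chrom.get(p.chrom, ()):
            if _overlaps(p.start, p.end, s, e):
                best = 0.0
                break
            gap = max(s - p.end, p.start - e)
            best = min(best, float(gap))
        out[i] = best
    return out


def eds_window_counts(peaks: Sequence[PeakRegion],
                      gene_table: pd.DataFrame,
                      flank_bp: int = 100_000):
    """Peak-center containment counts in flanked gene windows.

    ``gene_table`` needs columns gene, chrom, start, end, eds_score.
    Duplicate transcripts (same gene, chrom, start, end) are dropped.
    Returns ``(gene_counts, peak_counts)``: per gene, the number of peak
    centers inside its +-flank window together with the gene's EDS
    percentile rank; per peak, the number of gene windows containing its
    center.
    """
    required = {"gene", "chrom", "start", "end", "eds_score"}
    if not required.issubset(gene_table.columns):
        raise ValueError(f"gene table needs columns {required}")
    genes = gene_table.drop_duplicates(
        subset=["gene", "chrom", "start", "end"]).reset_index(drop=True)
    centers = pd.DataFrame({
        "peak_id": [p.peak_id for p in peaks],
        "chrom": [p.chrom for p in peaks],
        "center": [p.center for p in peaks]})
    win_start = np.maximum(genes["start"].to_numpy(int) - flank_bp, 0)
    win_end = genes["end"].to_numpy(int) + flank_bp

    gene_hits = np.zeros(len(genes), dtype=int)
    peak_hits = np.zeros(len(centers), dtype=int)
    for chrom, sub in centers.groupby("chrom", sort=False):
        gmask = (genes["chrom"] == chrom).to_numpy()
        if not gmask.any():
            continue
        gs, ge = win_start[gmask], win_end[gmask]
        c = sub["center"].to_numpy(int)
        inside = (c[:, None] >= gs[None, :]) & (c[:, None] < ge[None, :])
        gene_hits[gmask] += inside.sum(axis=0)
        peak_hits[sub.index] = inside.sum(axis=1)

    eds = genes["eds_score"].to_numpy(float)
    pct = 100.0 * pd.Series(eds).rank(pct=True).to_numpy()
    gene_counts = pd.DataFrame({
        "gene": genes["gene"], "chrom": genes["chrom"],
        "start": genes["start"], "end": genes["end"],
        "eds_score": eds, "eds_percentile": pct, "n_peaks": gene_hits})
    peak_counts = pd.DataFrame({"peak_id": centers["peak_id"],
                                "n_genes": peak_hits})
    return gene_counts, peak_counts
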