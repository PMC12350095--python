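"""Genomic context of Rut peaks: categories, tandems, promoter proximity,
distance to transcript 3'-ends, regional enrichment and density profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    AnnotationSet,
    GenomicInterval,
    Promoter,
    RutPeak,
    TerminatorEnd,
)

logger = logging.getLogger("rutscan")

CATEGORIES = ("ANTISENSE", "SENSE_INTRAGENIC", "SENSE_INTERGENIC", "ORPHAN")


@dataclass
class PeakCategoryReport:
    category: dict = field(default_factory=dict)           # peak_id -> category
    promoter_proximal: dict = field(default_factory=dict)  # peak_id -> bool
    tandem_partner: dict = field(default_factory=dict)     # peak_id -> partner id
    proportions: dict = field(default_factory=dict)        # category -> fraction


@dataclass(frozen=True)
class SignedDistance:
    """Signed distance d from a 3'-end to the downstream edge of its nearest
    same-strand peak; d < 0 means the end lies upstream of that edge
    (possible exonucleolytic trimming)."""

    end: TerminatorEnd
    peak_id: str
    d: int


def categorize_peaks(
    peaks: list[RutPeak],
    annotation: AnnotationSet,
    operon_gap: int = 500,
) -> PeakCategoryReport:
    """Assign each peak one exclusive category.

    The gene context (same- vs opposite-strand) with the largest summed
    overlap of the peak wins (ties go to ANTISENSE).  Peaks overlapping no
    gene are SENSE_INTERGENIC when they lie between two co-oriented genes on
    the peak's strand separated by at most ``operon_gap`` nt, else ORPHAN.
    """
    report = PeakCategoryReport()
    genes = [g.interval for g in annotation.genes]
    for p in peaks:
        iv = p.interval
        same = sum(iv.overlap_len(g) for g in genes if g.strand == iv.strand)
        opp = sum(iv.overlap_len(g) for g in genes if g.strand != iv.strand)
        if same == 0 and opp == 0:
            cat = "ORPHAN"
            same_strand = sorted(
                (g for g in genes if g.strand == iv.strand), key=lambda g: g.start
            )
            for g1, g2 in zip(same_strand, same_strand[1:]):
                if (
                    g1.end <= iv.start
                    and iv.end <= g2.start
                    and g2.start - g1.end <= operon_gap
                ):
                    cat = "SENSE_INTERGENIC"
                    break
        elif same > opp:
            cat = "SENSE_INTRAGENIC"
        else:
            cat = "ANTISENSE"
        report.category[p.peak_id] = cat
    n = len(peaks)
    report.proportions = {
        c: (sum(1 for v in report.category.values() if v == c) / n if n else 0.0)
        for c in CATEGORIES
    }
    return report


def find_bidirectional_tandems(
    peaks: list[RutPeak], max_gap: int = 0
) -> list[tuple[str, str]]:
    """Greedy pairing of opposite-strand peaks that overlap by >= 1 nt
    (or lie within ``max_gap`` nt when a gap extension is configured).

    Pairs are chosen by decreasing overlap (ties by leftmost pair); each peak
    joins at most one pair.
    """
    plus = [p for p in peaks if p.interval.strand == "+"]
    minus = [p for p in peaks if p.interval.strand == "-"]
    candidates = []
    for a in plus:
        for b in minus:
            ov = a.interval.overlap_len(b.interval)
            gap = max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end)
            if ov >= 1 or (max_gap > 0 and 0 <= gap <= max_gap):
                left = min(a.interval.start, b.interval.start)
                candidates.append((-ov, left, a.peak_id, b.peak_id))
    candidates.sort()
    used: set[str] = set()
    pairs = []
    for _negov, _left, ida, idb in candidates:
        if ida in used or idb in used:
            continue
        pairs.append((ida, idb))
        used.update((ida, idb))
    return pairs


def find_promoter_proximal(
    peaks: list[RutPeak],
    promoters: list[Promoter],
    window: int = 100,
) -> dict[str, bool]:
    """Flag peaks overlapping a promoter (any strand) or whose downstream
    edge lies within ``window`` nt upstream of a same-strand promoter start."""
    if window < 0:
        raise ValueError("window must be >= 0")
    flags = {}
    for p in peaks:
        iv = p.interval
        flag = any(iv.overlaps(pr.interval, stranded=False) for pr in promoters)
        if not flag:
            for pr in promoters:
                if pr.interval.strand != iv.strand:
                    continue
                if iv.strand == "+":
                    dist = pr.interval.start - iv.end
                else:
                    dist = iv.start - pr.interval.end
                if 0 <= dist <= window:
                    flag = True
                    break
        flags[p.peak_id] = flag
    return flags


def signed_distance(end: TerminatorEnd, peak: RutPeak) -> int:
    """d = end.position - downstream edge on '+'; mirror convention on '-'
    (downstream edge = peak start; d = peak.start - end.position)."""
    if peak.interval.strand == "+":
        return end.position - peak.interval.end
    return peak.interval.start - end.position


def signed_distance_to_ends(
    ends: list[TerminatorEnd],
    peaks: list[RutPeak],
) -> tuple[list[SignedDistance], dict[str, np.ndarray]]:
    """Shortest signed distance from each 3'-end to a same-strand peak.

    Ties in |d| break toward d >= 0.  Ends on a strand with no peaks are
    logged and left unassigned.  Returns the assignments and the sorted
    distance values per terminator class (the per-class ECDF support).
    """
    by_strand: dict[str, list[RutPeak]] = {"+": [], "-": []}
    for p in peaks:
        by_strand[p.interval.strand].append(p)
    out: list[SignedDistance] = []
    unassigned = 0
    for e in ends:
        cands = by_strand[e.strand]
        if not cands:
            unassigned += 1
            continue
        best = min(cands, key=lambda p: (abs(signed_distance(e, p)), -np.sign(signed_distance(e, p))))
        out.append(SignedDistance(end=e, peak_id=best.peak_id, d=signed_distance(e, best)))
    if unassigned:
        logger.info("signed_distance_to_ends: %d ends on strands without peaks", unassigned)
    ecdf = {}
    for cls in sorted({s.end.cls for s in out}):
        ecdf[cls] = np.sort([s.d for s in out if s.end.cls == cls])
    return out, ecdf


def compare_distance_distributions(
    by_class: dict[str, np.ndarray],
    bins: tuple = (-100.0, 0.0, 100.0, 500.0),
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Chi-square test of homogeneity of binned distances across classes.

    Distances are binned at the configured edges (default: <-100, [-100,0),
    [0,100), [100,500), >=500); bins empty in every class are dropped.
    Returns (statistic, p, observed, expected).
    """
    if len(by_class) < 2:
        raise ValueError("need >= 2 classes")
    edges = np.concatenate(([-np.inf], np.asarray(bins, dtype=float), [np.inf]))
    table = np.array(
        [np.histogram(np.asarray(v, dtype=float), bins=edges)[0] for v in by_class.values()]
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("all distances fall in one bin; use finer bins")
    stat, p, _dof, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        raise ValueError("expected count < 1 in some cell; use coarser bins")
    return float(stat), float(p), table, expected


def region_enrichment_permutation(
    peaks: list[RutPeak],
    regions: list[GenomicInterval],
    genome_length: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Permutation test of peak over-representation in a region set.

    Observed statistic: fraction of peaks whose midpoint lies in the regions.
    Null: each peak's start redrawn uniformly (length and strand preserved),
    ``n_perm`` times.  Returns (fold = observed / mean(null), p, observed)
    with the add-one permutation p-value.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm >= 100 required")
    mask = np.zeros(genome_length, dtype=bool)
    for r in regions:
        mask[r.start : r.end] = True
    lengths = np.array([p.interval.length for p in peaks])
    mids = np.array([p.interval.start + p.interval.length // 2 for p in peaks])
    observed = float(mask[mids].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        starts = (rng.random(lengths.size) * (genome_length - lengths)).astype(np.int64)
        null[i] = mask[starts + lengths // 2].mean()
    fold = observed / null.mean() if null.mean() > 0 else np.inf
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return float(fold), float(p), observed


def windowed_density_profiles(
    peaks: list[RutPeak],
    genes: list[GenomicInterval],
    genome_length: int,
    window: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Peak-midpoint counts and gene base-coverage fraction per window,
    with their Pearson correlation.

    Windows are non-overlapping; a trailing partial window is dropped
    (series length = genome_length // window).
    """
    if window < 1000:
        raise ValueError("window must be >= 1000")
    nwin = genome_length // window
    mids = np.array([p.interval.start + p.interval.length // 2 for p in peaks])
    peak_counts = np.histogram(mids, bins=nwin, range=(0, nwin * window))[0].astype(float)
    covered = np.zeros(genome_length, dtype=bool)
    for g in genes:
        covered[g.start : g.end] = True
    gene_frac = np.array(
        [covered[i * window : (i + 1) * window].mean() for i in range(nwin)]
    )
    if np.std(peak_counts) == 0 or np.std(gene_frac) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(peak_counts, gene_frac)[0, 1])
    return peak_counts, gene_frac, r
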