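"""Rut peak calling: threshold caller, median filters, differential caller
and cross-caller matching.

Two independent algorithms are run and only peaks found by both are kept:

* a threshold caller on the replicate-averaged log10FE profile (maximal
  above-cutoff runs, gap merging, minimum length), followed by median
  filters on the starting-library coverage and on log10FE;
* a replicate-aware differential caller on raw per-replicate counts
  (per-replicate log2 fold-change gate + pooled one-sided binomial test with
  Benjamini-Hochberg adjustment over genome blocks).

Matched peaks carry the threshold caller's coordinates, which are
consistently narrower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EnrichmentProfile, GenomicInterval, RutPeak, StrandedCoverageTrack


@dataclass
class DifferentialCallerParams:
    min_log2fc: float = 0.5
    adjusted_alpha: float = 0.05
    mad_filter: float = 0.0      # 0 disables the MAD filter
    block_len: int = 100
    read_len_norm: float = 165.0  # mean fragment length: converts coverage mass to counts

    def __post_init__(self):
        if not 0 < self.adjusted_alpha < 1:
            raise ValueError("adjusted_alpha must be in (0,1)")
        if self.block_len < 1:
            raise ValueError("block_len >= 1 required")


# ---------------------------------------------------------------------------
# threshold caller
# ---------------------------------------------------------------------------


def call_threshold_peaks(
    profile: EnrichmentProfile,
    cutoff: float = 0.0,
    min_len: int = 30,
    max_gap: int = 30,
    screen: str = "BS",
) -> list[RutPeak]:
    """Maximal runs with log10FE > cutoff, gap-merged, length-filtered.

    Runs separated by at most ``max_gap`` below-cutoff positions are merged
    (the gap positions become part of the merged interval); merged intervals
    shorter than ``min_len`` are discarded.
    """
    if min_len < 1:
        raise ValueError("min_len >= 1 required")
    if max_gap < 0:
        raise ValueError("max_gap >= 0 required")
    above = profile.log10fe > cutoff
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = idx[np.concatenate(([0], breaks + 1))]
    run_ends = idx[np.concatenate((breaks, [idx.size - 1]))] + 1
    # merge runs whose separating gap is <= max_gap
    merged_starts = [int(run_starts[0])]
    merged_ends = [int(run_ends[0])]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged_ends[-1] <= max_gap:
            merged_ends[-1] = int(e)
        else:
            merged_starts.append(int(s))
            merged_ends.append(int(e))
    peaks = []
    for i, (s, e) in enumerate(zip(merged_starts, merged_ends)):
        if e - s >= min_len:
            peaks.append(
                RutPeak(
                    interval=GenomicInterval(profile.chrom, s, e, profile.strand),
                    screen=screen,
                    caller="THRESHOLD",
                    peak_id=f"{screen.lower()}_thr_{profile.strand}_{s}",
                )
            )
    return peaks


def apply_median_filters(
    peaks: list[RutPeak],
    r0_track: StrandedCoverageTrack,
    profile: EnrichmentProfile,
    min_median_r0: float = 1.0,
    min_median_fe: float = 0.3,
) -> list[RutPeak]:
    """Keep peaks with median R0 read count >= min_median_r0 and median
    log10FE >= min_median_fe over their positions; medians are recorded on
    the retained peaks."""
    kept = []
    for p in peaks:
        s, e = p.interval.start, p.interval.end
        med_r0 = float(np.median(r0_track.values[s:e]))
        med_fe = float(np.median(profile.log10fe[s:e]))
        if med_r0 >= min_median_r0 and med_fe >= min_median_fe:
            kept.append(
                RutPeak(
                    interval=p.interval,
                    screen=p.screen,
                    caller=p.caller,
                    median_log10fe=med_fe,
                    median_r0=med_r0,
                    peak_id=p.peak_id,
                )
            )
    return kept


# ---------------------------------------------------------------------------
# differential caller
# ---------------------------------------------------------------------------


def _block_sums(values: np.ndarray, block_len: int) -> np.ndarray:
    edges = np.arange(0, values.size, block_len)
    return np.add.reduceat(values, edges)


def call_differential_peaks(
    enriched_reps: list[StrandedCoverageTrack],
    control: StrandedCoverageTrack,
    params: DifferentialCallerParams | None = None,
    min_len: int = 30,
    max_gap: int = 30,
    screen: str = "BS",
) -> list[RutPeak]:
    """Replicate-aware block caller on raw counts.

    The genome is tiled into ``block_len`` blocks.  A block passes if

    1. the library-size-normalized log2 fold change of enriched over control
       (pseudocount of one read) is >= ``min_log2fc`` in EVERY replicate, and
    2. a one-sided binomial test of pooled enriched vs control block counts,
       with success probability given by the library-size ratio, is
       significant after Benjamini-Hochberg adjustment (<= ``adjusted_alpha``).

    Passing blocks closer than ``max_gap`` nt are merged (gap included) and
    merged regions shorter than ``min_len`` are discarded.  Coverage mass is
    converted to approximate read counts by dividing by the mean fragment
    length before the binomial test.
    """
    params = params or DifferentialCallerParams()
    if len(enriched_reps) < 2:
        raise ValueError("differential caller needs >= 2 replicates")
    for t in enriched_reps + [control]:
        if t.scale != "RAW":
            raise ValueError("differential caller expects RAW count tracks")
        if (t.strand, t.length) != (control.strand, control.length):
            raise ValueError("tracks must share strand and length")
    bl = params.block_len
    rn = params.read_len_norm
    ctrl_blocks = np.rint(_block_sums(control.values, bl) / rn)
    ctrl_lib = max(control.values.sum() / rn, 1.0)
    rep_blocks = []
    rep_libs = []
    for t in enriched_reps:
        b = np.rint(_block_sums(t.values, bl) / rn)
        rep_blocks.append(b)
        rep_libs.append(max(t.values.sum() / rn, 1.0))

    # gate 1: per-replicate normalized log2 fold change with 1-read pseudocount
    fc_pass = np.ones(ctrl_blocks.size, dtype=bool)
    for b, lib in zip(rep_blocks, rep_libs):
        fc = np.log2(((b + 1) / lib) / ((ctrl_blocks + 1) / ctrl_lib))
        fc_pass &= fc >= params.min_log2fc

    # gate 2: pooled one-sided binomial vs the library-size ratio
    pooled = np.rint(sum(rep_blocks)).astype(np.int64)
    ctrl_i = ctrl_blocks.astype(np.int64)
    n = pooled + ctrl_i
    p0 = sum(rep_libs) / (sum(rep_libs) + ctrl_lib)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = np.where(n > 0, stats.binom.sf(pooled - 1, np.maximum(n, 1), p0), 1.0)
    qvals = stats.false_discovery_control(np.clip(pvals, 0.0, 1.0), method="bh")
    passing = fc_pass & (qvals <= params.adjusted_alpha)

    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return []
    starts = idx * bl
    ends = np.minimum((idx + 1) * bl, control.length)
    merged = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    peaks = []
    for s, e in merged:
        if e - s >= min_len:
            peaks.append(
                RutPeak(
                    interval=GenomicInterval(control.chrom, s, e, control.strand),
                    screen=screen,
                    caller="DIFFERENTIAL",
                    peak_id=f"{screen.lower()}_dif_{control.strand}_{s}",
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# cross-caller matching
# ---------------------------------------------------------------------------


def _overlap_any(iv: GenomicInterval, others: list[RutPeak]) -> bool:
    for o in others:
        if iv.overlaps(o.interval, stranded=True):
            return True
    return False


def match_peak_sets(
    a: list[RutPeak],
    b: list[RutPeak],
    coords_from: str = "A",
) -> list[RutPeak]:
    """Peaks of set A retained iff they overlap (>=1 nt, same strand) a peak
    of set B; retained peaks become caller=MATCHED with coordinates from the
    set named by ``coords_from`` (largest-overlap partner when 'B')."""
    if coords_from not in ("A", "B"):
        raise ValueError("coords_from must be 'A' or 'B'")
    out = []
    for p in a:
        partners = [q for q in b if p.interval.overlaps(q.interval, stranded=True)]
        if not partners:
            continue
        if coords_from == "A":
            iv = p.interval
        else:
            iv = max(partners, key=lambda q: p.interval.overlap_len(q.interval)).interval
        out.append(
            RutPeak(
                interval=iv,
                screen=p.screen,
                caller="MATCHED",
                median_log10fe=p.median_log10fe,
                median_r0=p.median_r0,
                peak_id=p.peak_id.replace("_thr_", "_mat_"),
            )
        )
    return out


def colocalization_fraction(a: list[RutPeak], b: list[RutPeak]) -> float:
    """Fraction of peaks in ``a`` overlapping (>=1 nt, same strand) any peak
    in ``b``."""
    if not a:
        raise ValueError("colocalization fraction undefined for empty peak set")
    hits = sum(1 for p in a if _overlap_any(p.interval, b))
    return hits / len(a)
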