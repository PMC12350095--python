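"""Coverage normalization, replicate averaging and log10 fold enrichment."""

from __future__ import annotations


import numpy as np

from .core import EnrichmentProfile, StrandedCoverageTrack


def rpm_normalize(track: StrandedCoverageTrack) -> StrandedCoverageTrack:
    """Scale a raw track to reads-per-million of its library total."""
    if track.scale != "RAW":
        raise ValueError("rpm_normalize expects a RAW track")
    if track.library_total <= 0:
        raise ValueError("library_total must be > 0 for RPM normalization")
    return StrandedCoverageTrack(
        chrom=track.chrom,
        strand=track.strand,
        values=track.values * (1e6 / track.library_total),
        scale="RPM",
        library_total=track.library_total,
    )


def average_replicates(tracks: list[StrandedCoverageTrack]) -> StrandedCoverageTrack:
    """Per-base arithmetic mean of replicate tracks (same strand and scale)."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 replicates to average")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.chrom, t.strand, t.scale, t.length) != (
            first.chrom,
            first.strand,
            first.scale,
            first.length,
        ):
            raise ValueError("replicates must share chrom, strand, scale and length")
    mean = np.mean([t.values for t in tracks], axis=0)
    return StrandedCoverageTrack(
        chrom=first.chrom,
        strand=first.strand,
        values=mean,
        scale=first.scale,
        library_total=float(np.mean([t.library_total for t in tracks])),
    )


def log10_fold_enrichment(
    enriched: StrandedCoverageTrack,
    control: StrandedCoverageTrack,
    pseudocount: float = 1.0,
) -> EnrichmentProfile:
    """Per-base log10((enriched + p) / (control + p)) on RPM tracks.

    The pseudocount (RPM units, applied to both operands) keeps the profile
    finite everywhere; downstream median filters make retained peaks
    insensitive to its exact value.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if enriched.scale != "RPM" or control.scale != "RPM":
        raise ValueError("log10_fold_enrichment expects RPM tracks")
    if (enriched.strand, enriched.length) != (control.strand, control.length):
        raise ValueError("enriched and control must share strand and length")
    fe = np.log10((enriched.values + pseudocount) / (control.values + pseudocount))
    return EnrichmentProfile(
        chrom=enriched.chrom, strand=enriched.strand, log10fe=fe, pseudocount=pseudocount
    )
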