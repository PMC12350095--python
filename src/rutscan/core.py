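"""Domain types, coordinate conventions and on-disk formats.

All coordinates are 0-based half-open internally.  BED is read and written
verbatim; GFF3 is converted from 1-based inclusive on the boundary.  Coverage
tracks live as dense per-base numpy arrays on a single-replicon genome, one
track per strand, with the strand encoded in the BEDGRAPH filename suffix
(``.plus.bedgraph`` / ``.minus.bedgraph``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("rutscan")

VALID_BASES = set("ACGTN")
STRANDS = ("+", "-")

# Transcript 3'-end classes: strong intrinsic terminator, Rho-stimulated
# (weak) intrinsic terminator, and Rho-dependent transcription termination.
END_CLASSES = ("STRONG_IT", "RHO_STIM_IT", "RDTT")


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single-replicon genome sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in genome: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty genome sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open stranded interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """Overlap requires >=1 shared base; touching intervals do not overlap."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TerminatorEnd:
    """A transcript 3'-end position with its terminator class label."""

    chrom: str
    position: int
    strand: str
    cls: str

    def __post_init__(self):
        if self.cls not in END_CLASSES:
            raise ValueError(f"unknown terminator class {self.cls!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"terminator end needs a strand, got {self.strand!r}")


@dataclass(frozen=True)
class Gene:
    interval: GenomicInterval
    name: str


@dataclass(frozen=True)
class Promoter:
    interval: GenomicInterval
    sigma: str | None = None


@dataclass
class AnnotationSet:
    """Genes, promoters, prophage regions and transcript 3'-ends."""

    genes: list[Gene] = field(default_factory=list)
    promoters: list[Promoter] = field(default_factory=list)
    prophage_regions: list[GenomicInterval] = field(default_factory=list)
    terminator_ends: list[TerminatorEnd] = field(default_factory=list)

    def validate(self, genome_length: int) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("gene names are not unique")
        for iv in (
            [g.interval for g in self.genes]
            + [p.interval for p in self.promoters]
            + list(self.prophage_regions)
        ):
            if iv.end > genome_length:
                raise ValueError(f"interval {iv} outside genome of length {genome_length}")
        for e in self.terminator_ends:
            if not 0 <= e.position < genome_length:
                raise ValueError(f"3'-end position {e.position} outside genome")


@dataclass
class StrandedCoverageTrack:
    """Per-base read coverage on one strand, raw counts or RPM-normalized.

    ``library_total`` is the raw mapped read count of the whole library (both
    strands) — one normalization constant per library.
    """

    chrom: str
    strand: str
    values: np.ndarray
    scale: str = "RAW"  # RAW | RPM
    library_total: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.scale not in ("RAW", "RPM"):
            raise ValueError(f"invalid scale {self.scale!r}")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.scale == "RPM" and self.library_total <= 0:
            raise ValueError("RPM track requires library_total > 0")

    @property
    def length(self) -> int:
        return self.values.size


@dataclass
class EnrichmentProfile:
    """Per-base log10 fold enrichment (log10FE) of an enriched library over R0."""

    chrom: str
    strand: str
    log10fe: np.ndarray
    pseudocount: float

    def __post_init__(self):
        self.log10fe = np.asarray(self.log10fe, dtype=float)
        if not np.all(np.isfinite(self.log10fe)):
            raise ValueError("log10FE profile must be finite everywhere")

    @property
    def length(self) -> int:
        return self.log10fe.size


@dataclass(frozen=True)
class RutPeak:
    """A stranded interval called as a putative Rut site."""

    interval: GenomicInterval
    screen: str = "BS"  # BS | EC
    caller: str = "THRESHOLD"  # THRESHOLD | DIFFERENTIAL | MATCHED
    median_log10fe: float = float("nan")
    median_r0: float = float("nan")
    peak_id: str = ""

    def __post_init__(self):
        if self.caller not in ("THRESHOLD", "DIFFERENTIAL", "MATCHED"):
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.screen not in ("BS", "EC"):
            raise ValueError(f"unknown screen {self.screen!r}")
        if self.caller == "MATCHED":
            if not (self.median_log10fe >= 0.3 and self.median_r0 >= 1):
                raise ValueError(
                    "MATCHED peak must satisfy median log10FE >= 0.3 and median R0 >= 1"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_genome(path: str | Path) -> GenomeSequence:
    """Load a single-record FASTA genome; lowercase is normalized to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: multiple records not supported")
    seq = str(records[0].seq).upper()
    if not seq:
        raise FormatError(f"{path}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"{path}: invalid characters {sorted(bad)}")
    n = seq.count("N")
    if n:
        logger.info("genome %s contains %d N bases", records[0].id, n)
    return GenomeSequence(name=records[0].id, sequence=seq)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def load_intervals(
    path: str | Path,
    kind: str = "generic",
    genome_length: int | None = None,
) -> list[GenomicInterval]:
    """Load intervals from BED6 (0-based half-open) or GFF3 (1-based inclusive).

    Format is decided by extension (.bed vs .gff/.gff3).  Strand '.' is only
    permitted for ``kind='prophage_regions'``.
    """
    path = Path(path)
    gff = path.suffix.lower() in (".gff", ".gff3")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if gff:
                    chrom, start, end, strand = cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]
                else:
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    strand = cols[5] if len(cols) > 5 else "."
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed line") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if strand == "." and kind != "prophage_regions":
                raise FormatError(f"{path}:{lineno}: unstranded record not allowed for {kind}")
            if genome_length is not None and end > genome_length:
                raise FormatError(f"{path}:{lineno}: coordinate beyond genome end")
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def load_annotation_gff3(path: str | Path, genome_length: int | None = None) -> AnnotationSet:
    """Read genes / promoters / prophage regions from a GFF3 file by feature type."""
    ann = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                ann.genes.append(Gene(iv, attrd.get("Name", attrd.get("ID", f"g{lineno}"))))
            elif ftype == "promoter":
                ann.promoters.append(Promoter(iv, attrd.get("sigma")))
            elif ftype in ("prophage", "mobile_genetic_element"):
                ann.prophage_regions.append(iv)
    if genome_length is not None:
        ann.validate(genome_length)
    return ann


def write_annotation_gff3(ann: AnnotationSet, chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            iv = g.interval
            fh.write(
                f"{chrom}\trutscan\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.name};Name={g.name}\n"
            )
        for p in ann.promoters:
            iv = p.interval
            sig = f";sigma={p.sigma}" if p.sigma else ""
            fh.write(
                f"{chrom}\trutscan\tpromoter\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID=prom_{iv.start}{sig}\n"
            )
        for i, iv in enumerate(ann.prophage_regions):
            fh.write(
                f"{chrom}\trutscan\tprophage\t{iv.start + 1}\t{iv.end}\t.\t.\t.\t"
                f"ID=prophage_{i}\n"
            )


def load_terminator_ends(path: str | Path) -> list[TerminatorEnd]:
    """Read transcript 3'-ends from BED6 with the class label in the name column."""
    ends = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            ends.append(
                TerminatorEnd(chrom=cols[0], position=int(cols[1]), strand=cols[5], cls=cols[3])
            )
    return ends


def write_terminator_ends(ends: Sequence[TerminatorEnd], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# 3'-end BED: name column carries the terminator class\n")
        for e in ends:
            fh.write(f"{e.chrom}\t{e.position}\t{e.position + 1}\t{e.cls}\t0\t{e.strand}\n")


PEAK_TSV_COLUMNS = (
    "peak_id",
    "chrom",
    "start",
    "end",
    "strand",
    "screen",
    "caller",
    "median_log10fe",
    "median_r0",
)


def write_peaks(peaks: Sequence[RutPeak], path: str | Path) -> None:
    """Write peaks as BED6 plus a TSV sidecar (same stem, ``.tsv`` suffix).

    BED score column holds round(median_log10fe * 1000).  Unsorted input is
    sorted with a warning; the sidecar preserves every field so that a
    write -> read round trip is the identity.
    """
    path = Path(path)
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].interval.chrom, peaks[i].interval.start))
    if order != list(range(len(peaks))):
        logger.warning("write_peaks: input not sorted; sorting %d peaks", len(peaks))
    peaks = [peaks[i] for i in order]
    with open(path, "w") as fh:
        fh.write("# rutscan peaks BED6; score = round(median_log10fe*1000)\n")
        for p in peaks:
            iv = p.interval
            score = 0 if np.isnan(p.median_log10fe) else int(round(p.median_log10fe * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{score}\t{iv.strand}\n")
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("\t".join(PEAK_TSV_COLUMNS) + "\n")
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{p.peak_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{p.screen}\t{p.caller}\t{p.median_log10fe!r}\t{p.median_r0!r}\n"
            )


def read_peaks(path: str | Path) -> list[RutPeak]:
    """Read peaks back from the TSV sidecar written by :func:`write_peaks`."""
    path = Path(path)
    tsv = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
    peaks = []
    with open(tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PEAK_TSV_COLUMNS:
            raise FormatError(f"{tsv}: unexpected header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                RutPeak(
                    interval=GenomicInterval(f[1], int(f[2]), int(f[3]), f[4]),
                    screen=f[5],
                    caller=f[6],
                    median_log10fe=float(f[7]),
                    median_r0=float(f[8]),
                    peak_id=f[0],
                )
            )
    return peaks


def write_bedgraph(track: StrandedCoverageTrack, path: str | Path) -> None:
    """Write a dense per-base track as run-length-compressed 4-column BEDGRAPH.

    The library read total travels in a header comment so that reloading
    reproduces the same RPM normalization constant.
    """
    v = track.values
    # run boundaries where the value changes
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [v.size]))
    with open(path, "w") as fh:
        fh.write(f"# library_total={float(track.library_total)!r}\n")
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{float(v[s])!r}\n")


def read_bedgraph(
    path: str | Path,
    strand: str,
    genome_length: int,
    scale: str = "RAW",
    library_total: float = 0.0,
) -> StrandedCoverageTrack:
    values = np.zeros(genome_length)
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("# library_total="):
                library_total = library_total or float(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: BEDGRAPH needs 4 columns")
            chrom = cols[0]
            s, e, val = int(cols[1]), int(cols[2]), float(cols[3])
            if e > genome_length:
                raise FormatError(f"{path}:{lineno}: interval beyond genome end")
            values[s:e] = val
    return StrandedCoverageTrack(
        chrom=chrom or "genome",
        strand=strand,
        values=values,
        scale=scale,
        library_total=library_total,
    )


def intervals_to_bed(intervals: Iterable[GenomicInterval], path: str | Path, names=None) -> None:
    intervals = list(intervals)
    if names is None:
        names = [f"iv{i}" for i in range(len(intervals))]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
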