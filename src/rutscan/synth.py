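"""Synthetic Helicase-SELEX data generator.

Emulates the statistical structure of an H-SELEX screen of a bacterial
genome: a toy genome with genes/promoters/prophages, planted pyrimidine-rich
Rut sites with graded activity, a random 30-300 bp fragment library whose
coverage breadth matches a deeply sampled genomic pool, multiplicative
per-round selection of site-bearing fragments under an increasing stringency
schedule with replicate noise, transcript 3'-ends placed around planted
sites with class-dependent exonucleolytic trimming, and pseudo-first-order
duplex-unwinding time courses.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnnotationSet,
    Gene,
    GenomeSequence,
    GenomicInterval,
    Promoter,
    StrandedCoverageTrack,
    TerminatorEnd,
)

BASES = np.array(list("ACGT"))

# Planted-site base composition (RNA-sense): U/C-rich, G-poor.
DEFAULT_SITE_COMPOSITION = {"A": 0.22, "C": 0.35, "G": 0.08, "T": 0.35}


@dataclass(frozen=True)
class PlantedSite:
    interval: GenomicInterval
    activity_score: float
    composition: dict

    def __post_init__(self):
        if not 0 < self.activity_score <= 1:
            raise ValueError("activity_score must be in (0,1]")


@dataclass
class TruthRegistry:
    """Ground-truth records linking simulated enrichment to planted intervals."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_end_links: dict = field(default_factory=dict)  # site index -> TerminatorEnd

    def validate(self) -> None:
        by_strand: dict[str, list[GenomicInterval]] = {}
        for s in self.planted_sites:
            by_strand.setdefault(s.interval.strand, []).append(s.interval)
        for ivs in by_strand.values():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"planted sites overlap on one strand: {a} {b}")


@dataclass
class SelectionConfig:
    """Per-round selection model parameters.

    ``stringency`` is the per-round selection exponent schedule, emulating the
    shrinking helicase reaction time across rounds: an active fragment's
    retention weight in round r is ``enrichment_base ** stringency[r]`` scaled
    by its site's activity score.
    """

    rounds: int = 6
    stringency: np.ndarray | None = None
    enrichment_base: float = 2.0
    replicate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds >= 1 required")
        if self.enrichment_base < 1:
            raise ValueError("enrichment_base must be >= 1 (1 = null selection)")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if self.stringency is None:
            # linear increase of the selection exponent from 1 to 3
            self.stringency = np.linspace(1.0, 3.0, self.rounds)
        self.stringency = np.asarray(self.stringency, dtype=float)
        if self.stringency.size != self.rounds:
            raise ValueError("stringency schedule length must equal rounds")


@dataclass
class UnwindingCurve:
    times: np.ndarray
    fraction_unwound: np.ndarray
    true_amplitude: float = float("nan")
    true_rate: float = float("nan")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_unwound = np.asarray(self.fraction_unwound, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.fraction_unwound < 0) | (self.fraction_unwound > 1)):
            raise ValueError("fractions must lie in [0,1]")


@dataclass
class FragmentTable:
    """The simulated fragment library: one row per distinct fragment."""

    starts: np.ndarray
    lengths: np.ndarray
    strands: np.ndarray  # 0 = '+', 1 = '-'

    @property
    def n(self) -> int:
        return self.starts.size


# ---------------------------------------------------------------------------
# genome and planted sites
# ---------------------------------------------------------------------------


def generate_toy_genome(
    length: int,
    gene_density: float = 0.7,
    seed: int = 0,
    prophage_fraction: float = 0.1,
    chrom: str = "toy",
) -> tuple[GenomeSequence, AnnotationSet]:
    """Random uniform-composition genome with non-overlapping genes.

    Genes are placed sequentially on alternating random strands with
    exponential intergenic gaps tuned so the expected gene coverage matches
    ``gene_density``; each gene gets a 40-nt promoter immediately upstream.
    A contiguous set of regions totalling ``prophage_fraction`` of the genome
    is marked as prophage.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10000")
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length)
    ann = AnnotationSet()
    if gene_density > 0:
        mean_gene = 1250.0
        mean_gap = max(60.0, mean_gene * (1 - gene_density) / gene_density)
        cursor = int(rng.integers(100, 400))
        gi = 0
        while cursor < length - 2500:
            glen = int(rng.integers(500, 2001))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, cursor, cursor + glen, strand)
            ann.genes.append(Gene(iv, f"gene{gi:05d}"))
            # 40-nt promoter immediately upstream in transcription direction
            if strand == "+" and cursor >= 40:
                ann.promoters.append(
                    Promoter(GenomicInterval(chrom, cursor - 40, cursor, "+"))
                )
            elif strand == "-" and cursor + glen + 40 <= length:
                ann.promoters.append(
                    Promoter(GenomicInterval(chrom, cursor + glen, cursor + glen + 40, "-"))
                )
            gi += 1
            cursor += glen + 50 + int(rng.exponential(mean_gap))
    if prophage_fraction > 0:
        n_regions = 3
        reg_len = int(length * prophage_fraction / n_regions)
        anchors = np.sort(rng.choice(length - reg_len, size=n_regions, replace=False))
        for a in anchors:
            ann.prophage_regions.append(GenomicInterval(chrom, int(a), int(a) + reg_len, "."))
    genome = GenomeSequence(name=chrom, sequence="".join(seq))
    ann.validate(length)
    return genome, ann


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _activity_from_pyrimidine(pct_pyr: float) -> float:
    """Logistic map from percent pyrimidine of the RNA-sense sequence to (0,1]."""
    return 1.0 / (1.0 + np.exp(-(pct_pyr - 50.0) / 10.0))


def plant_rut_sites(
    genome: GenomeSequence,
    annotation: AnnotationSet,
    n_sites: int = 200,
    composition: dict | None = None,
    min_len: int = 50,
    max_len: int = 150,
    antisense_prop: float = 0.8,
    seed: int = 0,
) -> tuple[GenomeSequence, TruthRegistry]:
    """Insert pyrimidine-rich, G-poor segments as ground-truth Rut sites.

    The RNA-sense sequence of each site is sampled from ``composition``
    (default C 35% / U 35% / A 22% / G 8%); its activity score is a logistic
    function of its pyrimidine percentage.  Sites overlapping a gene are put
    antisense to it with probability ``antisense_prop``; intergenic sites get
    a uniform strand.  Sites are pairwise non-overlapping.
    """
    composition = dict(composition or DEFAULT_SITE_COMPOSITION)
    rng = np.random.default_rng(seed)
    L = genome.length
    if n_sites == 0:
        return genome, TruthRegistry()
    if n_sites * (max_len + 50) > L:
        raise ValueError(f"cannot place {n_sites} sites in genome of length {L}")
    probs = np.array([composition[b] for b in "ACGT"])
    probs = probs / probs.sum()

    gene_ivs = [g.interval for g in annotation.genes]
    gene_starts = np.array([iv.start for iv in gene_ivs] or [0])
    gene_ends = np.array([iv.end for iv in gene_ivs] or [0])

    placed: list[tuple[int, int]] = []
    sites: list[PlantedSite] = []
    seq = list(genome.sequence)
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise ValueError(f"could not place {n_sites} sites after {attempts} attempts")
        slen = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, L - slen))
        # keep sites apart (any strand) so truth intervals are unambiguous
        if any(start < e + 50 and s - 50 < start + slen for s, e in placed):
            continue
        # strand relative to an overlapping gene, if any
        mid = start + slen // 2
        hit = np.flatnonzero((gene_starts <= mid) & (mid < gene_ends))
        if hit.size:
            gstrand = gene_ivs[int(hit[0])].strand
            if rng.random() < antisense_prop:
                strand = "-" if gstrand == "+" else "+"
            else:
                strand = gstrand
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        rna = "".join(rng.choice(BASES, size=slen, p=probs))
        pct_pyr = 100.0 * (rna.count("C") + rna.count("T")) / slen
        insert = rna if strand == "+" else _revcomp(rna)
        seq[start : start + slen] = insert
        placed.append((start, start + slen))
        sites.append(
            PlantedSite(
                interval=GenomicInterval(genome.name, start, start + slen, strand),
                activity_score=float(_activity_from_pyrimidine(pct_pyr)),
                composition=composition,
            )
        )
    sites.sort(key=lambda s: s.interval.start)
    registry = TruthRegistry(planted_sites=sites)
    registry.validate()
    return GenomeSequence(genome.name, "".join(seq)), registry


# ---------------------------------------------------------------------------
# fragment library and selection
# ---------------------------------------------------------------------------


def _coverage(starts, ends, weights, length) -> np.ndarray:
    diff = np.zeros(length + 1)
    np.add.at(diff, starts, weights)
    np.add.at(diff, ends, -weights)
    # cumsum of float weights can leave tiny negative residues
    return np.maximum(np.cumsum(diff)[:length], 0.0)


def simulate_fragment_coverage(
    genome: GenomeSequence,
    n_fragments: int = 300_000,
    len_min: int = 30,
    len_max: int = 300,
    seed: int = 0,
) -> tuple[StrandedCoverageTrack, StrandedCoverageTrack, FragmentTable]:
    """Random fragment library (the R0 pool) and its per-strand coverage."""
    if n_fragments < 1:
        raise ValueError("n_fragments >= 1 required")
    rng = np.random.default_rng(seed)
    L = genome.length
    lengths = rng.integers(len_min, len_max + 1, size=n_fragments)
    starts = (rng.random(n_fragments) * (L - lengths)).astype(np.int64)
    strands = rng.integers(0, 2, size=n_fragments)
    frags = FragmentTable(starts=starts, lengths=lengths.astype(np.int64), strands=strands)
    ones = np.ones(n_fragments)
    tracks = []
    for s in (0, 1):
        m = strands == s
        cov = _coverage(starts[m], starts[m] + lengths[m], ones[m], L)
        tracks.append(
            StrandedCoverageTrack(
                chrom=genome.name,
                strand="+" if s == 0 else "-",
                values=cov,
                scale="RAW",
                library_total=float(n_fragments),
            )
        )
    return tracks[0], tracks[1], frags


def fragment_site_activity(frags: FragmentTable, truth: TruthRegistry) -> np.ndarray:
    """Per-fragment activity multiplier.

    A fragment is active if it overlaps a planted site on the matching strand
    by at least half the site length (a Rut site must be largely contained in
    the transcript to activate Rho); the multiplier is that site's activity
    score, 0 for inactive fragments.
    """
    act = np.zeros(frags.n)
    fstart, fend = frags.starts, frags.starts + frags.lengths
    for site in truth.planted_sites:
        s_code = 0 if site.interval.strand == "+" else 1
        ov = np.minimum(fend, site.interval.end) - np.maximum(fstart, site.interval.start)
        hit = (frags.strands == s_code) & (ov >= 0.5 * site.interval.length)
        act[hit] = np.maximum(act[hit], site.activity_score)
    return act


def simulate_selection(
    genome: GenomeSequence,
    frags: FragmentTable,
    truth: TruthRegistry,
    cfg: SelectionConfig,
    n_replicates: int = 2,
    emit_rounds: str = "all",
) -> list[dict]:
    """Simulate iterative H-SELEX enrichment of the fragment library.

    Each round, the fragment multiset is resampled (fixed total) with
    probability proportional to count x retention weight, where the weight of
    an active fragment is ``enrichment_base ** stringency[r] * activity`` and
    1 otherwise.  Replicates then receive independent multiplicative
    lognormal noise on per-fragment counts.

    Returns one dict per round with keys ``round``, ``replicates`` (list of
    (plus_track, minus_track); empty for non-emitted rounds when
    ``emit_rounds='last'``), ``counts`` (noise-free fragment counts after
    that round's resampling) and ``active_fraction`` (share of the library
    carried by site-bearing fragments).
    """
    if frags.n == 0:
        raise ValueError("empty fragment table")
    rng = np.random.default_rng(cfg.seed)
    L = genome.length
    total = frags.n
    activity = fragment_site_activity(frags, truth)
    counts = np.ones(frags.n)
    out = []
    fstart, fend = frags.starts, frags.starts + frags.lengths
    active = activity > 0
    for r in range(cfg.rounds):
        w = np.where(
            active, cfg.enrichment_base ** cfg.stringency[r] * activity, 1.0
        )
        p = counts * w
        p = p / p.sum()
        counts = rng.multinomial(total, p).astype(float)
        replicates = []
        if emit_rounds == "all" or r == cfg.rounds - 1:
            for _rep in range(n_replicates):
                if cfg.replicate_noise_sd > 0:
                    noisy = counts * rng.lognormal(0.0, cfg.replicate_noise_sd, frags.n)
                else:
                    noisy = counts.copy()
                lib_total = float(noisy.sum())
                pair = []
                for s in (0, 1):
                    m = frags.strands == s
                    cov = _coverage(fstart[m], fend[m], noisy[m], L)
                    pair.append(
                        StrandedCoverageTrack(
                            chrom=genome.name,
                            strand="+" if s == 0 else "-",
                            values=cov,
                            scale="RAW",
                            library_total=lib_total,
                        )
                    )
                replicates.append(tuple(pair))
        out.append(
            {
                "round": r + 1,
                "replicates": replicates,
                "counts": counts.copy(),
                "active_fraction": float(counts[active].sum() / total),
            }
        )
    return out


# ---------------------------------------------------------------------------
# terminator 3'-ends
# ---------------------------------------------------------------------------


def simulate_terminator_ends(
    truth: TruthRegistry,
    annotation: AnnotationSet,
    genome_length: int,
    end_fraction: float = 0.5,
    trim_mean: float = 400.0,
    geom_p_down: float = 0.00167,
    seed: int = 0,
) -> list[TerminatorEnd]:
    """Place transcript 3'-ends around planted sites with class-dependent trimming.

    RDTT ends start a geometric distance downstream of the site's downstream
    edge and are then trimmed upstream by an exponential offset of mean
    ``trim_mean`` (emulating 3'-to-5' exonucleolytic processing); Rho-stimulated
    IT ends are placed the same way but with one-eighth of the trimming (the
    terminator hairpin shields the 3'-end); strong-IT ends are drawn uniformly
    from gene 3'-ends unrelated to any site.  Signed distances d from the site
    downstream edge are therefore mostly >= 0 for Rho-stimulated IT and often
    < 0 for RDTT.
    """
    if not truth.planted_sites:
        raise ValueError("truth registry is empty")
    rng = np.random.default_rng(seed)
    n = len(truth.planted_sites)
    order = rng.permutation(n)
    n_rdtt = int(round(end_fraction * n))
    n_it = int(round(0.5 * end_fraction * n))
    ends: list[TerminatorEnd] = []

    def place(site: PlantedSite, cls: str, mean_trim: float) -> TerminatorEnd:
        down = int(rng.geometric(geom_p_down))
        trim = int(round(rng.exponential(mean_trim))) if mean_trim > 0 else 0
        iv = site.interval
        if iv.strand == "+":
            pos = iv.end + down - trim
        else:
            pos = iv.start - down + trim
        pos = int(np.clip(pos, 0, genome_length - 1))
        return TerminatorEnd(chrom=iv.chrom, position=pos, strand=iv.strand, cls=cls)

    used = set()
    for idx in order[:n_rdtt]:
        site = truth.planted_sites[int(idx)]
        end = place(site, "RDTT", trim_mean)
        ends.append(end)
        truth.planted_end_links[int(idx)] = end
        used.add(int(idx))
    for idx in order[n_rdtt : n_rdtt + n_it]:
        site = truth.planted_sites[int(idx)]
        end = place(site, "RHO_STIM_IT", trim_mean / 8.0)
        ends.append(end)
        truth.planted_end_links[int(idx)] = end
        used.add(int(idx))

    # strong-IT ends: 3'-ends of genes whose body is far from every site
    site_mids = np.array([(s.interval.start + s.interval.end) // 2 for s in truth.planted_sites])
    far_genes = []
    for g in annotation.genes:
        iv = g.interval
        if np.all((site_mids < iv.start - 500) | (site_mids > iv.end + 500)):
            far_genes.append(iv)
    n_strong = min(len(far_genes), max(n_rdtt, 1))
    if far_genes:
        pick = rng.choice(len(far_genes), size=n_strong, replace=False)
        for i in np.atleast_1d(pick):
            iv = far_genes[int(i)]
            pos = iv.end - 1 if iv.strand == "+" else iv.start
            ends.append(
                TerminatorEnd(chrom=iv.chrom, position=int(pos), strand=iv.strand, cls="STRONG_IT")
            )
    return ends


# ---------------------------------------------------------------------------
# unwinding kinetics
# ---------------------------------------------------------------------------


def simulate_unwinding(
    A: float,
    k: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> UnwindingCurve:
    """Pseudo-first-order unwinding: f(t) = A (1 - e^{-kt}) + Gaussian noise."""
    if not 0 <= A <= 1:
        raise ValueError("amplitude A must be in [0,1]")
    if k <= 0:
        raise ValueError("rate k must be > 0")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    f = A * (1.0 - np.exp(-k * times))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, times.size)
    f = np.clip(f, 0.0, 1.0)
    return UnwindingCurve(times=times, fraction_unwound=f, true_amplitude=A, true_rate=k)
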