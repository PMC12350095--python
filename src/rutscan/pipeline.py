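"""End-to-end orchestration: simulate -> enrich -> callpeaks -> context ->
features -> kinetics, with a reproducibility manifest and a run summary."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .context import (
    categorize_peaks,
    compare_distance_distributions,
    find_bidirectional_tandems,
    find_promoter_proximal,
    region_enrichment_permutation,
    signed_distance_to_ends,
    windowed_density_profiles,
)
from .core import (
    intervals_to_bed,
    load_annotation_gff3,
    load_genome,
    load_terminator_ends,
    read_bedgraph,
    write_annotation_gff3,
    write_bedgraph,
    write_genome,
    write_peaks,
    write_terminator_ends,
)
from .enrichment import average_replicates, log10_fold_enrichment, rpm_normalize
from .features import (
    descriptor_table,
    extract_peak_sequences,
    rank_descriptors,
    sample_rutless_controls,
)
from .kinetics import detect_plateau_round, fit_burst
from .peaks import (
    DifferentialCallerParams,
    apply_median_filters,
    call_differential_peaks,
    call_threshold_peaks,
    match_peak_sets,
)
from .synth import (
    SelectionConfig,
    TruthRegistry,
    generate_toy_genome,
    plant_rut_sites,
    simulate_fragment_coverage,
    simulate_selection,
    simulate_terminator_ends,
    simulate_unwinding,
)

logger = logging.getLogger("rutscan")

# NC_000964.3 replicon length, used for density arithmetic on published counts
BSUBTILIS_GENOME_LENGTH = 4_215_606

UNWIND_TIMES = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])  # seconds


def density_per_mb(n_peaks: int, genome_length: int) -> float:
    """Peaks per Mb of screened sequence; both strands are screened, so the
    denominator is twice the genome length."""
    return n_peaks * 1e6 / (2 * genome_length)


def recovery_stats(matched_peaks, truth: TruthRegistry) -> tuple[float, float]:
    """(fraction of planted sites overlapped by a matched peak on the same
    strand, fraction of matched peaks overlapping no planted site)."""
    sites = [s.interval for s in truth.planted_sites]
    if not sites:
        return 0.0, 1.0 if matched_peaks else 0.0
    hit_sites = sum(
        1 for s in sites if any(s.overlaps(p.interval, stranded=True) for p in matched_peaks)
    )
    if matched_peaks:
        orphan_peaks = sum(
            1
            for p in matched_peaks
            if not any(p.interval.overlaps(s, stranded=True) for s in sites)
        )
        fdr = orphan_peaks / len(matched_peaks)
    else:
        fdr = 0.0
    return hit_sites / len(sites), fdr


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulation(cfg: PipelineConfig, seed: int):
    """Generate the full synthetic study: genome, truth, R0 and final-round
    replicate coverage, 3'-ends and the per-round unwinding amplitude model."""
    genome, annotation = generate_toy_genome(
        cfg.genome_length,
        gene_density=cfg.gene_density,
        seed=seed,
        prophage_fraction=cfg.prophage_fraction,
    )
    genome, truth = plant_rut_sites(
        genome,
        annotation,
        n_sites=cfg.n_sites,
        min_len=cfg.site_min_len,
        max_len=cfg.site_max_len,
        antisense_prop=cfg.site_antisense_prop,
        seed=seed + 1,
    )
    r0_plus, r0_minus, frags = simulate_fragment_coverage(
        genome,
        n_fragments=cfg.n_fragments,
        len_min=cfg.fragment_min_len,
        len_max=cfg.fragment_max_len,
        seed=seed + 2,
    )
    sel_cfg = SelectionConfig(
        rounds=cfg.rounds,
        stringency=np.linspace(cfg.stringency_start, cfg.stringency_end, cfg.rounds),
        enrichment_base=cfg.enrichment_base,
        replicate_noise_sd=cfg.replicate_noise_sd,
        seed=seed + 3,
    )
    rounds = simulate_selection(genome, frags, truth, sel_cfg, emit_rounds="last")
    ends = simulate_terminator_ends(
        truth,
        annotation,
        genome.length,
        end_fraction=cfg.end_fraction,
        trim_mean=cfg.trim_mean,
        geom_p_down=cfg.geom_p_down,
        seed=seed + 4,
    )
    return {
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "r0": (r0_plus, r0_minus),
        "frags": frags,
        "rounds": rounds,
        "ends": ends,
    }


def unwinding_amplitude_series(cfg: PipelineConfig, sim: dict, seed: int):
    """Per-round burst amplitudes of the library, A_r = A_max x active
    fraction, from a counts-only selection run over ``kinetics_rounds``
    rounds, together with one noisy unwinding curve per round."""
    sel_cfg = SelectionConfig(
        rounds=cfg.kinetics_rounds,
        stringency=np.linspace(cfg.stringency_start, cfg.stringency_end, cfg.kinetics_rounds),
        enrichment_base=cfg.enrichment_base,
        replicate_noise_sd=0.0,
        seed=seed + 5,
    )
    history = simulate_selection(
        sim["genome"], sim["frags"], sim["truth"], sel_cfg, n_replicates=0, emit_rounds="last"
    )
    true_amps = [(h["round"], cfg.unwind_max_amplitude * h["active_fraction"]) for h in history]
    curves = [
        (
            r,
            simulate_unwinding(
                A, cfg.unwind_k, UNWIND_TIMES, noise_sd=cfg.unwind_noise_sd, seed=seed + 100 + r
            ),
        )
        for r, A in true_amps
    ]
    return true_amps, curves


def call_matched_peaks(cfg: PipelineConfig, sim: dict, screen: str = "BS"):
    """Enrichment profiles and the three peak sets for one strand pair."""
    r0 = {"+": sim["r0"][0], "-": sim["r0"][1]}
    final = sim["rounds"][-1]["replicates"]
    out = {"profiles": {}, "threshold": [], "differential": [], "matched": []}
    for si, strand in enumerate(("+", "-")):
        r0_rpm = rpm_normalize(r0[strand])
        reps_raw = [rep[si] for rep in final]
        reps_rpm = [rpm_normalize(t) for t in reps_raw]
        mean_rpm = average_replicates(reps_rpm)
        profile = log10_fold_enrichment(mean_rpm, r0_rpm, pseudocount=cfg.pseudocount)
        thr = call_threshold_peaks(
            profile, cutoff=cfg.cutoff, min_len=cfg.min_len, max_gap=cfg.max_gap, screen=screen
        )
        thr = apply_median_filters(
            thr, r0[strand], profile, min_median_r0=cfg.min_median_r0, min_median_fe=cfg.min_median_fe
        )
        dif = call_differential_peaks(
            reps_raw,
            r0[strand],
            DifferentialCallerParams(
                min_log2fc=cfg.min_log2fc,
                adjusted_alpha=cfg.adjusted_alpha,
                mad_filter=cfg.mad_filter,
                block_len=cfg.block_len,
            ),
            min_len=cfg.min_len,
            max_gap=cfg.max_gap,
            screen=screen,
        )
        matched = match_peak_sets(thr, dif, coords_from="A")
        out["profiles"][strand] = profile
        out["threshold"] += thr
        out["differential"] += dif
        out["matched"] += matched
    return out


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    simulate: bool = True,
) -> dict:
    """Execute all stages in dependency order and write every stage output
    plus a manifest into ``outdir``.  Identical config + seed reproduce
    byte-identical TSV/BED outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed

    # -- stage: simulate (or load) ------------------------------------------
    if simulate:
        sim = run_simulation(cfg, seed)
        write_genome(sim["genome"], outdir / "genome.fasta")
        write_annotation_gff3(sim["annotation"], sim["genome"].name, outdir / "annotation.gff3")
        intervals_to_bed(
            [s.interval for s in sim["truth"].planted_sites],
            outdir / "truth.bed",
            names=[f"site{i}" for i in range(len(sim["truth"].planted_sites))],
        )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("site_id\tchrom\tstart\tend\tstrand\tactivity_score\n")
            for i, s in enumerate(sim["truth"].planted_sites):
                iv = s.interval
                fh.write(
                    f"site{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{s.activity_score:.6f}\n"
                )
        for strand, name in (("+", "plus"), ("-", "minus")):
            write_bedgraph(sim["r0"][0 if strand == "+" else 1], outdir / f"r0.{name}.bedgraph")
        for rep_i, rep in enumerate(sim["rounds"][-1]["replicates"]):
            for si, name in ((0, "plus"), (1, "minus")):
                write_bedgraph(
                    rep[si], outdir / f"round{cfg.rounds}_rep{'ab'[rep_i]}.{name}.bedgraph"
                )
        write_terminator_ends(sim["ends"], outdir / "ends.bed")
    else:
        fasta = outdir / "genome.fasta"
        if not fasta.exists():
            raise FileNotFoundError(f"missing genome FASTA: {fasta} (use simulate=True)")
        genome = load_genome(fasta)
        annotation = load_annotation_gff3(outdir / "annotation.gff3", genome.length)
        truth_df = pd.read_csv(outdir / "truth.tsv", sep="\t")
        from .core import GenomicInterval
        from .synth import PlantedSite

        truth = TruthRegistry(
            planted_sites=[
                PlantedSite(
                    GenomicInterval(r.chrom, r.start, r.end, r.strand), r.activity_score, {}
                )
                for r in truth_df.itertuples()
            ]
        )
        r0 = tuple(
            read_bedgraph(outdir / f"r0.{nm}.bedgraph", st, genome.length, "RAW")
            for st, nm in (("+", "plus"), ("-", "minus"))
        )
        reps = []
        for rep_c in "ab":
            pair = tuple(
                read_bedgraph(
                    outdir / f"round{cfg.rounds}_rep{rep_c}.{nm}.bedgraph",
                    st,
                    genome.length,
                    "RAW",
                )
                for st, nm in (("+", "plus"), ("-", "minus"))
            )
            reps.append(pair)
        sim = {
            "genome": genome,
            "annotation": annotation,
            "truth": truth,
            "r0": r0,
            "frags": None,
            "rounds": [{"round": cfg.rounds, "replicates": reps, "active_fraction": np.nan}],
            "ends": load_terminator_ends(outdir / "ends.bed"),
        }

    # -- stage: enrich + callpeaks ------------------------------------------
    called = call_matched_peaks(cfg, sim)
    # log10FE can be negative, so it is written directly (coverage tracks are
    # non-negative by type)
    for strand, name in (("+", "plus"), ("-", "minus")):
        prof = called["profiles"][strand]
        v = prof.log10fe
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends_ = np.concatenate((change, [v.size]))
        with open(outdir / f"log10fe.{name}.bedgraph", "w") as fh:
            for s, e in zip(starts, ends_):
                fh.write(f"{prof.chrom}\t{s}\t{e}\t{v[s]:.6g}\n")
    def by_pos(p):
        return (p.interval.chrom, p.interval.start)

    write_peaks(sorted(called["threshold"], key=by_pos), outdir / "peaks_threshold.bed")
    write_peaks(sorted(called["differential"], key=by_pos), outdir / "peaks_differential.bed")
    write_peaks(sorted(called["matched"], key=by_pos), outdir / "peaks_matched.bed")
    matched = called["matched"]

    # -- stage: context ------------------------------------------------------
    genome = sim["genome"]
    annotation = sim["annotation"]
    report = categorize_peaks(matched, annotation, operon_gap=cfg.operon_gap)
    report.promoter_proximal = find_promoter_proximal(
        matched, annotation.promoters, window=cfg.promoter_window
    )
    tandems = find_bidirectional_tandems(matched, max_gap=cfg.tandem_max_gap)
    for a, b in tandems:
        report.tandem_partner[a] = b
        report.tandem_partner[b] = a
    dists, ecdf = signed_distance_to_ends(sim["ends"], matched)
    by_class = {cls: vals for cls, vals in ecdf.items() if vals.size}
    try:
        chi_stat, chi_p, _obs, _exp = compare_distance_distributions(
            by_class, bins=cfg.distance_bins
        )
    except ValueError as exc:
        logger.info("distance chi-square not computed: %s", exc)
        chi_stat, chi_p = np.nan, np.nan
    if annotation.prophage_regions and matched:
        fold, perm_p, _obs = region_enrichment_permutation(
            matched, annotation.prophage_regions, genome.length, n_perm=cfg.n_perm, seed=seed + 6
        )
    else:
        fold, perm_p = np.nan, np.nan
    _pc, _gf, density_corr = windowed_density_profiles(
        matched, [g.interval for g in annotation.genes], genome.length, window=cfg.density_window
    )
    cat_df = pd.DataFrame(
        {
            "peak_id": list(report.category),
            "category": [report.category[k] for k in report.category],
            "promoter_proximal": [report.promoter_proximal.get(k, False) for k in report.category],
            "tandem_partner": [report.tandem_partner.get(k, "") for k in report.category],
        }
    )
    cat_df.to_csv(outdir / "peak_categories.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "end_chrom": d.end.chrom,
                "end_position": d.end.position,
                "strand": d.end.strand,
                "cls": d.end.cls,
                "peak_id": d.peak_id,
                "d": d.d,
            }
            for d in dists
        ]
    ).to_csv(outdir / "end_distances.tsv", sep="\t", index=False)

    # -- stage: features -----------------------------------------------------
    if matched:
        peak_seqs = extract_peak_sequences(genome, matched)
        if cfg.control_len_matched:
            ctl_len = int(np.median([p.interval.length for p in matched]))
        else:
            ctl_len = cfg.control_len
        controls = sample_rutless_controls(
            genome, matched, n=cfg.n_controls, length=ctl_len, seed=seed + 7
        )
        from .core import RutPeak

        control_peaks = [
            RutPeak(interval=iv, caller="THRESHOLD", peak_id=f"ctl{i}", median_log10fe=0.0, median_r0=0.0)
            for i, iv in enumerate(controls)
        ]
        control_seqs = extract_peak_sequences(genome, control_peaks)
        peak_desc = descriptor_table(
            peak_seqs, [p.peak_id for p in matched], backend=cfg.fold_backend
        )
        ctl_desc = descriptor_table(
            control_seqs, [f"ctl{i}" for i in range(len(controls))], backend=cfg.fold_backend
        )
        ranking = rank_descriptors(
            peak_desc, ctl_desc, alpha=cfg.descriptor_alpha, bh=cfg.descriptor_bh
        )
        peak_desc.to_csv(outdir / "descriptors_peaks.tsv", sep="\t")
        ctl_desc.to_csv(outdir / "descriptors_controls.tsv", sep="\t")
        ranking.to_csv(outdir / "descriptor_ranking.tsv", sep="\t")
        intervals_to_bed(controls, outdir / "controls.bed")
    else:
        ranking = pd.DataFrame()

    # -- stage: kinetics -----------------------------------------------------
    if sim["frags"] is not None:
        true_amps, curves = unwinding_amplitude_series(cfg, sim, seed)
        fits = [(r, fit_burst(c)) for r, c in curves]
        plateau_round, plateaued = detect_plateau_round(
            [(r, f.amplitude) for r, f in fits], rel_tol=cfg.plateau_rel_tol
        )
        with open(outdir / "kinetics_fits.tsv", "w") as fh:
            fh.write("round\ttrue_A\tfit_A\tfit_k\trss\n")
            for (r, f), (_r, A) in zip(fits, true_amps):
                fh.write(f"{r}\t{A:.6f}\t{f.amplitude:.6f}\t{f.rate:.6f}\t{f.rss:.6g}\n")
    else:
        plateau_round, plateaued = -1, False

    # -- recovery + summary + manifest --------------------------------------
    recovery, false_frac = recovery_stats(matched, sim["truth"])
    results = {
        "n_threshold": len(called["threshold"]),
        "n_differential": len(called["differential"]),
        "n_matched": len(matched),
        "density_per_mb": density_per_mb(len(matched), genome.length),
        "category_proportions": report.proportions,
        "n_tandem_pairs": len(tandems),
        "n_promoter_proximal": int(sum(report.promoter_proximal.values())),
        "distance_chi2": chi_stat,
        "distance_chi2_p": chi_p,
        "prophage_fold": fold,
        "prophage_p": perm_p,
        "gene_density_correlation": density_corr,
        "site_recovery": recovery,
        "matched_without_site": false_frac,
        "plateau_round": plateau_round,
        "plateaued": plateaued,
        "top_descriptors": (
            ranking.head(5).index.tolist() if len(ranking) else []
        ),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    manifest = {
        "rutscan_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".bed", ".tsv", ".bedgraph", ".fasta", ".gff3", ".json")
            and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def summarize_run(outdir: str | Path) -> dict:
    """One-page summary of a completed run: peak counts, densities,
    category proportions, top descriptors and the plateau round."""
    outdir = Path(outdir)
    results_path = outdir / "results.json"
    if not results_path.exists():
        raise FileNotFoundError(f"no results.json under {outdir}; incomplete run")
    with open(results_path) as fh:
        results = json.load(fh)
    lines = ["metric\tvalue"]
    for key in (
        "n_threshold",
        "n_differential",
        "n_matched",
        "density_per_mb",
        "n_tandem_pairs",
        "n_promoter_proximal",
        "site_recovery",
        "matched_without_site",
        "plateau_round",
    ):
        lines.append(f"{key}\t{results.get(key)}")
    props = results.get("category_proportions") or {}
    if results.get("n_matched", 0) == 0:
        props = {k: "NA" for k in props} or {"ANTISENSE": "NA"}
    for cat, frac in props.items():
        lines.append(f"proportion_{cat}\t{frac}")
    for i, d in enumerate(results.get("top_descriptors", []), 1):
        lines.append(f"top_descriptor_{i}\t{d}")
    (outdir / "summary.tsv").write_text("\n".join(lines) + "\n")
    return results
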