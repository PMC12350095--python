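"""Place Rut peaks in their genomic context.

Categorizes matched peaks against the annotation, finds bidirectional
tandems and promoter-proximal peaks, tests prophage over-representation by
permutation, and compares peak-to-3'-end distance distributions across
terminator classes.
"""

from rutscan.config import PipelineConfig
from rutscan.context import (
    categorize_peaks,
    compare_distance_distributions,
    find_bidirectional_tandems,
    find_promoter_proximal,
    region_enrichment_permutation,
    signed_distance_to_ends,
)
from rutscan.pipeline import call_matched_peaks, run_simulation

cfg = PipelineConfig()  # default study scale: 1 Mb, 200 sites
sim = run_simulation(cfg, seed=1)
matched = call_matched_peaks(cfg, sim)["matched"]
ann = sim["annotation"]

report = categorize_peaks(matched, ann, operon_gap=cfg.operon_gap)
print("category proportions:")
for cat, frac in report.proportions.items():
    print(f"  {cat:16s} {frac:.1%}")

tandems = find_bidirectional_tandems(matched)
proximal = find_promoter_proximal(matched, ann.promoters, window=cfg.promoter_window)
print(f"bidirectional tandem pairs: {len(tandems)}")
print(f"promoter-proximal peaks:    {sum(proximal.values())}")

fold, p, _ = region_enrichment_permutation(
    matched, ann.prophage_regions, sim["genome"].length, n_perm=cfg.n_perm, seed=1
)
print(f"prophage enrichment: fold={fold:.2f}, permutation p={p:.3f}")
# the toy generator plants sites uniformly, so fold ~ 1 is the expectation
# here; the permutation machinery is what a real screen would use to test
# xenogeneic-region over-representation

_, ecdf = signed_distance_to_ends(sim["ends"], matched)
stat, chi_p, _, _ = compare_distance_distributions(ecdf, cfg.distance_bins)
for cls, d in ecdf.items():
    print(f"  {cls:12s} n={len(d):3d}  fraction d<0: {(d < 0).mean():.2f}")
print(f"distance-by-class chi-square: {stat:.1f}, p={chi_p:.2g}")
# RDTT 3'-ends sit upstream of the peak edge (d<0) more often than
# Rho-stimulated IT ends: hairpin-protected ends resist exonucleolytic
# trimming, Rho-terminated ends do not.
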