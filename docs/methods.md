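# Methods

`rutscan` analyses Helicase-SELEX (H-SELEX) screens: iterative in-vitro
selections in which the Rho transcription termination factor unwinds
RNA–DNA duplexes whose RNA carries a functional Rho utilization (Rut)
site, thereby enriching a genomic fragment library in Rut-bearing
sequences. The pipeline maps Rut sites from strand-specific coverage of
the starting (R0) and enriched libraries, characterizes their sequence
and genomic context, and fits the selection's unwinding kinetics. A
synthetic-data generator reproduces the statistical structure of such a
screen so every stage can be exercised and validated against ground
truth.

## Enrichment model

Coverage tracks are per-base, per-strand arrays over a single replicon.
Raw tracks are scaled to reads per million (RPM) with one normalization
constant per library (both strands pooled). Enriched-replicate RPM
tracks are averaged arithmetically and compared with R0 as

    log10FE[i] = log10((enriched[i] + p) / (r0[i] + p))

with a pseudocount p = 1 RPM on both operands. The pseudocount only
guards finiteness; retained peaks are insensitive to p in [0.1, 1]
because of the downstream median filters.

## Peak calling

Two independent callers must agree:

* **Threshold caller** — maximal runs with log10FE > 0; runs separated
  by at most 30 below-cutoff positions are merged (gap positions
  included); merged intervals shorter than 30 nt are dropped. Retained
  peaks must additionally have a median R0 raw read count >= 1 per
  position and a median log10FE >= 0.3.
* **Differential caller** — a replicate-aware re-implementation of a
  count-based caller: the genome is tiled into 100-nt blocks; a block
  passes when the library-size-normalized log2 fold change (pseudocount
  one read) is >= 0.5 in *every* replicate and a pooled one-sided
  binomial test against the library-size ratio survives
  Benjamini–Hochberg adjustment at 0.05. With only two replicates a
  dispersion-estimating count model is unstable, so this gate
  deliberately combines a per-replicate effect-size requirement with a
  pooled exact test rather than fitting a negative-binomial model.
  Coverage mass is converted to approximate read counts by dividing by
  the mean fragment length (165 nt); because bases within a fragment
  are correlated the binomial tail is anticonservative on its own,
  which is acceptable in conjunction with the fold-change gate and
  cross-caller matching. The MAD filter parameter defaults to 0 (off).

A peak is **matched** when it overlaps (>= 1 nt, same strand) a peak
from the other caller; matched peaks keep the threshold caller's
coordinates, which are consistently narrower. Overlap everywhere in the
package requires at least one shared base: touching intervals do not
overlap.

## Synthetic screen

The generator is the package's definition of the study conditions; all
parameters live in `PipelineConfig` with these defaults:

| parameter | default | meaning |
|---|---|---|
| genome_length | 1 Mb | uniform-composition toy replicon |
| gene_density | 0.7 | fraction of genome covered by genes (500–2000 nt, both strands, 40-nt promoters upstream) |
| prophage_fraction | 0.1 | genome fraction marked as prophage (3 regions) |
| n_sites | 200 | planted Rut sites, 50–150 nt |
| site composition | C 35 / U 35 / A 22 / G 8 % | pyrimidine-rich, G-poor RNA-sense |
| site_antisense_prop | 0.8 | probability a gene-overlapping site is antisense to its gene |
| n_fragments | 300 000 | library fragments (30–300 nt, uniform starts/strands) |
| rounds | 6 | selection rounds |
| stringency | 1 → 3 linear | per-round selection exponent, emulating the shrinking reaction time across rounds |
| enrichment_base | 2.0 | retention advantage base of active fragments |
| replicate_noise_sd | 0.1 | lognormal multiplicative noise on per-fragment counts |

A fragment is *active* when it overlaps a planted site on the matching
strand by at least half the site length — a Rut site must be largely
contained in the transcript to load Rho. Its retention weight in round
r is `enrichment_base ** stringency[r]` times the site's activity score
(a logistic function of the site's pyrimidine percentage, so that
(%C+%U) = 60% maps to ~0.73 and 70% to ~0.88). Each round the fragment
multiset is resampled multinomially at fixed total; two replicates then
receive independent lognormal noise. The per-round share of the library
held by active fragments ("active fraction") is recorded and drives the
kinetics model below.

Transcript 3'-ends are placed to emulate the relation between Rut
sites and in-vivo termination: for half the sites an RDTT-class end is
placed a geometric offset (mean ~600 nt) downstream of the site's
downstream edge and then trimmed back upstream by an exponential offset
(mean 400 nt), emulating 3'-to-5' exonucleolytic processing; a further
quarter receive Rho-stimulated-IT ends with one-eighth of the trimming
(the terminator hairpin shields the end); strong-IT ends sit at gene
3'-ends far from any site. Distances are later measured to *called
peak* edges, which overshoot planted sites by roughly 180 nt of
fragment smear, so the offset and trimming means were chosen against
that reference: with them, the fraction of ends upstream of the peak
edge (d < 0) is substantially larger for RDTT than for Rho-stimulated
IT, and the binned distance distributions differ strongly across
classes.

What the generator does **not** emulate: read-level errors, PCR and
reverse-transcription bias, non-uniform fragmentation, genome repeats,
and any sequence-specific unwinding kinetics beyond the logistic
activity score. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the modeled statistics, not
performance on real sequencing data.

## Genomic context

Peak categories are exclusive: the gene context (same- versus
opposite-strand) with the largest summed overlap wins, ties going to
antisense; peaks without gene overlap are sense-intergenic when they
lie between co-oriented genes separated by at most 500 nt (an
operon-internal gap), else orphans. Bidirectional tandems pair
opposite-strand overlapping peaks greedily by decreasing overlap, ties
by leftmost pair. Promoter-proximal peaks overlap a promoter or end
within 100 nt upstream of a same-strand promoter start; the window is a
configuration choice, as is the tandem gap extension (default 0 =
overlap required).

Signed distance d of a 3'-end to a peak is measured from the peak's
downstream edge in the direction of transcription (plus strand:
d = end − peak.end; minus strand: d = peak.start − end); negative d
means the end lies upstream of the edge, the signature of
exonucleolytic trimming. Each end is assigned the same-strand peak
minimizing |d|, ties resolved toward d >= 0. Class distributions are
compared by a chi-square homogeneity test on the bins
(−∞,−100), [−100,0), [0,100), [100,500), [500,∞); bins empty in every
class are dropped, and an expected count below 1 raises instead of
silently producing an unreliable statistic.

Regional over-representation (e.g. in prophages) uses a permutation
null that redraws each peak's start uniformly with length and strand
preserved; p-values use the add-one estimator and are therefore never
below 1/(n_perm+1).

## Sequence descriptors and effect sizes

Descriptors are computed on RNA-sense peak sequences: base percentages
(over non-N positions), pyrimidine percentage, U−G and C−G biases, the
frequency of a pyrimidine followed by C per dinucleotide position, and
the folding minimum free energy both raw and per kilobase.

Folding is a Zuker-style dynamic program over Watson–Crick plus GU
pairs with a shipped simplified nearest-neighbor table: stacking
energies per adjacent pair of pairs, linear hairpin (>= 3-nt loop),
bulge and internal-loop penalties (interior loops enumerated up to 30
nt total), and an affine multiloop term (closing 3.4, per branch 0.4,
per unpaired 0.1 kcal/mol). The open chain scores 0, so the minimum is
always <= 0. The table is symmetrized so the energy is invariant under
sequence reversal, the symmetry a wobble-inclusive pair set actually
admits. The estimator targets ordering and direction among sequences;
absolute Mfold/ViennaRNA magnitudes are not claimed, and an external
`RNAfold` backend can be selected (`fold_backend: rnafold`) where
Mfold-scale values are required. An explicit-structure scorer using the
same table supports exhaustive-enumeration cross-checks.

Groups are compared per descriptor with two-sided Mann–Whitney U
tests; the standardized effect size is R = |Z| / sqrt(n1 + n2), the
standard rank-test definition, with Z recovered from the exact p-value
when the exact branch applies (n1 + n2 <= 16, no ties) and otherwise
computed with tie and continuity corrections. Descriptor screening uses
raw p <= 0.05 by default, with an optional Benjamini–Hochberg switch.

Rut-less control windows are sampled uniformly, rejecting windows that
touch any peak on either strand or contain N. The op default is
130-nt windows; the pipeline's descriptor stage instead samples
controls at the median matched-peak length (configurable). Called peaks
carry ~300 nt of fragment smear around the underlying site, and per-kb
minimum free energy deepens with sequence length, so 130-nt controls
against ~450-nt peaks would confound the structure comparison with
length; matching lengths removes the confound, exactly as comparable
peak and control lengths did in screens of real genomes.

## Unwinding kinetics

Time courses follow pseudo-first-order kinetics,
f(t) = A·(1 − e^(−kt)), with burst amplitude A equal to the active
library fraction scaled by a maximal unwinding efficiency (0.9) and a
fixed rate (0.2 /s, Gaussian noise sd 0.02). Fits are unweighted least
squares with A constrained to [0,1], A initialized at the maximal
observed fraction and k started from a log grid over 1e-3–10 /s, the
best grid start being refined; all-zero data return A = 0 with the rate
flagged unidentifiable. The enrichment plateau round is the smallest
round from which every subsequent amplitude step is below 5% of the
maximum amplitude — an explicit operationalization of the visual
plateau read-out, with the never-settling case flagged. The pipeline
builds its amplitude series from a 10-round counts-only selection run
so the plateau is reachable within the series.

## Numerical and design notes

* Coordinates are 0-based half-open throughout; GFF3 converts on the
  boundary. Touching intervals never overlap.
* All generators and the pipeline are deterministic given a seed;
  rerunning with the same configuration and seed reproduces
  byte-identical BED/TSV outputs (verified via manifest checksums).
* Peak density per Mb divides by **twice** the genome length: both
  strands are screened, and this is the only denominator that
  reconciles published peak counts with published densities.
* The block caller rounds block masses to integers for the binomial
  test; empty blocks get p = 1.
* Degenerate inputs raise rather than guess: empty fragment tables,
  empty regions, single-class distance tables, saturated control
  sampling, constant pooled rank data (p = 1, R = 0).
* In a full-default pipeline run the descriptor stage dominates the
  runtime: it folds all 5000 control windows at the matched peak length.
  Reduce `n_controls` (a few hundred amply powers the rank tests) for
  exploratory runs.
* Problem sizes used by the test-suite and the acceptance script
  (reduced genome sizes for integration fixtures, 300 control windows,
  three default-scale seeds in the script and ten in the recovery
  test) were chosen so a complete run finishes in minutes on one CPU
  while keeping every statistical assertion comfortably powered.

## Known limitations

* The differential caller approximates the role, not the internals, of
  published replicate-aware callers; block boundaries quantize peak
  edges to 100 nt.
* The folding parameter set is deliberately small; energies correlate
  with, but do not reproduce, full nearest-neighbor models.
* Called peak edges inherit the fragment-length smear of the library,
  overshooting the underlying site by up to a few hundred nt — the same
  overshoot reported for screens of real genomes — so peak coordinates
  should be read as containing, not delimiting, the functional site.
* Single-replicon genomes only; multi-chromosome support would extend
  the coordinate layer.
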