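import numpy as np
import pytest


from rutscan.core import GenomicInterval
from rutscan.synth import (
    FragmentTable,
    SelectionConfig,
    TruthRegistry,
    fragment_site_activity,
    generate_toy_genome,
    plant_rut_sites,
    simulate_fragment_coverage,
    simulate_selection,
    simulate_terminator_ends,
    simulate_unwinding,
)


class TestToyGenome:
    def test_seed_determinism(self):
        g1, a1 = generate_toy_genome(20_000, seed=7)
        g2, a2 = generate_toy_genome(20_000, seed=7)
        assert g1.sequence == g2.sequence
        assert [g.interval for g in a1.genes] == [g.interval for g in a2.genes]
        g3, _ = generate_toy_genome(20_000, seed=8)
        assert g3.sequence != g1.sequence

    def test_zero_gene_density(self):
        _, ann = generate_toy_genome(20_000, gene_density=0, seed=1)
        assert not ann.genes and not ann.promoters

    def test_background_composition_near_uniform(self):
        g, _ = generate_toy_genome(100_000, gene_density=0, prophage_fraction=0, seed=3)
        for b in "ACGT":
            assert abs(g.sequence.count(b) / g.length - 0.25) < 0.02

    def test_genes_do_not_overlap_and_promoters_upstream(self):
        _, ann = generate_toy_genome(50_000, seed=2)
        ivs = sorted((g.interval for g in ann.genes), key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))
        assert len(ann.promoters) > 0


class TestPlantSites:
    def test_sites_more_pyrimidine_rich_than_background(self):
        g0, ann = generate_toy_genome(100_000, seed=4)
        g, truth = plant_rut_sites(g0, ann, n_sites=30, seed=4)

        def pyr_frac(iv):
            s = g.sequence[iv.start : iv.end]
            if iv.strand == "-":
                s = s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            return (s.count("C") + s.count("T")) / len(s)

        site_pyr = np.mean([pyr_frac(s.interval) for s in truth.planted_sites])
        rng = np.random.default_rng(0)
        bg = []
        for _ in range(100):
            st = int(rng.integers(0, g.length - 100))
            bg.append(pyr_frac(GenomicInterval(g.name, st, st + 100, "+")))
        assert site_pyr > np.mean(bg) + 0.1

    def test_zero_sites_identity(self):
        g0, ann = generate_toy_genome(20_000, seed=5)
        g, truth = plant_rut_sites(g0, ann, n_sites=0, seed=5)
        assert g.sequence == g0.sequence and not truth.planted_sites

    def test_antisense_proportion(self):
        g0, ann = generate_toy_genome(300_000, seed=6)
        _, truth = plant_rut_sites(g0, ann, n_sites=100, antisense_prop=0.8, seed=6)
        gene_ivs = [g.interval for g in ann.genes]
        anti = tot = 0
        for s in truth.planted_sites:
            mid = (s.interval.start + s.interval.end) // 2
            hit = [g for g in gene_ivs if g.start <= mid < g.end]
            if hit:
                tot += 1
                anti += s.interval.strand != hit[0].strand
        # binomial tolerance around 0.8
        assert tot > 30
        assert abs(anti / tot - 0.8) < 3 * np.sqrt(0.8 * 0.2 / tot)

    def test_sites_non_overlapping_invariant(self):
        g0, ann = generate_toy_genome(50_000, seed=7)
        _, truth = plant_rut_sites(g0, ann, n_sites=40, seed=7)
        truth.validate()

    def test_infeasible_density_errors(self):
        g0, ann = generate_toy_genome(10_000, seed=8)
        with pytest.raises(ValueError):
            plant_rut_sites(g0, ann, n_sites=200, seed=8)


class TestFragmentCoverage:
    def test_single_fragment_coverage_definition(self):
        g, _ = generate_toy_genome(10_000, gene_density=0, seed=9)
        plus, minus, frags = simulate_fragment_coverage(g, n_fragments=1, seed=9)
        track = plus if frags.strands[0] == 0 else minus
        s, e = frags.starts[0], frags.starts[0] + frags.lengths[0]
        assert np.all(track.values[s:e] == 1)
        assert track.values.sum() == e - s

    def test_breadth_at_study_depth(self):
        # ~25x per-strand depth at mean length 165 covers >= 98% of positions
        L = 100_000
        n = int(2 * 25 * L / 165)
        breadths = []
        for seed in range(5):
            g, _ = generate_toy_genome(L, gene_density=0, prophage_fraction=0, seed=seed)
            plus, minus, _ = simulate_fragment_coverage(g, n_fragments=n, seed=seed)
            both = (plus.values > 0) & (minus.values > 0)
            breadths.append(both.mean())
        assert np.mean(breadths) >= 0.98

    def test_seed_determinism(self):
        g, _ = generate_toy_genome(20_000, seed=10)
        p1, _, _ = simulate_fragment_coverage(g, n_fragments=5000, seed=3)
        p2, _, _ = simulate_fragment_coverage(g, n_fragments=5000, seed=3)
        np.testing.assert_array_equal(p1.values, p2.values)


@pytest.fixture(scope="module")
def setup():
    g0, ann = generate_toy_genome(100_000, seed=11)
    g, truth = plant_rut_sites(g0, ann, n_sites=20, seed=11)
    _, _, frags = simulate_fragment_coverage(g, n_fragments=30_000, seed=11)
    return g, truth, frags


class TestSelection:

    def test_null_selection_does_not_enrich_planted_sites(self, setup):
        # with enrichment_base=1 the resampling is a plain bootstrap: the
        # share of the library held by site-bearing fragments must not grow
        g, truth, frags = setup
        act = fragment_site_activity(frags, truth) > 0
        initial = act.mean()
        for seed in range(3):
            cfg = SelectionConfig(rounds=3, enrichment_base=1.0, replicate_noise_sd=0.0, seed=seed)
            rounds = simulate_selection(g, frags, truth, cfg, emit_rounds="all")
            for r in rounds:
                assert abs(r["active_fraction"] - initial) < 0.2 * initial + 0.005

    def test_planted_enrichment_monotone_over_rounds(self, setup):
        g, truth, frags = setup
        ratios_by_round = []
        for seed in range(5):
            cfg = SelectionConfig(rounds=4, seed=seed)
            rounds = simulate_selection(g, frags, truth, cfg, emit_rounds="all")
            ratios_by_round.append([r["active_fraction"] for r in rounds])
        mean = np.mean(ratios_by_round, axis=0)
        assert np.all(np.diff(mean) > 0)

    def test_zero_noise_replicates_identical(self, setup):
        g, truth, frags = setup
        cfg = SelectionConfig(rounds=2, replicate_noise_sd=0.0, seed=1)
        rounds = simulate_selection(g, frags, truth, cfg, emit_rounds="last")
        a, b = rounds[-1]["replicates"]
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_fragment_total_conserved(self, setup):
        g, truth, frags = setup
        cfg = SelectionConfig(rounds=3, seed=2)
        rounds = simulate_selection(g, frags, truth, cfg, emit_rounds="all")
        for r in rounds:
            assert r["counts"].sum() == frags.n

    def test_empty_fragment_table_errors(self, setup):
        g, truth, _ = setup
        empty = FragmentTable(np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(ValueError):
            simulate_selection(g, empty, truth, SelectionConfig())

    def test_activity_requires_half_site_overlap(self):
        g0, ann = generate_toy_genome(20_000, gene_density=0, seed=12)
        g, truth = plant_rut_sites(g0, ann, n_sites=1, min_len=100, max_len=100, seed=12)
        site = truth.planted_sites[0].interval
        scode = 0 if site.strand == "+" else 1
        # one fragment covering 60% of the site, one covering 40%
        frags = FragmentTable(
            starts=np.array([site.start, site.start + 60]),
            lengths=np.array([60, 40]),
            strands=np.array([scode, scode]),
        )
        act = fragment_site_activity(frags, truth)
        assert act[0] > 0 and act[1] == 0


@pytest.fixture(scope="module")
def truth_ann():
    g0, ann = generate_toy_genome(200_000, seed=13)
    g, truth = plant_rut_sites(g0, ann, n_sites=40, seed=13)
    return g, ann, truth


class TestTerminatorEnds:

    def _site_edge_d(self, truth, ends):
        # signed distance from each linked site's downstream edge
        out = {}
        for idx, end in truth.planted_end_links.items():
            iv = truth.planted_sites[idx].interval
            d = end.position - iv.end if iv.strand == "+" else iv.start - end.position
            out.setdefault(end.cls, []).append(d)
        return out

    def test_zero_trimming_gives_nonnegative_rdtt_distances(self, truth_ann):
        g, ann, truth = truth_ann
        truth.planted_end_links.clear()
        ends = simulate_terminator_ends(truth, ann, g.length, trim_mean=0.0, seed=1)
        d = self._site_edge_d(truth, ends)
        assert all(x >= 0 for x in d["RDTT"])

    def test_heavy_trimming_shifts_rdtt_upstream_of_rho_stim(self, truth_ann):
        g, ann, truth = truth_ann
        truth.planted_end_links.clear()
        ends = simulate_terminator_ends(truth, ann, g.length, trim_mean=400.0, seed=2)
        d = self._site_edge_d(truth, ends)
        neg = {c: np.mean([x < 0 for x in v]) for c, v in d.items()}
        assert neg["RDTT"] > neg["RHO_STIM_IT"]

    def test_seed_determinism_and_empty_truth_error(self, truth_ann):
        g, ann, truth = truth_ann
        e1 = simulate_terminator_ends(truth, ann, g.length, seed=3)
        e2 = simulate_terminator_ends(truth, ann, g.length, seed=3)
        assert e1 == e2
        with pytest.raises(ValueError):
            simulate_terminator_ends(TruthRegistry(), ann, g.length, seed=3)


class TestUnwinding:
    def test_closed_form_value(self):
        c = simulate_unwinding(0.8, 0.2, [5, 10, 20], noise_sd=0.0)
        assert c.fraction_unwound[1] == pytest.approx(0.8 * (1 - np.exp(-2)), abs=1e-12)

    def test_time_zero_is_zero_without_noise(self):
        c = simulate_unwinding(0.8, 0.2, [0, 5, 10], noise_sd=0.0)
        assert c.fraction_unwound[0] == 0.0

    def test_noiseless_curve_monotone(self):
        c = simulate_unwinding(0.5, 0.7, np.linspace(1, 100, 30), noise_sd=0.0)
        assert np.all(np.diff(c.fraction_unwound) >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_unwinding(1.2, 0.2, [1, 2, 3])
        with pytest.raises(ValueError):
            simulate_unwinding(0.5, 0.2, [1, 1, 2])
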