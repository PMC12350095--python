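
import numpy as np
import pytest
from scipy import stats

from conftest import make_peak
from rutscan.core import GenomeSequence
from rutscan.features import (
    categorical_test,
    compute_descriptors,
    descriptor_table,
    extract_peak_sequences,
    mannwhitney_effect_size,
    rank_descriptors,
    sample_rutless_controls,
)
from rutscan.fold import fold_min_energy, pairable, structure_energy

def enumerate_structures(seq):
    """All nested structures (hairpin loops >= 3) over the WC+GU pair set."""
    n = len(seq)
    cand = [(i, j) for i in range(n) for j in range(i + 4, n) if pairable(seq[i], seq[j])]

    def compatible(p, chosen):
        i, j = p
        for a, b in chosen:
            if len({i, j, a, b}) < 4:
                return False
            if (a < i < b < j) or (i < a < j < b):
                return False
        return True

    out = []

    def rec(chosen, rest):
        out.append(list(chosen))
        for k, p in enumerate(rest):
            if compatible(p, chosen):
                rec(chosen + [p], rest[k + 1 :])

    rec([], cand)
    return out

class TestFolding:
    def test_poly_a_has_no_structure(self):
        assert fold_min_energy("A" * 20) == 0.0

    def test_simple_hairpin_matches_enumeration(self):
        seq = "GGGGAAAACCCC"
        best = min(
            [0.0] + [structure_energy(seq, s) for s in enumerate_structures(seq) if s]
        )
        assert fold_min_energy(seq) == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(5, 14))
            seq = "".join(rng.choice(list("ACGU"), n))
            best = min(
                [0.0] + [structure_energy(seq, s) for s in enumerate_structures(seq) if s]
            )
            assert fold_min_energy(seq) == pytest.approx(best, abs=1e-9), seq

    def test_reversal_symmetry_of_parameter_set(self):
        # the shipped stack table satisfies S[a][b] == S[flip a][flip b], so
        # the minimum energy is invariant under sequence reversal
        rng = np.random.default_rng(42)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), 30))
            assert fold_min_energy(seq) == pytest.approx(fold_min_energy(seq[::-1]), abs=1e-9)

    def test_dna_alphabet_rejected_with_advice(self):
        with pytest.raises(ValueError, match="T to U"):
            fold_min_energy("ACGT")

    def test_n_bases_never_pair(self):
        assert fold_min_energy("GGGGNNNNCCCC".replace("N", "N")) <= 0.0
        assert fold_min_energy("NNNNNNNNNNNN") == 0.0

class TestExtractSequences:
    GENOME = GenomeSequence("toy", "AACGT" + "A" * 95)

    def test_plus_strand_transcription(self):
        (s,) = extract_peak_sequences(self.GENOME, [make_peak(0, 35, "+")])
        assert s[:5] == "AACGU"

    def test_minus_strand_reverse_complement(self):
        g = GenomeSequence("toy", "AACGT")
        peaks = [
            make_peak(0, 40, "-", fe=0.5)
        ]  # peak type needs >=30nt; use a wider genome below
        g100 = GenomeSequence("toy", "AACGT" + "A" * 95)
        (s,) = extract_peak_sequences(g100, peaks)
        assert s.endswith("ACGUU")  # revcomp of AACGT = ACGTT -> ACGUU

    def test_empty_peak_list(self):
        assert extract_peak_sequences(self.GENOME, []) == []

class TestDescriptors:
    def test_pyrimidine_rich_counting(self):
        row = compute_descriptors("UUUUCCCC")
        assert row["pct_pyrimidine"] == 100.0
        assert row["bias_U_G"] == 50.0 and row["bias_C_G"] == 50.0

    def test_purine_rich_counting(self):
        row = compute_descriptors("AAAAGGGG")
        assert row["pct_pyrimidine"] == 0.0 and row["bias_U_G"] == -50.0

    def test_balanced_sequence(self):
        row = compute_descriptors("ACGUACGU")
        assert row["pct_A"] == row["pct_C"] == row["pct_G"] == row["pct_U"] == 25.0
        assert row["bias_U_G"] == 0.0

    def test_percentages_sum_and_dg_sign(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 40))
            row = compute_descriptors(seq)
            total = row["pct_A"] + row["pct_C"] + row["pct_G"] + row["pct_U"]
            assert total == pytest.approx(100.0, abs=1e-6)
            assert row["dG_per_kb"] <= 0
            assert row["dG_per_kb"] == pytest.approx(row["dG"] * 1000 / 40)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_descriptors("ACGU")

class TestControls:
    GENOME = GenomeSequence("toy", "ACGT" * 25_000)  # 100 kb

    def test_no_peaks_all_accepted(self):
        ivs = sample_rutless_controls(self.GENOME, [], n=50, length=130, seed=0)
        assert len(ivs) == 50 and all(iv.length == 130 for iv in ivs)

    def test_windows_never_intersect_peaks_either_strand(self):
        peaks = [make_peak(s, s + 500, "+" if i % 2 else "-") for i, s in enumerate(range(0, 50_000, 2_000))]
        ivs = sample_rutless_controls(self.GENOME, peaks, n=100, length=130, seed=1)
        for iv in ivs:
            for p in peaks:
                assert not iv.overlaps(p.interval, stranded=False)

    def test_saturated_genome_errors(self):
        peaks = [make_peak(s, min(s + 5_000, 100_000)) for s in range(0, 100_000, 5_000)]
        with pytest.raises(ValueError, match="could only place"):
            sample_rutless_controls(self.GENOME, peaks, n=10, length=130, seed=2)

    def test_deterministic_per_seed(self):
        a = sample_rutless_controls(self.GENOME, [], n=20, length=130, seed=3)
        b = sample_rutless_controls(self.GENOME, [], n=20, length=130, seed=3)
        assert a == b

class TestMannWhitney:
    def test_exact_micro_example(self):
        r = mannwhitney_effect_size([1, 2], [3, 4])
        assert r.U == 0.0
        assert r.p == pytest.approx(2 / 6, abs=1e-12)

    def test_constant_data_null(self):
        r = mannwhitney_effect_size([5, 5, 5], [5, 5, 5])
        assert r.p == 1.0 and r.R == 0.0

    def test_identical_groups_zero_effect(self, rng):
        x = rng.normal(size=30)
        r = mannwhitney_effect_size(x, x.copy())
        assert r.R < 0.05

    def test_branches_agree_for_moderate_n(self):
        rng = np.random.default_rng(7)
        deltas = []
        for _ in range(100):
            x = rng.uniform(0, 1, 8)
            y = rng.uniform(0.2, 1.2, 8)
            pe = mannwhitney_effect_size(x, y, method="exact").p
            pa = mannwhitney_effect_size(x, y, method="asymptotic").p
            deltas.append(abs(pe - pa))
        assert max(deltas) <= 0.02

    def test_matches_scipy_asymptotic_direction(self, rng):
        x = rng.normal(1.5, 1, 50)
        y = rng.normal(0.0, 1, 50)
        r = mannwhitney_effect_size(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert r.p == pytest.approx(ref.pvalue, rel=0.05)
        assert r.direction == 1 and r.R > 0.3

class TestCategorical:
    def test_fisher_enumerated_example(self):
        _, p = categorical_test([[2, 0], [0, 2]], "fisher")
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_fisher_balanced_table(self):
        _, p = categorical_test([[5, 5], [5, 5]], "fisher")
        assert p == 1.0

    def test_chisq_hand_computation(self):
        stat, _ = categorical_test([[10, 0], [0, 10]], "chisq")
        assert stat == pytest.approx(20.0)

    def test_fisher_rejects_rxc(self):
        with pytest.raises(ValueError):
            categorical_test([[1, 2, 3], [4, 5, 6]], "fisher")
        with pytest.raises(ValueError):
            categorical_test([[1.5, 2], [3, 4]], "fisher")

class TestRankDescriptors:
    def test_null_significant_fraction_near_alpha(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        sig = total = 0
        for _ in range(150):
            a = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
            b = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
            out = rank_descriptors(a, b)
            sig += int(out["significant"].sum())
            total += 4
        frac = sig / total
        assert 0.02 < frac < 0.09  # ~alpha=0.05 under the null

    def test_shifted_descriptor_ranks_first(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        for _ in range(5):
            a = pd.DataFrame(rng.normal(size=(200, 3)), columns=["u", "v", "w"])
            b = pd.DataFrame(rng.normal(size=(200, 3)), columns=["u", "v", "w"])
            a["v"] += 3.0
            out = rank_descriptors(a, b)
            assert out.index[0] == "v" and out.iloc[0]["significant"]

    def test_empty_intersection_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            rank_descriptors(pd.DataFrame({"a": [1, 2]}), pd.DataFrame({"b": [1, 2]}))

class TestPeakVsControlDirectionality:
    def test_peaks_more_pyrimidine_rich_and_less_structured(self, small_run):
        sim, called = small_run
        matched = called["matched"]
        seqs = extract_peak_sequences(sim["genome"], matched)
        peak_desc = descriptor_table(seqs, [p.peak_id for p in matched])
        med_len = int(np.median([p.interval.length for p in matched]))
        ctls = sample_rutless_controls(
            sim["genome"], matched, n=150, length=med_len, seed=5
        )
        ctl_peaks = [
            make_peak(iv.start, iv.end, iv.strand, f"c{i}") for i, iv in enumerate(ctls)
        ]
        ctl_desc = descriptor_table(
            extract_peak_sequences(sim["genome"], ctl_peaks),
            [p.peak_id for p in ctl_peaks],
        )
        pyr = mannwhitney_effect_size(
            peak_desc["pct_pyrimidine"], ctl_desc["pct_pyrimidine"], "pct_pyrimidine"
        )
        dg = mannwhitney_effect_size(
            peak_desc["dG_per_kb"], ctl_desc["dG_per_kb"], "dG_per_kb"
        )
        assert pyr.direction == 1 and pyr.p < 0.01 and pyr.R > 0.3
        assert dg.direction == 1 and dg.p < 0.01  # less negative = weaker structure

class TestEffectSizeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_r_and_u_stay_in_range(self, x, y):
        r = mannwhitney_effect_size(x, y)
        assert 0 <= r.R <= 1
        assert 0 <= r.U <= r.n1 * r.n2
        assert 0 <= r.p <= 1
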