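"""Sequence descriptors of Rut peaks, Rut-less control sampling, and
rank-test effect sizes.

Descriptors are computed on the RNA-sense sequence of each peak: base
percentages, pyrimidine content, U-G and C-G biases, the YC dinucleotide
frequency (a proxy for Rho primary-binding-site contacts), and the folding
minimum free energy both raw and normalized per kilobase.  Groups are
compared with two-sided Mann-Whitney U tests and ranked by the standardized
effect size R = |Z| / sqrt(n1 + n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeSequence, GenomicInterval, RutPeak
from .fold import fold_min_energy

_RC = str.maketrans("ACGTN", "TGCAN")

DESCRIPTOR_COLUMNS = (
    "length",
    "pct_A",
    "pct_C",
    "pct_G",
    "pct_U",
    "pct_pyrimidine",
    "bias_U_G",
    "bias_C_G",
    "yc_dinucleotide_freq",
    "dG",
    "dG_per_kb",
)


@dataclass(frozen=True)
class EffectSizeResult:
    descriptor: str
    U: float
    p: float
    R: float
    direction: int  # sign of median(x) - median(y)
    n1: int
    n2: int

    def __post_init__(self):
        if not 0 <= self.R <= 1 + 1e-12:
            raise ValueError("R must lie in [0,1]")
        if not 0 <= self.U <= self.n1 * self.n2:
            raise ValueError("U out of range")


def extract_peak_sequences(genome: GenomeSequence, peaks: list[RutPeak]) -> list[str]:
    """RNA-sense sequence of each peak: plus-strand peaks transcribe the
    genome substring (T->U); minus-strand peaks its reverse complement."""
    out = []
    for p in peaks:
        iv = p.interval
        if iv.end > genome.length:
            raise ValueError(f"peak {p.peak_id} outside genome bounds")
        s = genome.sequence[iv.start : iv.end]
        if iv.strand == "-":
            s = s.translate(_RC)[::-1]
        out.append(s.replace("T", "U"))
    return out


def compute_descriptors(seq: str, backend: str = "internal") -> dict:
    """One descriptor row for an RNA-alphabet sequence (>= 10 nt).

    Percentages are over non-N positions; the YC frequency counts pyrimidine
    followed by C per dinucleotide position; dG_per_kb is the folding minimum
    free energy scaled by 1000 / length.
    """
    if len(seq) < 8:
        raise ValueError("descriptors need sequences of length >= 8")
    counts = {b: seq.count(b) for b in "ACGU"}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all-N sequence has no descriptors")
    pct = {b: 100.0 * c / n for b, c in counts.items()}
    yc = sum(
        1 for t in range(len(seq) - 1) if seq[t] in "CU" and seq[t + 1] == "C"
    ) / (len(seq) - 1)
    dg = fold_min_energy(seq, backend=backend)
    return {
        "length": len(seq),
        "pct_A": pct["A"],
        "pct_C": pct["C"],
        "pct_G": pct["G"],
        "pct_U": pct["U"],
        "pct_pyrimidine": pct["C"] + pct["U"],
        "bias_U_G": pct["U"] - pct["G"],
        "bias_C_G": pct["C"] - pct["G"],
        "yc_dinucleotide_freq": yc,
        "dG": dg,
        "dG_per_kb": dg * 1000.0 / len(seq),
    }


def descriptor_table(seqs: list[str], ids: list[str] | None = None, backend: str = "internal") -> pd.DataFrame:
    ids = ids or [f"seq{i}" for i in range(len(seqs))]
    rows = [compute_descriptors(s, backend=backend) for s in seqs]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return df


def sample_rutless_controls(
    genome: GenomeSequence,
    peaks: list[RutPeak],
    n: int = 5000,
    length: int = 130,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Uniform random fixed-length windows not intersecting any peak on
    either strand and free of N, exactly ``n`` of them, deterministic per
    seed.  Raises (reporting the achievable count) when the rejection budget
    is exhausted."""
    rng = np.random.default_rng(seed)
    L = genome.length
    if length > L:
        raise ValueError("control length exceeds genome length")
    blocked = np.zeros(L, dtype=bool)
    for p in peaks:
        blocked[p.interval.start : p.interval.end] = True
    has_n = np.frombuffer(genome.sequence.encode(), dtype=np.uint8) == ord("N")
    bad = blocked | has_n
    # prefix sums let a window be vetted in O(1)
    cum = np.concatenate(([0], np.cumsum(bad)))
    out: list[GenomicInterval] = []
    budget = 200 * n
    draws = 0
    while len(out) < n:
        if draws >= budget:
            raise ValueError(
                f"could only place {len(out)} of {n} Rut-less windows within budget"
            )
        batch = min(4 * (n - len(out)), budget - draws)
        starts = rng.integers(0, L - length + 1, size=batch)
        strands = rng.integers(0, 2, size=batch)
        draws += batch
        ok = cum[starts + length] - cum[starts] == 0
        for s, st in zip(starts[ok], strands[ok]):
            out.append(
                GenomicInterval(genome.name, int(s), int(s) + length, "+" if st == 0 else "-")
            )
            if len(out) == n:
                break
    return out


# ---------------------------------------------------------------------------
# rank tests and effect sizes
# ---------------------------------------------------------------------------


def mannwhitney_effect_size(x, y, name: str = "", method: str = "auto") -> EffectSizeResult:
    """Two-sided Mann-Whitney U with standardized effect size R = |Z|/sqrt(N).

    Exact enumeration (via the exact null distribution of U) when
    n1 + n2 <= 16 and the pooled data are tie-free, otherwise the normal
    approximation with tie and continuity corrections; for the exact branch
    Z is recovered from the exact p-value.  ``method`` forces a branch
    ('exact' / 'asymptotic').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 observations")
    N = n1 + n2
    pooled = np.concatenate([x, y])
    direction = int(np.sign(np.median(x) - np.median(y)))
    if np.all(pooled == pooled[0]):
        return EffectSizeResult(name, U=n1 * n2 / 2, p=1.0, R=0.0, direction=0, n1=n1, n2=n2)
    ties = np.unique(pooled).size < N
    use_exact = (N <= 16 and not ties) if method == "auto" else method == "exact"
    if use_exact and ties:
        raise ValueError("exact branch requires tie-free data")
    if use_exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        z = float(stats.norm.isf(min(p, 1.0) / 2)) if p < 1 else 0.0
        return EffectSizeResult(
            name, U=float(res.statistic), p=p, R=min(abs(z) / np.sqrt(N), 1.0),
            direction=direction, n1=n1, n2=n2,
        )
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    sigma2 = n1 * n2 / 12 * (N + 1 - tie_term)
    if sigma2 <= 0:
        return EffectSizeResult(name, U=float(u1), p=1.0, R=0.0, direction=0, n1=n1, n2=n2)
    sigma = np.sqrt(sigma2)
    # continuity correction of 0.5 toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma if u1 != mu else 0.0
    p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
    return EffectSizeResult(
        name, U=float(u1), p=p, R=min(abs(z) / np.sqrt(N), 1.0),
        direction=direction, n1=n1, n2=n2,
    )


def categorical_test(table, method: str = "fisher") -> tuple[float, float]:
    """Fisher's exact (two-sided, 2x2 only) or Pearson chi-square without
    continuity correction; returns (statistic, p)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if method == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if method == "chisq":
        stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    raise ValueError(f"unknown method {method!r}")


def rank_descriptors(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """One Mann-Whitney test per shared descriptor column, ranked by R.

    Raw p <= alpha flags significance by default; ``bh=True`` switches to a
    Benjamini-Hochberg adjusted threshold.  The full table (including
    non-significant descriptors) is returned, significant rows first, each
    block sorted by R descending.
    """
    common = [c for c in group_a.columns if c in group_b.columns]
    if not common:
        raise ValueError("no shared descriptor columns between groups")
    rows = []
    for col in common:
        r = mannwhitney_effect_size(group_a[col].to_numpy(), group_b[col].to_numpy(), name=col)
        rows.append(
            {
                "descriptor": col, "U": r.U, "p": r.p, "R": r.R,
                "direction": r.direction, "n1": r.n1, "n2": r.n2,
            }
        )
    df = pd.DataFrame(rows).set_index("descriptor")
    pcol = df["p"].to_numpy()
    if bh:
        df["p_adj"] = stats.false_discovery_control(pcol, method="bh")
        df["significant"] = df["p_adj"] <= alpha
    else:
        df["significant"] = df["p"] <= alpha
    return df.sort_values(["significant", "R"], ascending=[False, False])
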