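"""Minimum free energy of nested RNA secondary structure.

A Zuker-style dynamic program over Watson-Crick + GU wobble pairs with a
shipped, simplified nearest-neighbor parameter set: stacking energies per
adjacent pair of pairs, linear hairpin / bulge / internal loop penalties
(hairpin loops >= 3 nt), and an affine multiloop penalty (closing + per
branch + per unpaired base).  The unstructured chain has energy zero, so the
reported minimum is always <= 0.

The same parameter table drives :func:`structure_energy`, which scores an
explicit structure by loop decomposition; the DP minimum equals the minimum
of ``structure_energy`` over all admissible structures.

This estimator targets ordering and direction, not Mfold-magnitude
agreement; an external ``RNAfold`` backend can be plugged in where
Mfold-compatible values are needed.
"""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
from numba import njit

MAXLOOP = 30  # largest bulge/internal loop enumerated (nt, both sides summed)

# pair type indices: AU UA CG GC GU UG
_PAIR_IDX = -np.ones((5, 5), dtype=np.int64)
for _i, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_IDX[_a, _b] = _i

_FLIP = np.array([1, 0, 3, 2, 5, 4])  # AU<->UA, CG<->GC, GU<->UG

# Simplified stacking free energies (kcal/mol), outer pair x inner pair,
# symmetrized so that S[a,b] == S[flip(a),flip(b)] (sequence-reversal
# symmetry of the shipped parameter set).
_RAW_STACK = np.array(
    [
        # inner: AU     UA     CG     GC     GU     UG
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # outer AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # outer UA
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],  # outer CG
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],  # outer GC
        [-1.3, -1.4, -2.5, -2.1, -0.5, -0.4],  # outer GU
        [-1.0, -0.6, -1.5, -1.4, -0.2, -0.5],  # outer UG
    ]
)
STACK = 0.5 * (_RAW_STACK + _RAW_STACK[np.ix_(_FLIP, _FLIP)])

HAIRPIN_A, HAIRPIN_B = 4.5, 0.12    # closing + per-nt loop penalty
BULGE_A, BULGE_B = 3.8, 0.25
INTERNAL_A, INTERNAL_B = 4.0, 0.25
MULTI_A, MULTI_B, MULTI_C = 3.4, 0.4, 0.1  # closing, per branch, per unpaired

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    if "T" in seq:
        raise ValueError("DNA alphabet detected: transcribe T to U before folding")
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r}") from None


@njit(cache=True)
def _dp(code, pair_idx, stack, hpA, hpB, bA, bB, iA, iB, mA, mB, mC, maxloop):
    n = code.size
    INF = 1e9
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M2 = np.full((n, n), INF)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            a, b = code[i], code[j]
            pt = pair_idx[a, b] if a < 4 and b < 4 else -1
            if pt >= 0:
                best = hpA + hpB * (span - 1)
                for k in range(i + 1, j - 3):
                    left = k - i - 1
                    if left > maxloop:
                        break
                    lmin = max(k + 4, j - 1 - (maxloop - left))
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= INF:
                            continue
                        gap = left + (j - l - 1)
                        if left == 0 and j - l - 1 == 0:
                            ck, cl = code[k], code[l]
                            e = stack[pt, pair_idx[ck, cl]] + V[k, l]
                        elif left == 0 or j - l - 1 == 0:
                            e = bA + bB * gap + V[k, l]
                        else:
                            e = iA + iB * gap + V[k, l]
                        if e < best:
                            best = e
                if M2[i + 1, j - 1] < INF:
                    e = mA + M2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # M: >= 1 multiloop branch on [i..j]
            m = INF
            if M[i + 1, j] + mC < m:
                m = M[i + 1, j] + mC
            if M[i, j - 1] + mC < m:
                m = M[i, j - 1] + mC
            if pt >= 0 and V[i, j] + mB < m:
                m = V[i, j] + mB
            m2 = INF
            for k in range(i + 1, j + 1):
                if M[i, k - 1] < INF and M[k, j] < INF:
                    cand = M[i, k - 1] + M[k, j]
                    if cand < m2:
                        m2 = cand
            if m2 < m:
                m = m2
            M[i, j] = m
            M2[i, j] = m2
    # exterior loop: unpaired bases are free
    w = np.zeros(n)
    for j in range(n):
        best = w[j - 1] if j > 0 else 0.0
        for i in range(0, j - 3):
            if V[i, j] < INF:
                cand = (w[i - 1] if i > 0 else 0.0) + V[i, j]
                if cand < best:
                    best = cand
        w[j] = best
    return w[n - 1] if n > 0 else 0.0


def fold_min_energy(seq: str, backend: str = "internal") -> float:
    """Minimum free energy (kcal/mol, <= 0) of ``seq`` over nested structures.

    ``backend='rnafold'`` delegates to the ViennaRNA ``RNAfold`` executable
    when available (Mfold-magnitude values); the default internal DP uses the
    shipped simplified parameter table.
    """
    if len(seq) > 5000:
        raise ValueError("sequences longer than 5000 nt are not supported")
    if backend == "rnafold":
        return _rnafold_energy(seq)
    if backend != "internal":
        raise ValueError(f"unknown folding backend {backend!r}")
    code = _encode(seq)
    if code.size < 5:
        return 0.0
    e = _dp(
        code,
        _PAIR_IDX,
        STACK,
        HAIRPIN_A,
        HAIRPIN_B,
        BULGE_A,
        BULGE_B,
        INTERNAL_A,
        INTERNAL_B,
        MULTI_A,
        MULTI_B,
        MULTI_C,
        MAXLOOP,
    )
    return float(min(e, 0.0))


def _rnafold_energy(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found; install ViennaRNA")
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout
    last = out.strip().splitlines()[-1]
    return float(last[last.rindex("(") + 1 : last.rindex(")")])


# ---------------------------------------------------------------------------
# explicit-structure scoring (loop decomposition under the same parameters)
# ---------------------------------------------------------------------------


def pairable(a: str, b: str) -> bool:
    return _PAIR_IDX[_CODE.get(a, 4), _CODE.get(b, 4)] >= 0 if a in _CODE and b in _CODE else False


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit nested structure by loop decomposition.

    Validates pairability, nestedness and the 3-nt minimum hairpin loop.
    """
    code = _encode(seq)
    pairs = sorted((min(i, j), max(i, j)) for i, j in pairs)
    seen: set[int] = set()
    for i, j in pairs:
        if code[i] >= 4 or code[j] >= 4 or _PAIR_IDX[code[i], code[j]] < 0:
            raise ValueError(f"bases {i},{j} cannot pair")
        if j - i - 1 < 3:
            raise ValueError(f"hairpin loop of pair ({i},{j}) shorter than 3")
        if i in seen or j in seen:
            raise ValueError("base in more than one pair")
        seen.update((i, j))
    # nestedness + parent/child structure via a stack
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            if p[1] > stack[-1][1]:
                raise ValueError(f"pseudoknot between {stack[-1]} and {p}")
            children[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)
    energy = 0.0
    for (i, j), cs in children.items():
        pt = _PAIR_IDX[code[i], code[j]]
        if not cs:
            energy += HAIRPIN_A + HAIRPIN_B * (j - i - 1)
        elif len(cs) == 1:
            (k, l) = cs[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                energy += STACK[pt, _PAIR_IDX[code[k], code[l]]]
            elif left == 0 or right == 0:
                energy += BULGE_A + BULGE_B * (left + right)
            else:
                energy += INTERNAL_A + INTERNAL_B * (left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in cs)
            energy += MULTI_A + MULTI_B * len(cs) + MULTI_C * unpaired
    return float(energy)
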