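"""Pseudo-first-order unwinding kinetics: burst fits and plateau detection.

A Rho helicase time course on a duplex library follows, to first
approximation, f(t) = A (1 - e^{-k t}) where the burst amplitude A is the
fraction of duplexes carrying a functional Rut site and k the unwinding
rate.  Across selection rounds A grows and plateaus when the library is
maximally enriched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synth import UnwindingCurve


@dataclass(frozen=True)
class BurstFit:
    amplitude: float
    rate: float
    rss: float
    n_points: int
    rate_identifiable: bool = True

    def __post_init__(self):
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must be in [0,1]")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


_K_GRID = np.logspace(-3, 1, 13)  # per-second starting grid for k


def fit_burst(curve: UnwindingCurve | np.ndarray, fractions=None) -> BurstFit:
    """Unweighted least-squares fit of f(t) = A (1 - e^{-kt}), A in [0,1].

    Accepts an :class:`UnwindingCurve` or raw (times, fractions) arrays in
    any order of time points.  Initialization: A0 = max(fraction); k started
    from a log grid over 1e-3..10 /s and the best grid start refined.
    All-zero fractions return A = 0 with the rate flagged unidentifiable.
    """
    if fractions is None:
        t = np.asarray(curve.times, dtype=float)
        f = np.asarray(curve.fraction_unwound, dtype=float)
    else:
        t = np.asarray(curve, dtype=float)
        f = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 time points")
    if np.any(t <= 0) or np.unique(t).size != t.size:
        raise ValueError("times must be positive and distinct")
    order = np.argsort(t)  # the fit is invariant under reordering of points
    t, f = t[order], f[order]
    if np.all(f == 0):
        return BurstFit(amplitude=0.0, rate=1.0, rss=0.0, n_points=t.size, rate_identifiable=False)

    def resid(theta):
        A, logk = theta
        return A * (1.0 - np.exp(-np.exp(logk) * t)) - f

    a0 = float(np.clip(f.max(), 1e-6, 1.0))
    best = None
    for k0 in _K_GRID:
        sol = least_squares(
            resid,
            x0=[a0, np.log(k0)],
            bounds=([0.0, np.log(1e-6)], [1.0, np.log(1e4)]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, logk = best.x
    rss = float(2 * best.cost)
    return BurstFit(
        amplitude=float(A),
        rate=float(np.exp(logk)),
        rss=rss,
        n_points=t.size,
    )


def detect_plateau_round(
    amplitudes_by_round: list[tuple[int, float]],
    rel_tol: float = 0.05,
) -> tuple[int, bool]:
    """Smallest round r from which every subsequent amplitude step is below
    ``rel_tol`` of the maximum amplitude.

    Returns (round, plateaued).  When the series never settles the last
    round is returned with ``plateaued=False``.
    """
    if len(amplitudes_by_round) < 3:
        raise ValueError("need >= 3 rounds")
    rounds = [r for r, _ in amplitudes_by_round]
    if any(b <= a for a, b in zip(rounds, rounds[1:])):
        raise ValueError("rounds must be strictly increasing")
    amps = np.array([a for _, a in amplitudes_by_round], dtype=float)
    amax = amps.max()
    if amax <= 0:
        return rounds[-1], False
    steps = np.diff(amps) / amax  # step into round i+1
    small = steps < rel_tol
    # smallest index i >= 1 such that all steps from i-1 onwards are small
    for i in range(1, len(amps)):
        if small[i - 1 :].all():
            return rounds[i], True
    return rounds[-1], False
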