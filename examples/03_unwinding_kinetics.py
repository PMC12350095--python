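"""Fit pseudo-first-order unwinding curves and find the enrichment plateau.

Simulates one unwinding time course per selection round (burst amplitude
proportional to the library's active fraction), fits A(1 - e^{-kt}) to each,
and detects the round at which the amplitude plateaus -- the point of
maximal library enrichment.
"""

from rutscan.config import PipelineConfig
from rutscan.kinetics import detect_plateau_round, fit_burst
from rutscan.pipeline import run_simulation, unwinding_amplitude_series

cfg = PipelineConfig(genome_length=100_000, n_sites=20, n_fragments=30_000)
sim = run_simulation(cfg, seed=2)
true_amps, curves = unwinding_amplitude_series(cfg, sim, seed=2)

fitted = []
print("round  true A   fitted A  fitted k (/s)")
for (r, A), (_, curve) in zip(true_amps, curves):
    fit = fit_burst(curve)
    fitted.append((r, fit.amplitude))
    print(f"{r:5d}  {A:.3f}    {fit.amplitude:.3f}     {fit.rate:.3f}")

plateau, ok = detect_plateau_round(fitted, rel_tol=cfg.plateau_rel_tol)
print(f"plateau round: {plateau} (plateaued={ok})")
# The amplitude tracks the fraction of library molecules carrying an active
# Rut site; once it stops growing by >5% of its maximum per round, further
# selection rounds no longer enrich the library.
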