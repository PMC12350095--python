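import numpy as np
import pytest

from rutscan.config import PipelineConfig
from rutscan.core import GenomicInterval, RutPeak
from rutscan.pipeline import call_matched_peaks, run_simulation


def make_peak(start, end, strand="+", peak_id=None, fe=0.5, r0=10.0, caller="THRESHOLD"):
    """Convenience constructor for a valid peak on the 'toy' chromosome."""
    return RutPeak(
        interval=GenomicInterval("toy", start, end, strand),
        caller=caller,
        median_log10fe=fe,
        median_r0=r0,
        peak_id=peak_id or f"pk_{strand}_{start}",
    )


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced-scale study configuration used across integration tests."""
    return PipelineConfig(
        genome_length=200_000,
        n_sites=40,
        n_fragments=60_000,
        n_controls=150,
        n_perm=200,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """One reduced-scale simulated screen with its called peak sets."""
    sim = run_simulation(small_cfg, seed=11)
    called = call_matched_peaks(small_cfg, sim)
    return sim, called


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale simulated screen (1 Mb, 200 sites)."""
    cfg = PipelineConfig()
    sim = run_simulation(cfg, seed=1)
    called = call_matched_peaks(cfg, sim)
    return cfg, sim, called


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
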