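"""Centralized pipeline configuration.

Every tunable of the pipeline lives here with its default; a YAML file can
override any field and overrides are validated against type and range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- synthetic data -----------------------------------------------------
    genome_length: int = 1_000_000
    gene_density: float = 0.7          # fraction of genome covered by genes
    prophage_fraction: float = 0.1     # fraction of genome marked as prophage
    n_sites: int = 200                 # planted Rut sites
    site_min_len: int = 50
    site_max_len: int = 150
    site_antisense_prop: float = 0.8   # planted-site strand vs overlapping gene
    n_fragments: int = 300_000         # total fragments (both strands pooled)
    fragment_min_len: int = 30
    fragment_max_len: int = 300
    rounds: int = 6
    stringency_start: float = 1.0      # selection exponent, round 1
    stringency_end: float = 3.0        # selection exponent, final round
    enrichment_base: float = 2.0       # per-round advantage of active fragments
    replicate_noise_sd: float = 0.1    # lognormal sd on per-fragment counts
    end_fraction: float = 0.5          # fraction of sites given an RDTT 3'-end
    trim_mean: float = 400.0           # mean of exponential RDTT 3'-end trimming (nt)
    geom_p_down: float = 0.00167       # geometric downstream termination offset (mean ~600 nt)
    # --- enrichment ---------------------------------------------------------
    pseudocount: float = 1.0           # RPM units, both operands of log10FE
    # --- threshold caller ---------------------------------------------------
    cutoff: float = 0.0
    min_len: int = 30
    max_gap: int = 30
    min_median_r0: float = 1.0
    min_median_fe: float = 0.3
    # --- differential caller ------------------------------------------------
    block_len: int = 100
    min_log2fc: float = 0.5
    adjusted_alpha: float = 0.05
    mad_filter: float = 0.0            # 0 disables the MAD filter
    # --- genome context -----------------------------------------------------
    operon_gap: int = 500
    promoter_window: int = 100
    tandem_max_gap: int = 0
    distance_bins: tuple = (-100.0, 0.0, 100.0, 500.0)
    n_perm: int = 1000
    density_window: int = 10_000
    # --- sequence features --------------------------------------------------
    n_controls: int = 5000
    control_len: int = 130
    # match control window length to the median called-peak length so the
    # composition/structure comparison is not confounded by length
    control_len_matched: bool = True
    descriptor_alpha: float = 0.05
    descriptor_bh: bool = False        # optional Benjamini-Hochberg switch
    fold_backend: str = "internal"     # internal | rnafold
    # --- kinetics -----------------------------------------------------------
    kinetics_rounds: int = 10          # selection rounds for the unwinding series
    unwind_k: float = 0.2              # per second
    unwind_noise_sd: float = 0.02
    unwind_max_amplitude: float = 0.9  # amplitude of a fully active library
    plateau_rel_tol: float = 0.05
    # --- misc ---------------------------------------------------------------
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.genome_length >= 10_000, "genome_length >= 10000"),
            (0 <= self.gene_density <= 1, "gene_density in [0,1]"),
            (0 <= self.prophage_fraction < 1, "prophage_fraction in [0,1)"),
            (self.rounds >= 1, "rounds >= 1"),
            (self.enrichment_base >= 1, "enrichment_base >= 1"),
            (self.replicate_noise_sd >= 0, "replicate_noise_sd >= 0"),
            (self.pseudocount > 0, "pseudocount > 0"),
            (self.min_len >= 1, "min_len >= 1"),
            (self.max_gap >= 0, "max_gap >= 0"),
            (0 < self.adjusted_alpha < 1, "adjusted_alpha in (0,1)"),
            (self.block_len >= 1, "block_len >= 1"),
            (self.promoter_window >= 0, "promoter_window >= 0"),
            (self.n_perm >= 100, "n_perm >= 100"),
            (self.density_window >= 1000, "density_window >= 1000"),
            (self.site_min_len <= self.site_max_len, "site_min_len <= site_max_len"),
            (self.fragment_min_len <= self.fragment_max_len, "fragment lengths ordered"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            want = fields[key].type
            if want == "int" and not isinstance(value, int):
                raise ValueError(f"config key {key} must be int, got {value!r}")
            if key == "distance_bins":
                value = tuple(float(v) for v in value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distance_bins"] = list(d["distance_bins"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
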