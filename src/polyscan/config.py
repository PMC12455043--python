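"""Pipeline and simulator configuration.

Configuration files are flat YAML key/value mappings; unknown keys are
rejected so typos fail loudly rather than silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .model import GenomeLayout

__all__ = ["ScanConfig", "SimConfig", "load_config", "load_sim_config"]


@dataclass
class ScanConfig:
    """Tunable parameters of the scan pipeline (defaults match the study)."""

    window_size: int = 50_000          # bp
    window_step: int = 25_000          # bp
    q_threshold: float = 0.05          # FDR significance cut for all scans
    proximity: int = 8_000             # bp, gene-proximity rule
    n_permutations: int = 1_000        # gene-enrichment permutation count
    str_maf_min: float = 0.1           # minor-allele frequency floor for STRs
    min_region_support: int = 2        # overlapping windows per outlier region
    min_accessible_fraction: float = 0.1  # windows below this are nulled
    sv_max_missing: float = 0.2        # SV loci with more missingness dropped
    # haplotype statistics
    ehh_cutoff: float = 0.05
    ihs_maf_min: float = 0.05
    ihs_bins: int = 20
    max_gap: int = 200_000             # bp, discard cores whose curve spans a larger gap
    max_extend: int = 500_000          # bp, hard limit on EHH integration
    ancestral: str = "reference"       # or "major"
    # which population provides within-population statistics for the DCMS
    within_pop: str = "popB"
    tajima_pop: str = "popB"
    seed: int = 0

    def validate(self) -> "ScanConfig":
        if self.window_step <= 0:
            raise ValueError("window_step must be > 0")
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")
        for key in ("q_threshold", "str_maf_min", "min_accessible_fraction",
                    "sv_max_missing", "ehh_cutoff", "ihs_maf_min"):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                raise ValueError(f"{key} must lie in [0, 1], got {v}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.ancestral not in ("reference", "major"):
            raise ValueError("ancestral must be 'reference' or 'major'")
        return self


def _default_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (5_000_000, 5_000_000))


@dataclass
class SimConfig:
    """Parameters of the synthetic two-population dataset.

    Defaults are the documented study conditions: two weakly differentiated
    populations (background F = 0.02) at ancestral per-site diversity
    0.0036, population B scaled to 94% of population A's diversity, ten
    planted 100 kb sweep regions in population B, and SV/STR panels with a
    2% divergent fraction.
    """

    seed: int = 0
    layout: GenomeLayout = field(default_factory=_default_layout)
    n_diploids: int = 20               # per population (study minimum is 6)
    n_hybrids: int = 0                 # optional excluded hybrid population
    background_f: float = 0.02        # Balding-Nichols F between populations
    theta_anc: float = 0.0036         # expected per-bp heterozygosity (dXY scale)
    diversity_scale_a: float = 1.0
    diversity_scale_b: float = 0.94
    n_founders: int = 30              # founder haplotypes per population
    switch_rate: float = 1e-6         # per-bp founder-mosaic switch probability
    # planted sweeps (population B)
    n_sweeps: int = 10
    sweep_length: int = 100_000
    f_sweep: float = 0.8              # frequency of the sweep founder haplotype
    # marker panels
    n_svs: int = 2_000
    sv_divergent_fraction: float = 0.02
    sv_delta_p: float = 0.6           # minimum |p_A - p_B| at divergent SVs
    n_strs: int = 5_000
    str_divergent_fraction: float = 0.02
    str_shift: float = 2.0            # minimum repeat-mean shift at divergent STRs
    str_sd: float = 1.5               # within-population repeat-count s.d.
    str_neutral_jitter: float = 0.3   # s.d. of neutral between-population mean shift
    str_missing_fraction: float = 0.02  # loci given one missing call
    # annotation
    mean_intergenic_gap: int = 16_000
    gene_length_min: int = 2_000
    gene_length_max: int = 15_000
    # ancestral allele-frequency law: Uniform(freq_min, 1 - freq_min)
    freq_min: float = 0.05

    def validate(self) -> "SimConfig":
        for key in ("background_f", "f_sweep", "sv_divergent_fraction",
                    "str_divergent_fraction", "str_missing_fraction", "freq_min"):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                raise ValueError(f"{key} must lie in [0, 1], got {v}")
        if not 0 < self.background_f < 1:
            raise ValueError("background_f must lie strictly in (0, 1)")
        for key in ("n_diploids", "n_founders", "n_sweeps", "sweep_length",
                    "n_svs", "n_strs", "mean_intergenic_gap"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.n_diploids < 6:
            raise ValueError("n_diploids must be >= 6 (study minimum)")
        if self.n_sweeps * self.sweep_length > min(self.layout.lengths):
            raise ValueError("sweep regions do not fit on the shortest chromosome")
        return self


def _from_mapping(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "layout" in data:
        lay = data["layout"]
        data = dict(data)
        data["layout"] = GenomeLayout(tuple(lay["names"]), tuple(int(x) for x in lay["lengths"]))
    try:
        return cls(**data).validate()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def load_config(path) -> ScanConfig:
    """Read a scan configuration file; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return _from_mapping(ScanConfig, data, str(path))


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return _from_mapping(SimConfig, data, str(path))
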