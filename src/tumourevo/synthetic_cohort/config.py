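"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

from ..cohort_io.context import context_classes
from ..cohort_io.model import InvalidInputError

#: Small three-chromosome toy genome: (name, length bp, arm boundary bp).
DEFAULT_GENOME = [
    ("chr1", 60_000_000, 25_000_000),
    ("chr2", 50_000_000, 20_000_000),
    ("chr3", 40_000_000, 18_000_000),
]

DEFAULT_HLA_LOCUS = ("chr1", 1_000_001, 1_500_000)  # 1-based inclusive
DEFAULT_HLA_GENE_POSITIONS = {
    "HLA-A": ("chr1", 1_050_000),
    "HLA-B": ("chr1", 1_200_000),
    "HLA-C": ("chr1", 1_350_000),
}
DEFAULT_APG_GENE_POSITIONS = {
    "B2M": ("chr2", 5_000_000),
    "TAP1": ("chr2", 10_000_000),
    "TAP2": ("chr2", 10_200_000),
    "TAPBP": ("chr3", 8_000_000),
}

DEFAULT_SV_CLASS_MIXTURE = {
    "deletion": 0.35,
    "tandem-duplication": 0.30,
    "inversion": 0.15,
    "unclassified": 0.20,
}


def default_context_rates(total_per_site: float = 1e-6) -> dict:
    """A kidney-like 96-class background: clock-like C>T at CpG and T>C excess."""
    weights = {}
    for cls in context_classes():
        tri, sub = cls.split(":")
        if sub == "C>T" and tri[2] == "G":
            w = 8.0
        elif sub == "C>T":
            w = 2.0
        elif sub == "T>C":
            w = 1.5
        else:
            w = 1.0
        weights[cls] = w
    total_w = sum(weights.values())
    return {cls: total_per_site * w / total_w for cls, w in weights.items()}


@dataclass(frozen=True)
class GainSpec:
    """A clonal gain applied to every non-WGD sample (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    time: float  # molecular time in [0,1]

    @property
    def state(self) -> str:
        return f"{self.major_cn}+{self.minor_cn}"

    @property
    def target(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class HotspotSpec:
    """SV hotspot interval (0-based half-open) with fold enrichment >= 1."""

    chrom: str
    start: int
    end: int
    fold: float


@dataclass(frozen=True)
class ElementSpec:
    """Driver element interval (0-based half-open) with mutation fold >= 1."""

    element_id: str
    chrom: str
    start: int
    end: int
    fold: float


@dataclass(frozen=True)
class EscapeSpec:
    hla_loh: bool = False
    hla_mutation: bool = False
    apg_mutation: bool = False

    @property
    def any(self) -> bool:
        return self.hla_loh or self.hla_mutation or self.apg_mutation


@dataclass
class SimulationConfig:
    """Everything needed to generate a cohort with known ground truth."""

    n_samples: int = 10
    genome: list = field(default_factory=lambda: list(DEFAULT_GENOME))
    depth_mean: float = 60.0
    purity_range: tuple = (0.5, 0.9)
    context_rates: dict = field(default_factory=default_context_rates)
    gain_events: list = field(default_factory=list)
    wgd_fraction: float = 0.0
    wgd_time: float = 0.7
    subclonal_fraction: float = 0.3  # subclonal burden relative to clonal
    subclonal_ccf: float = 0.4
    sv_background_rate: float = 1.0  # breakpoints per Mb
    sv_class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_SV_CLASS_MIXTURE))
    hotspot_specs: list = field(default_factory=list)
    driver_element_specs: list = field(default_factory=list)
    escape_specs: dict = field(default_factory=dict)  # sample index -> EscapeSpec
    hla_locus: tuple = DEFAULT_HLA_LOCUS
    hla_gene_positions: dict = field(default_factory=lambda: dict(DEFAULT_HLA_GENE_POSITIONS))
    apg_gene_positions: dict = field(default_factory=lambda: dict(DEFAULT_APG_GENE_POSITIONS))
    clock_rate_per_year: float = 0.05  # mutations per Mb per year
    acceleration_factor: float = 5.0
    initiation_lead_years: float = 10.0
    age_mean: float = 60.0
    age_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidInputError("n_samples must be >= 1")
        if not self.genome:
            raise InvalidInputError("genome must be non-empty")
        for chrom, length, boundary in self.genome:
            if not (0 < boundary < length):
                raise InvalidInputError(
                    f"{chrom}: arm boundary must lie strictly inside the chromosome"
                )
        if self.depth_mean <= 0:
            raise InvalidInputError("depth_mean must be positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidInputError("purity_range must satisfy 0 < lo <= hi <= 1")
        if sum(self.context_rates.values()) <= 0:
            raise InvalidInputError("context rates must have positive total")
        for gain in self.gain_events:
            if not (0.0 <= gain.time <= 1.0):
                raise InvalidInputError(f"gain time {gain.time} outside [0,1]")
            if gain.state not in ("2+1", "2+0", "2+2"):
                raise InvalidInputError(f"unsupported gain state {gain.state}")
        if not (0.0 <= self.wgd_fraction <= 1.0):
            raise InvalidInputError("wgd_fraction must be in [0,1]")
        if not (0.0 <= self.wgd_time <= 1.0):
            raise InvalidInputError("wgd_time must be in [0,1]")
        for spec in self.hotspot_specs:
            if spec.fold < 1.0:
                raise InvalidInputError("hotspot fold enrichments must be >= 1")
        for spec in self.driver_element_specs:
            if spec.fold < 1.0:
                raise InvalidInputError("element fold enrichments must be >= 1")
        if self.acceleration_factor < 1.0:
            raise InvalidInputError("acceleration_factor must be >= 1")
        if self.sv_background_rate < 0:
            raise InvalidInputError("sv_background_rate must be >= 0")

    @property
    def total_rate_per_site(self) -> float:
        """Per-copy, per-bp clonal mutation intensity (summed over classes)."""
        return float(sum(self.context_rates.values()))

    def chrom_length(self, chrom: str) -> int:
        for name, length, _ in self.genome:
            if name == chrom:
                return length
        raise InvalidInputError(f"unknown chromosome {chrom}")


@dataclass
class SampleGroundTruth:
    sample_id: str
    purity: float
    age: float
    wgd: bool
    gain_times: dict = field(default_factory=dict)  # target -> {state, t, lead_years}
    variant_truth: list = field(default_factory=list)
    escape: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortGroundTruth:
    samples: list = field(default_factory=list)
    hotspots: list = field(default_factory=list)  # [chrom, start, end, fold]
    driver_elements: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "samples": [s.to_dict() for s in self.samples],
            "hotspots": [list(h) for h in self.hotspots],
            "driver_elements": [list(e) for e in self.driver_elements],
        }
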