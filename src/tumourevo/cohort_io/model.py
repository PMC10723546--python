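"""Core record types for somatic variants, copy-number segments, SVs and samples.

Coordinate conventions: VCF positions and copy-number segment bounds are
1-based inclusive; BED/BEDPE-style intervals used elsewhere in the package
are 0-based half-open. Conversions happen at the file boundary, never inside
analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CONSEQUENCES = {"missense", "truncating", "synonymous", "non-coding", "other"}
SV_CLASSES = {"deletion", "tandem-duplication", "inversion", "translocation", "unclassified"}


class FormatError(ValueError):
    """A file or record violates the expected on-disk format."""


class InvalidInputError(ValueError):
    """An argument violates an operation precondition."""


@dataclass
class VariantRecord:
    """One somatic SNV or indel with read support and optional annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    gene: Optional[str] = None
    consequence: Optional[str] = None
    trinucleotide_context: Optional[str] = None
    multiplicity: Optional[int] = None
    clonal: Optional[bool] = None
    ccf_estimate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidInputError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise InvalidInputError("empty ref/alt allele")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise InvalidInputError("negative read depth")
        if self.ref_depth + self.alt_depth <= 0:
            raise InvalidInputError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: total depth must be > 0"
            )
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise InvalidInputError(f"unknown consequence {self.consequence!r}")
        if self.multiplicity is not None and self.multiplicity < 1:
            raise InvalidInputError("multiplicity must be >= 1")

    @property
    def vaf(self) -> float:
        return self.alt_depth / (self.alt_depth + self.ref_depth)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def is_indel(self) -> bool:
        return not self.is_snv


@dataclass
class CopyNumberSegment:
    """Allele-specific copy-number interval (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInputError(f"segment end {self.end} < start {self.start}")
        if self.minor_cn < 0 or self.major_cn < 0:
            raise InvalidInputError("negative copy number")
        if self.major_cn < self.minor_cn:
            raise InvalidInputError("major_cn must be >= minor_cn")
        if not (0.0 < self.clonal_fraction <= 1.0):
            raise InvalidInputError("clonal_fraction must be in (0, 1]")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SVRecord:
    """Paired-breakpoint rearrangement; intrachromosomal pairs stored pos1 <= pos2."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_class: str = "unclassified"
    callers: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise InvalidInputError(f"unknown SV class {self.sv_class!r}")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise InvalidInputError("strands must be '+' or '-'")
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            # canonical ordering for intrachromosomal events
            p1, p2 = self.pos1, self.pos2
            s1, s2 = self.strand1, self.strand2
            object.__setattr__(self, "pos1", p2)
            object.__setattr__(self, "pos2", p1)
            object.__setattr__(self, "strand1", s2)
            object.__setattr__(self, "strand2", s1)
        if not isinstance(self.callers, frozenset):
            object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def breakends(self):
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


@dataclass
class TumourSample:
    """One patient's purity/ploidy/clinical covariates plus somatic calls."""

    sample_id: str
    purity: float
    ploidy: float
    age_at_sampling: float
    grade: Optional[int] = None
    stage: Optional[int] = None
    variants: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    svs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise InvalidInputError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise InvalidInputError("ploidy must be positive")
        _check_segments_disjoint(self.segments)

    def segment_at(self, chrom: str, pos: int) -> Optional[CopyNumberSegment]:
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None


def _check_segments_disjoint(segments) -> None:
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise InvalidInputError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
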