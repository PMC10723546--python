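"""Genomic elements and trinucleotide-context background rates."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..cohort_io.model import InvalidInputError


class InconsistencyError(ValueError):
    """Observed mutations in a context class with zero callable abundance."""


@dataclass
class GenomicElement:
    """A (possibly multi-interval) non-coding element with context abundances.

    ``intervals`` are 0-based half-open (chrom, start, end) tuples;
    ``context_abundance`` maps 96-class labels to callable site counts.
    """

    element_id: str
    intervals: list
    element_type: str = "other"
    context_abundance: dict = field(default_factory=dict)

    @property
    def total_sites(self) -> int:
        return sum(self.context_abundance.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return any(c == chrom and s < pos <= e for c, s, e in self.intervals)


def estimate_context_rates(cohort, callable_context_abundance: dict) -> dict:
    """Per-site, per-sample background mutation rate for each context class.

    r_c = (total cohort SNVs in class c) / (n_samples * callable sites for c).
    """
    n_samples = len(cohort)
    if n_samples == 0:
        raise InvalidInputError("empty cohort")
    counts: dict = {}
    for sample in cohort:
        for v in sample.variants:
            if v.is_snv and v.trinucleotide_context is not None:
                counts[v.trinucleotide_context] = counts.get(v.trinucleotide_context, 0) + 1
    rates = {}
    for cls, count in counts.items():
        abundance = callable_context_abundance.get(cls, 0)
        if abundance <= 0:
            raise InconsistencyError(
                f"context class {cls} has {count} mutations but zero callable abundance"
            )
        rates[cls] = count / (n_samples * abundance)
    for cls, abundance in callable_context_abundance.items():
        rates.setdefault(cls, 0.0)
    return rates


def expected_element_count(element: GenomicElement, rates: dict, n_samples: int = 1) -> float:
    """Expected mutation count in an element: mu_e = n_samples * sum_c n_ec * r_c."""
    mu = 0.0
    for cls, n_sites in element.context_abundance.items():
        mu += n_sites * rates.get(cls, 0.0)
    return n_samples * mu


def observed_element_count(element: GenomicElement, cohort) -> int:
    """Pooled cohort SNV count falling inside the element's intervals."""
    count = 0
    for sample in cohort:
        for v in sample.variants:
            if v.is_snv and element.contains(v.chrom, v.pos):
                count += 1
    return count
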