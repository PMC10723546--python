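"""Pyrimidine-collapsed 96-class trinucleotide substitution labels."""

from __future__ import annotations

from itertools import product

from .model import InvalidInputError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")

#: The six pyrimidine-centred substitution types.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class ReferenceMismatchError(ValueError):
    """Reference base at the variant position disagrees with the REF allele."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def context_classes() -> list:
    """All 96 labels in deterministic order, e.g. ``'ACA:C>A'``."""
    labels = []
    for sub in SUBSTITUTION_TYPES:
        ref = sub[0]
        for five, three in product("ACGT", "ACGT"):
            labels.append(f"{five}{ref}{three}:{sub}")
    return labels


def collapse_context(trinucleotide: str, ref: str, alt: str) -> str:
    """Collapse a stranded trinucleotide substitution onto the pyrimidine strand."""
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in COMPLEMENT for b in tri):
        raise InvalidInputError(f"bad trinucleotide {trinucleotide!r}")
    if tri[1] != ref.upper():
        raise InvalidInputError("trinucleotide centre does not match ref allele")
    if ref.upper() not in PYRIMIDINES:
        tri = revcomp(tri)
        ref = COMPLEMENT[ref.upper()]
        alt = COMPLEMENT[alt.upper()]
    return f"{tri}:{ref.upper()}>{alt.upper()}"


def trinucleotide_context(variant, reference_fetcher) -> str:
    """Label a somatic SNV with its 96-class trinucleotide context.

    ``reference_fetcher(chrom, start0, end0)`` must return the reference
    sequence over a 0-based half-open interval (a ``pyfaidx.Fasta`` wrapped in
    a small lambda works).
    """
    if not variant.is_snv:
        raise InvalidInputError("trinucleotide context is defined for SNVs only")
    tri = str(reference_fetcher(variant.chrom, variant.pos - 2, variant.pos + 1)).upper()
    if len(tri) != 3:
        raise InvalidInputError(f"reference fetch at {variant.chrom}:{variant.pos} returned {tri!r}")
    if tri[1] != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: reference base {tri[1]} != REF {variant.ref}"
        )
    return collapse_context(tri, variant.ref, variant.alt)
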