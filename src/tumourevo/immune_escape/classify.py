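"""Genetic immune-evasion classification.

Three independent routes flag a tumour as escaped: loss of heterozygosity
across the class I HLA locus (called from allele-specific segments as a
surrogate for allele-resolved methods), a nonsynonymous HLA gene mutation,
or an inactivating mutation in an antigen-presenting gene (APG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from ..cohort_io.model import InvalidInputError

HLA_CLASS_I_GENES = ("HLA-A", "HLA-B", "HLA-C")
TRUNCATING = "truncating"
MIN_LOCUS_COVERAGE = 0.5


class UnclassifiableError(ValueError):
    """No escape component could be evaluated for the sample."""


def default_apg_genes() -> list:
    """The bundled 22-gene antigen-presentation list."""
    text = (
        resources.files("tumourevo.immune_escape")
        .joinpath("data/apg_default.txt")
        .read_text()
    )
    return read_gene_list_text(text)


def read_gene_list_text(text: str) -> list:
    genes = [ln.strip() for ln in text.splitlines()]
    return [g for g in genes if g and not g.startswith("#")]


def read_gene_list(path) -> list:
    with open(path) as fh:
        return read_gene_list_text(fh.read())


@dataclass
class EscapeConfig:
    """Inputs for escape classification; the APG list is mandatory config."""

    hla_locus: tuple  # (chrom, start, end), 1-based inclusive
    apg_genes: list = field(default_factory=default_apg_genes)
    hla_genes: tuple = HLA_CLASS_I_GENES
    biallelic_missense: bool = False  # pathogenic missense also requires gene LOH
    pathogenic_is_inactivating: bool = True

    def __post_init__(self) -> None:
        if not self.apg_genes:
            raise InvalidInputError("APG gene list must be non-empty")


@dataclass
class ImmuneEscapeCall:
    sample_id: str
    hla_loh: Optional[bool]
    hla_mutation: Optional[bool]
    apg_inactivation: Optional[bool]
    escaped: bool
    evidence: list = field(default_factory=list)
    missing_components: list = field(default_factory=list)


def hla_loh_call(sample, hla_locus) -> Optional[bool]:
    """Segment-based HLA LOH call; None when the locus is under-covered.

    LOH iff the length-weighted majority of the covered locus has minor_cn = 0
    at clonal fraction >= 0.5.
    """
    chrom, start, end = hla_locus
    locus_len = end - start + 1
    covered = 0
    loh_len = 0
    for seg in sample.segments:
        if seg.chrom != chrom:
            continue
        ov = max(0, min(seg.end, end) - max(seg.start, start) + 1)
        if ov == 0:
            continue
        covered += ov
        if seg.minor_cn == 0 and seg.clonal_fraction >= 0.5:
            loh_len += ov
    if covered / locus_len < MIN_LOCUS_COVERAGE:
        return None
    return loh_len > covered / 2


def hla_mutation_call(sample, hla_genes=HLA_CLASS_I_GENES) -> bool:
    """True iff any HLA class I gene carries a nonsynonymous mutation."""
    for v in sample.variants:
        if v.gene in hla_genes and v.consequence in ("missense", TRUNCATING):
            return True
    return False


def _gene_has_loh(sample, gene_variants) -> bool:
    for v in gene_variants:
        seg = sample.segment_at(v.chrom, v.pos)
        if seg is not None and seg.minor_cn == 0:
            return True
    return False


def apg_inactivation(
    sample,
    apg_genes,
    pathogenic_missense=None,
    biallelic_missense: bool = False,
) -> tuple:
    """(flag, evidence) for inactivating mutations in antigen-presenting genes.

    Truncating mutations always inactivate. A missense counts when flagged in
    ``pathogenic_missense`` (a set of (gene, pos) or a predicate over the
    variant); with ``biallelic_missense`` it additionally requires LOH over
    the gene's segment.
    """
    if not apg_genes:
        raise InvalidInputError("APG gene list must be non-empty")
    apg_set = set(apg_genes)
    evidence = []
    by_gene: dict = {}
    for v in sample.variants:
        if v.gene in apg_set:
            by_gene.setdefault(v.gene, []).append(v)
    for gene, variants in sorted(by_gene.items()):
        for v in variants:
            if v.consequence == TRUNCATING:
                evidence.append((gene, "truncating"))
                break
            if v.consequence == "missense" and _is_pathogenic(v, pathogenic_missense):
                if biallelic_missense and not _gene_has_loh(sample, variants):
                    continue
                evidence.append((gene, "pathogenic-missense"))
                break
    return bool(evidence), evidence


def _is_pathogenic(variant, pathogenic_missense) -> bool:
    if pathogenic_missense is None:
        return False
    if callable(pathogenic_missense):
        return bool(pathogenic_missense(variant))
    return (variant.gene, variant.pos) in pathogenic_missense


def classify_escape(sample, config: EscapeConfig, pathogenic_missense=None) -> ImmuneEscapeCall:
    """Combine the three escape routes; escaped = OR over available components.

    Components that cannot be evaluated are recorded as missing, never
    silently treated as negative; a sample with no evaluable component raises.
    """
    loh = hla_loh_call(sample, config.hla_locus)
    hla_mut = hla_mutation_call(sample, config.hla_genes)
    apg_flag, apg_evidence = apg_inactivation(
        sample,
        config.apg_genes,
        pathogenic_missense=pathogenic_missense if config.pathogenic_is_inactivating else None,
        biallelic_missense=config.biallelic_missense,
    )

    components = {"hla_loh": loh, "hla_mutation": hla_mut, "apg_inactivation": apg_flag}
    missing = [k for k, v in components.items() if v is None]
    if len(missing) == len(components):
        raise UnclassifiableError(f"sample {sample.sample_id}: no escape component evaluable")

    evidence = []
    if loh:
        evidence.append(("HLA", "loh"))
    if hla_mut:
        evidence.append(("HLA", "mutation"))
    evidence.extend(apg_evidence)

    escaped = any(v for v in components.values() if v is not None)
    return ImmuneEscapeCall(
        sample_id=sample.sample_id,
        hla_loh=loh,
        hla_mutation=hla_mut,
        apg_inactivation=apg_flag,
        escaped=escaped,
        evidence=evidence,
        missing_components=missing,
    )


def escape_summary(calls) -> dict:
    """Cohort-level escape fractions from a list of ImmuneEscapeCall."""
    n = len(calls)
    if n == 0:
        raise InvalidInputError("empty call list")
    return {
        "n_samples": n,
        "n_escaped": sum(c.escaped for c in calls),
        "escaped_pct": 100.0 * sum(c.escaped for c in calls) / n,
        "hla_loh_pct": 100.0 * sum(bool(c.hla_loh) for c in calls) / n,
        "hla_mutation_pct": 100.0 * sum(bool(c.hla_mutation) for c in calls) / n,
        "apg_inactivation_pct": 100.0 * sum(bool(c.apg_inactivation) for c in calls) / n,
    }
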