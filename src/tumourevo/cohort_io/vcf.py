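"""VCF 4.2 reading/writing for somatic SNV/indel records.

Depths travel in the tumour sample's ``AD`` FORMAT field; optional annotation
(gene, consequence, trinucleotide context, multiplicity/clonality/CCF) is
round-tripped through INFO keys. CCF is serialised as a string to avoid the
float32 truncation VCF Float fields impose.
"""

from __future__ import annotations

import pysam

from .model import FormatError, VariantRecord

_SAMPLE_NAME = "TUMOUR"

_INFO_DEFS = [
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">'),
    ('##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context label">'),
    ('##INFO=<ID=MULT,Number=1,Type=Integer,Description="Mutation multiplicity">'),
    ('##INFO=<ID=CLONAL,Number=1,Type=Integer,Description="Clonal flag (1/0)">'),
    ('##INFO=<ID=CCF,Number=1,Type=String,Description="Cancer cell fraction estimate">'),
]


def write_snv_vcf(records, path, chrom_order=None) -> None:
    """Write variant records to an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    chroms = chrom_order or _stable_chroms(records)
    for chrom in chroms:
        header.contigs.add(chrom)
    for line in _INFO_DEFS:
        header.add_line(line)
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_sample(_SAMPLE_NAME)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            row.samples[_SAMPLE_NAME]["AD"] = (rec.ref_depth, rec.alt_depth)
            if rec.gene is not None:
                row.info["GENE"] = rec.gene
            if rec.consequence is not None:
                row.info["CSQCLASS"] = rec.consequence
            if rec.trinucleotide_context is not None:
                row.info["CTX"] = rec.trinucleotide_context
            if rec.multiplicity is not None:
                row.info["MULT"] = rec.multiplicity
            if rec.clonal is not None:
                row.info["CLONAL"] = int(rec.clonal)
            if rec.ccf_estimate is not None:
                row.info["CCF"] = repr(float(rec.ccf_estimate))
            vcf.write(row)


def read_snv_vcf(path) -> list:
    """Read somatic SNV/indel records from a VCF with AD depth fields."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            if len(row.alts or ()) != 1:
                raise FormatError(
                    f"{row.chrom}:{row.pos}: expected exactly one ALT allele"
                )
            ad = None
            if row.samples:
                sample = row.samples[next(iter(row.samples))]
                ad = sample.get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                raise FormatError(
                    f"{row.chrom}:{row.pos} {row.ref}>{row.alts[0]}: missing AD depth field"
                )
            info = row.info
            clonal = info.get("CLONAL")
            ccf = info.get("CCF")
            records.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=row.ref,
                    alt=row.alts[0],
                    ref_depth=int(ad[0]),
                    alt_depth=int(ad[1]),
                    gene=info.get("GENE"),
                    consequence=info.get("CSQCLASS"),
                    trinucleotide_context=info.get("CTX"),
                    multiplicity=None if info.get("MULT") is None else int(info["MULT"]),
                    clonal=None if clonal is None else bool(int(clonal)),
                    ccf_estimate=None if ccf is None else float(ccf),
                )
            )
    return records


def _stable_chroms(records):
    seen = []
    for rec in records:
        if rec.chrom not in seen:
            seen.append(rec.chrom)
    return seen
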