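"""Shared fixtures and small builders used across the suite."""

from __future__ import annotations

import pytest

from tumourevo.cohort_io import CopyNumberSegment, SVRecord, TumourSample, VariantRecord


def make_variant(chrom="chr1", pos=100, ref="C", alt="T", ref_depth=30, alt_depth=30, **kw):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        ref_depth=ref_depth, alt_depth=alt_depth, **kw,
    )


def make_indel(chrom="chr1", pos=100, **kw):
    kw.setdefault("ref", "CA")
    kw.setdefault("alt", "C")
    kw.setdefault("ref_depth", 30)
    kw.setdefault("alt_depth", 10)
    return VariantRecord(chrom=chrom, pos=pos, **kw)


def make_sv(chrom1="chr1", pos1=1000, chrom2="chr1", pos2=5000,
            strand1="+", strand2="-", sv_class="deletion", callers=()):
    return SVRecord(
        chrom1=chrom1, pos1=pos1, strand1=strand1,
        chrom2=chrom2, pos2=pos2, strand2=strand2,
        sv_class=sv_class, callers=frozenset(callers),
    )


def make_sample(segments=None, variants=None, svs=None, purity=1.0, ploidy=2.0, **kw):
    kw.setdefault("sample_id", "T01")
    kw.setdefault("age_at_sampling", 60.0)
    return TumourSample(
        purity=purity, ploidy=ploidy,
        variants=variants or [], segments=segments or [], svs=svs or [], **kw,
    )


def diploid_genome(n_chroms=22, length=10_000_000):
    return [(f"chr{i + 1}", length, length // 2) for i in range(n_chroms)]


def diploid_segments(genome):
    return [CopyNumberSegment(c, 1, ln, 1, 1) for c, ln, _ in genome]


@pytest.fixture
def toy_genome():
    return [("chr1", 5_000_000, 2_000_000), ("chr2", 4_000_000, 1_500_000)]
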