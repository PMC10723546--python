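"""Tab-delimited segment, clinical and BEDPE tables."""

from __future__ import annotations

import pandas as pd

from .model import CopyNumberSegment, FormatError, SVRecord

SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn", "clonal_fraction"]
CLINICAL_COLUMNS = ["sample_id", "purity", "ploidy", "age_at_sampling", "grade", "stage"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "caller", "sv_class",
]


def write_segments(segments, path) -> None:
    df = pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.major_cn, s.minor_cn, s.clonal_fraction)
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"segment table missing columns: {sorted(missing)}")
    return [
        CopyNumberSegment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            major_cn=int(r.major_cn),
            minor_cn=int(r.minor_cn),
            clonal_fraction=float(r.clonal_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical(samples, path) -> None:
    df = pd.DataFrame(
        [
            (s.sample_id, s.purity, s.ploidy, s.age_at_sampling, s.grade, s.stage)
            for s in samples
        ],
        columns=CLINICAL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    return df


def write_bedpe(svs, path) -> None:
    """BEDPE with breakends as 0-based half-open single-base intervals."""
    rows = []
    for i, sv in enumerate(svs):
        rows.append(
            (
                sv.chrom1, sv.pos1 - 1, sv.pos1,
                sv.chrom2, sv.pos2 - 1, sv.pos2,
                f"sv{i}", ".", sv.strand1, sv.strand2,
                ",".join(sorted(sv.callers)) or ".",
                sv.sv_class,
            )
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(BEDPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"BEDPE missing columns: {sorted(missing)}")
    svs = []
    for r in df.itertuples(index=False):
        callers = frozenset() if r.caller == "." else frozenset(str(r.caller).split(","))
        svs.append(
            SVRecord(
                chrom1=str(r.chrom1), pos1=int(r.end1), strand1=str(r.strand1),
                chrom2=str(r.chrom2), pos2=int(r.end2), strand2=str(r.strand2),
                sv_class=str(r.sv_class), callers=callers,
            )
        )
    return svs
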