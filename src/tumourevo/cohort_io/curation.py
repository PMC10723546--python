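"""Somatic-call curation: germline-proximity indel filtering, multi-caller SV
consensus and tumour mutational burden."""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .model import InvalidInputError, SVRecord

#: Inclusive distance (bp) to a common germline indel at which a somatic
#: indel is discarded.
DEFAULT_INDEL_WINDOW_BP = 10

DEFAULT_SLOP_BP = 300
DEFAULT_MIN_CALLERS = 2


def filter_indels_near_germline(
    somatic_indels,
    germline_panel,
    window_bp: int = DEFAULT_INDEL_WINDOW_BP,
    inclusive: bool = True,
):
    """Split somatic indels into (kept, removed) by proximity to a germline panel.

    An indel is removed iff a panel indel on the same chromosome lies within
    ``window_bp`` of it (boundary inclusive by default).
    """
    for rec in somatic_indels:
        if rec.is_snv:
            raise InvalidInputError(f"SNV in somatic indel input at {rec.chrom}:{rec.pos}")
    for rec in germline_panel:
        if rec.is_snv:
            raise InvalidInputError(f"SNV in germline panel at {rec.chrom}:{rec.pos}")

    panel_pos = defaultdict(list)
    for rec in germline_panel:
        panel_pos[rec.chrom].append(rec.pos)
    panel_sorted = {c: np.sort(np.asarray(p)) for c, p in panel_pos.items()}

    kept, removed = [], []
    for rec in somatic_indels:
        positions = panel_sorted.get(rec.chrom)
        if positions is None or positions.size == 0:
            kept.append(rec)
            continue
        idx = np.searchsorted(positions, rec.pos)
        dist = min(
            abs(rec.pos - positions[i]) for i in (idx - 1, idx) if 0 <= i < positions.size
        )
        hit = dist <= window_bp if inclusive else dist < window_bp
        (removed if hit else kept).append(rec)
    return kept, removed


def _classes_compatible(a: str, b: str) -> bool:
    return a == b or "unclassified" in (a, b)


def _sv_match(a: SVRecord, b: SVRecord, slop_bp: int) -> bool:
    return (
        a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and a.strand1 == b.strand1
        and a.strand2 == b.strand2
        and abs(a.pos1 - b.pos1) <= slop_bp
        and abs(a.pos2 - b.pos2) <= slop_bp
        and _classes_compatible(a.sv_class, b.sv_class)
    )


def consensus_sv(
    callsets: dict,
    slop_bp: int = DEFAULT_SLOP_BP,
    min_callers: int = DEFAULT_MIN_CALLERS,
):
    """Merge per-caller SV callsets into consensus records.

    Calls from different callers whose breakpoints both lie within ``slop_bp``
    (matching strands, compatible classes) are clustered by single linkage;
    a consensus record is emitted iff the cluster spans >= ``min_callers``
    distinct callers. Consensus positions are the per-breakend medians.
    """
    if len(callsets) < 2:
        raise InvalidInputError("consensus requires at least two callsets")

    tagged = []
    for caller in sorted(callsets):
        for sv in callsets[caller]:
            tagged.append((caller, sv))

    n = len(tagged)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            if _sv_match(tagged[i][1], tagged[j][1], slop_bp):
                union(i, j)

    clusters = defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(tagged[i])

    out = []
    for root in sorted(clusters):
        members = clusters[root]
        callers = frozenset(c for c, _ in members)
        if len(callers) < min_callers:
            continue
        svs = [sv for _, sv in members]
        pos1 = int(np.median([s.pos1 for s in svs]))
        pos2 = int(np.median([s.pos2 for s in svs]))
        classes = [s.sv_class for s in svs if s.sv_class != "unclassified"]
        sv_class = max(set(classes), key=classes.count) if classes else "unclassified"
        ref = svs[0]
        out.append(
            SVRecord(
                chrom1=ref.chrom1, pos1=pos1, strand1=ref.strand1,
                chrom2=ref.chrom2, pos2=pos2, strand2=ref.strand2,
                sv_class=sv_class, callers=callers,
            )
        )
    out.sort(key=lambda s: (s.chrom1, s.pos1, s.chrom2, s.pos2, s.sv_class))
    return out


def compute_tmb(sample, callable_mb: float) -> dict:
    """Somatic mutation rates per callable megabase, SNVs and indels separately."""
    if callable_mb <= 0:
        raise InvalidInputError("callable_mb must be > 0")
    n_snv = sum(1 for v in sample.variants if v.is_snv)
    n_indel = sum(1 for v in sample.variants if v.is_indel)
    return {
        "snv_per_mb": n_snv / callable_mb,
        "indel_per_mb": n_indel / callable_mb,
        "total_per_mb": (n_snv + n_indel) / callable_mb,
    }
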