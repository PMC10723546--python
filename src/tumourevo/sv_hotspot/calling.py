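"""Hotspot calling on PCF segments and fragile-site annotation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..cohort_io.model import InvalidInputError
from .background import fit_background
from .pcf import pcf_segment, select_gamma
from .tracks import BinnedTrack, bin_breakpoints

DEFAULT_FDR = 0.05
DEFAULT_MIN_RATE_RATIO = 2.0
LARGE_GENE_BP = 600_000
LATE_REPLICATION_DECILE = 0.1


@dataclass
class HotspotSegment:
    chrom: str
    start: int  # 0-based half-open genomic coords
    end: int
    n_bins: int
    observed_breakpoints: int
    expected_breakpoints: float
    rate_ratio: float
    p_value: float
    q_value: float
    fragile_flag: bool = False
    flag_reason: Optional[str] = None


def call_hotspots(
    segments,
    counts: BinnedTrack,
    expected: BinnedTrack,
    fdr: float = DEFAULT_FDR,
    min_rate_ratio: float = DEFAULT_MIN_RATE_RATIO,
) -> list:
    """Poisson upper-tail test per PCF segment; hotspots need q <= fdr and
    rate ratio >= min_rate_ratio."""
    if not (0 < fdr < 1):
        raise InvalidInputError("fdr must be in (0,1)")
    rows = []
    for seg in segments:
        obs = float(counts.values[seg.chrom][seg.start_bin : seg.end_bin].sum())
        exp = float(expected.values[seg.chrom][seg.start_bin : seg.end_bin].sum())
        if exp <= 0:
            if obs > 0:
                warnings.warn(
                    f"segment {seg.chrom}:{seg.start_bin}-{seg.end_bin} has zero "
                    "expectation with observed breakpoints; applying pseudo-expected floor"
                )
            exp = 0.5
        p = float(stats.poisson.sf(obs - 1, exp)) if obs > 0 else 1.0
        rows.append((seg, int(obs), exp, min(p, 1.0)))

    q_values = multipletests([r[3] for r in rows], method="fdr_bh")[1] if rows else []
    out = []
    for (seg, obs, exp, p), q in zip(rows, q_values):
        ratio = obs / exp
        if q <= fdr and ratio >= min_rate_ratio:
            out.append(
                HotspotSegment(
                    chrom=seg.chrom,
                    start=seg.start_bin * counts.bin_width,
                    end=seg.end_bin * counts.bin_width,
                    n_bins=seg.n_bins,
                    observed_breakpoints=obs,
                    expected_breakpoints=exp,
                    rate_ratio=ratio,
                    p_value=p,
                    q_value=float(q),
                )
            )
    out.sort(key=lambda h: (h.q_value, h.chrom, h.start))
    return out


def _intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def flag_fragile(
    hotspots,
    fragile_intervals=None,
    large_genes=None,
    replication_track: Optional[BinnedTrack] = None,
) -> list:
    """Annotate hotspots overlapping fragile resources.

    ``fragile_intervals``: (chrom, start, end) 0-based half-open curated sites;
    ``large_genes``: (name, chrom, start, end); a hotspot is also flagged when
    it contains a gene >= 600 kb whose mean replication-timing value falls in
    the latest-replicating decile of the supplied track (low value = late).
    """
    if fragile_intervals is None and large_genes is None:
        raise InvalidInputError("at least one fragile-flagging source is required")

    late_cutoff = None
    if replication_track is not None:
        late_cutoff = float(np.quantile(replication_track.concat(), LATE_REPLICATION_DECILE))

    out = []
    for h in hotspots:
        flag, reason = False, None
        for chrom, start, end in fragile_intervals or ():
            if chrom == h.chrom and _intervals_overlap(h.start, h.end, start, end):
                flag, reason = True, "listed-site"
                break
        if not flag and large_genes:
            for name, chrom, start, end in large_genes:
                if chrom != h.chrom or (end - start) < LARGE_GENE_BP:
                    continue
                if not (h.start <= start and end <= h.end):
                    continue
                if replication_track is None:
                    flag, reason = True, f"large-gene:{name}"
                    break
                vals = replication_track.values[chrom]
                lo = start // replication_track.bin_width
                hi = max(lo + 1, -(-end // replication_track.bin_width))
                if float(vals[lo:hi].mean()) <= late_cutoff:
                    flag, reason = True, f"large-late-gene:{name}"
                    break
        out.append(
            HotspotSegment(
                **{**h.__dict__, "fragile_flag": flag, "flag_reason": reason}
            )
        )
    return out


def exclude_fragile(hotspots) -> list:
    return [h for h in hotspots if not h.fragile_flag]


def detect_hotspots(
    svs,
    genome,
    covariates=(),
    bin_width: int = 100_000,
    gamma: Optional[float] = None,
    fdr: float = DEFAULT_FDR,
    min_rate_ratio: float = DEFAULT_MIN_RATE_RATIO,
) -> dict:
    """Full pipeline: bin breakpoints, fit covariate background, PCF the
    observed/expected ratio, and call hotspot segments."""
    counts = bin_breakpoints(svs, genome, bin_width)
    expected, beta = fit_background(counts, covariates)
    ratio = counts.like(counts.concat() / np.maximum(expected.concat(), 1e-12))
    if gamma is None:
        gamma = select_gamma(ratio)
    segments = pcf_segment(ratio, gamma)
    hotspots = call_hotspots(segments, counts, expected, fdr=fdr, min_rate_ratio=min_rate_ratio)
    return {
        "counts": counts,
        "expected": expected,
        "coefficients": beta,
        "segments": segments,
        "gamma": gamma,
        "hotspots": hotspots,
    }
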