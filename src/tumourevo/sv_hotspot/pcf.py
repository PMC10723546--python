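"""Exact piecewise constant fitting by penalized least-squares dynamic programming."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cohort_io.model import InvalidInputError

DEFAULT_MIN_BINS = 2


@dataclass
class ConstantSegment:
    """One fitted segment on a single chromosome, bins [start, end)."""

    chrom: str
    start_bin: int
    end_bin: int
    mean: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def pcf_segment_values(x, gamma: float, min_bins: int = DEFAULT_MIN_BINS):
    """Exact minimizer of sum of within-segment squared deviations + gamma per segment.

    Dynamic programming over breakpoints; O(n^2) with vectorized inner loop.
    Returns a list of (start, end, mean) with end exclusive.
    """
    if gamma <= 0:
        raise InvalidInputError("gamma must be > 0")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return []
    if n < min_bins:
        return [(0, n, float(x.mean()))]

    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = 0.0  # every segment, including the first, pays one gamma below

    for j in range(min_bins, n + 1):
        i = np.arange(0, j - min_bins + 1)
        length = j - i
        seg_sum = s1[j] - s1[i]
        seg_cost = (s2[j] - s2[i]) - seg_sum * seg_sum / length
        totals = best[i] + seg_cost + gamma
        k = int(np.argmin(totals))
        best[j] = totals[k]
        prev[j] = i[k]

    cuts = []
    j = n
    while j > 0:
        cuts.append((prev[j], j))
        j = prev[j]
    cuts.reverse()
    return [(a, b, float(x[a:b].mean())) for a, b in cuts]


def pcf_segment(track, gamma: float, min_bins: int = DEFAULT_MIN_BINS) -> list:
    """Run PCF independently per chromosome of a BinnedTrack."""
    segments = []
    for chrom in sorted(track.values):
        for a, b, mean in pcf_segment_values(track.values[chrom], gamma, min_bins):
            segments.append(ConstantSegment(chrom, a, b, mean))
    return segments


def select_gamma(track, floor: float = 1e-3) -> float:
    """Modified-BIC style default penalty: 2 * sigma^2 * log(n)."""
    x = track.concat()
    n = max(x.size, 2)
    diffs = np.diff(x)
    sigma2 = np.median(np.abs(diffs)) ** 2 / (2 * 0.4549) if diffs.size else 1.0
    return max(float(2.0 * max(sigma2, floor) * np.log(n)), floor)
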