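"""Copy-number summary metrics: wGII, WGD call, arm alterations and enrichment."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..cohort_io.model import InvalidInputError

DEFAULT_WGD_MAJOR_CN = 2
DEFAULT_WGD_GENOME_FRACTION = 0.5
ARM_ALTERATION_FRACTION = 0.5
MIN_AUTOSOME_COVERAGE = 0.9


@dataclass(frozen=True)
class ArmDefinition:
    chrom: str
    arm: str  # "p" or "q"
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


def arms_from_genome(genome) -> list:
    """Build p/q arm definitions from (chrom, length, arm_boundary) triples."""
    arms = []
    for chrom, length, boundary in genome:
        if not (0 < boundary < length):
            raise InvalidInputError(
                f"{chrom}: arm boundary {boundary} not strictly inside length {length}"
            )
        arms.append(ArmDefinition(chrom, "p", 1, boundary))
        arms.append(ArmDefinition(chrom, "q", boundary + 1, length))
    return arms


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _overlap(seg, start: int, end: int) -> int:
    return max(0, min(seg.end, end) - max(seg.start, start) + 1)


def wgii(sample, autosomes) -> float:
    """Weighted genome instability index relative to rounded sample ploidy.

    Per autosome: fraction of segment-covered length whose total copy number
    differs from round(ploidy); wGII is the unweighted mean over autosomes.
    ``autosomes`` is a list of (chrom, length) or (chrom, length, boundary).
    Raises if segments cover < 90% of the summed autosome length.
    """
    baseline = _round_half_up(sample.ploidy)
    total_len = 0
    covered_len = 0
    fractions = []
    for entry in autosomes:
        chrom, length = entry[0], entry[1]
        total_len += length
        chrom_covered = 0
        chrom_altered = 0
        for seg in sample.segments:
            if seg.chrom != chrom:
                continue
            ov = _overlap(seg, 1, length)
            chrom_covered += ov
            if seg.total_cn != baseline:
                chrom_altered += ov
        covered_len += chrom_covered
        fractions.append(chrom_altered / chrom_covered if chrom_covered else 0.0)
    if total_len == 0:
        raise InvalidInputError("empty autosome definition")
    if covered_len / total_len < MIN_AUTOSOME_COVERAGE:
        raise InvalidInputError(
            f"segments cover {covered_len / total_len:.1%} of autosomes "
            f"(< {MIN_AUTOSOME_COVERAGE:.0%}); wGII undefined"
        )
    return float(np.mean(fractions))


def call_wgd(
    sample,
    major_cn_threshold: int = DEFAULT_WGD_MAJOR_CN,
    genome_fraction: float = DEFAULT_WGD_GENOME_FRACTION,
) -> bool:
    """WGD iff > ``genome_fraction`` of segment length has major_cn >= 2."""
    total = sum(seg.length for seg in sample.segments)
    if total == 0:
        return False
    high = sum(seg.length for seg in sample.segments if seg.major_cn >= major_cn_threshold)
    return high / total > genome_fraction


def _arm_state(sample, arm: ArmDefinition) -> str:
    baseline = _round_half_up(sample.ploidy)
    gained = lost = 0
    for seg in sample.segments:
        if seg.chrom != arm.chrom:
            continue
        ov = _overlap(seg, arm.start, arm.end)
        if ov == 0:
            continue
        if seg.total_cn > baseline:
            gained += ov
        elif seg.total_cn < baseline:
            lost += ov
    frac_gain = gained / arm.length
    frac_loss = lost / arm.length
    if frac_gain >= ARM_ALTERATION_FRACTION and frac_gain > frac_loss:
        return "gain"
    if frac_loss >= ARM_ALTERATION_FRACTION and frac_loss > frac_gain:
        return "loss"
    return "neutral"


def arm_alteration_matrix(cohort, arm_definitions) -> pd.DataFrame:
    """Arms x samples matrix of {'gain','loss','neutral'} calls.

    An arm is gained/lost iff >= 50% of its length sits above/below the
    sample's rounded ploidy; segment-arm overlap is apportioned by length.
    """
    data = {
        sample.sample_id: [_arm_state(sample, arm) for arm in arm_definitions]
        for sample in cohort
    }
    index = [arm.name for arm in arm_definitions]
    return pd.DataFrame(data, index=index)


def arm_enrichment_test(matrix: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Per-arm, per-direction binomial enrichment against the cohort mean rate.

    Background = cohort-wide mean per-arm alteration rate for the direction;
    p = binomial upper tail P(X >= k); BH correction across arms x directions.
    """
    n_samples = matrix.shape[1]
    if n_samples < min_samples:
        raise InvalidInputError(f"need >= {min_samples} samples, got {n_samples}")
    rows = []
    for direction in ("gain", "loss"):
        hits = (matrix == direction).sum(axis=1)
        background = float(hits.sum()) / (matrix.shape[0] * n_samples)
        if background == 0.0 and hits.sum() > 0:  # pragma: no cover - defensive
            background = 0.5 / (matrix.shape[0] * n_samples)
            warnings.warn("zero background rate with nonzero hits; using pseudo-count")
        for arm, k in hits.items():
            if background == 0.0:
                p = 1.0
            else:
                p = float(stats.binom.sf(k - 1, n_samples, background))
            rows.append(
                {
                    "arm": arm,
                    "direction": direction,
                    "altered": int(k),
                    "n_samples": n_samples,
                    "background_rate": background,
                    "p_value": min(1.0, p),
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["q_value", "arm"]).reset_index(drop=True)
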