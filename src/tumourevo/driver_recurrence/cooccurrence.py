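"""Pairwise driver co-occurrence / mutual-exclusivity testing and the
pathogenic-fraction comparison."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..cohort_io.model import InvalidInputError


@dataclass
class CooccurrencePair:
    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str  # "co-occurring" | "mutually-exclusive" | "independent"


def cooccurrence_test(mutation_matrix: pd.DataFrame) -> tuple:
    """Two-sided Fisher exact test per gene pair over a gene x sample matrix.

    Returns (pairs, untestable): genes constant across the cohort are skipped
    and excluded from the BH family. The odds ratio uses a Haldane-Anscombe
    0.5 correction; the p-value does not.
    """
    matrix = mutation_matrix.astype(bool)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise InvalidInputError("need >= 2 genes and >= 2 samples")

    testable, untestable = [], []
    for gene in matrix.index:
        row = matrix.loc[gene]
        (untestable if row.all() or not row.any() else testable).append(gene)

    raw = []
    for gene_a, gene_b in combinations(sorted(testable), 2):
        a = matrix.loc[gene_a].to_numpy()
        b = matrix.loc[gene_b].to_numpy()
        both = int(np.sum(a & b))
        a_only = int(np.sum(a & ~b))
        b_only = int(np.sum(~a & b))
        neither = int(np.sum(~a & ~b))
        _, p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")
        odds = ((both + 0.5) * (neither + 0.5)) / ((a_only + 0.5) * (b_only + 0.5))
        raw.append((gene_a, gene_b, both, a_only, b_only, neither, odds, float(p)))

    pairs = []
    if raw:
        q_values = multipletests([r[7] for r in raw], method="fdr_bh")[1]
        for (gene_a, gene_b, both, a_only, b_only, neither, odds, p), q in zip(raw, q_values):
            if odds > 1:
                direction = "co-occurring"
            elif odds < 1:
                direction = "mutually-exclusive"
            else:
                direction = "independent"
            pairs.append(
                CooccurrencePair(
                    gene_a, gene_b, both, a_only, b_only, neither,
                    float(odds), p, float(q), direction,
                )
            )
        pairs.sort(key=lambda c: (c.q_value, c.p_value, c.gene_a, c.gene_b))
    return pairs, sorted(untestable)


def pathogenicity_fraction_compare(
    hit_a: int,
    total_a: int,
    hit_b: Optional[int] = None,
    total_b: Optional[int] = None,
) -> tuple:
    """Compare pathogenic-annotated fractions between two variant groups.

    Returns (fraction_a, fraction_b, p_value); the second group is optional,
    in which case only fraction_a is computed. The p-value is a two-sided
    two-proportion chi-square with continuity correction.
    """
    for hit, total in ((hit_a, total_a), (hit_b, total_b)):
        if hit is None and total is None:
            continue
        if hit is None or total is None:
            raise InvalidInputError("hit and total must be given together")
        if total <= 0:
            raise InvalidInputError("total must be > 0")
        if hit < 0 or hit > total:
            raise InvalidInputError("hits must satisfy 0 <= hit <= total")

    fraction_a = hit_a / total_a
    if hit_b is None:
        return fraction_a, None, None
    fraction_b = hit_b / total_b

    table = np.array([[hit_a, total_a - hit_a], [hit_b, total_b - hit_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=True)[1])
    return fraction_a, fraction_b, p
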