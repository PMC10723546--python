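"""Driver clonality odds ratios and relative event ordering (Bradley-Terry)."""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np

from ..cohort_io.model import InvalidInputError


class AbsentGeneError(KeyError):
    pass


def clonality_odds_ratio(
    clonal_gene: int, subclonal_gene: int, clonal_rest: int, subclonal_rest: int
) -> tuple:
    """Odds ratio that a mutation in a gene is clonal versus the remaining genes.

    Haldane-Anscombe 0.5 correction applied to every cell; 95% CI by the
    Woolf logit method on the corrected table.
    """
    cells = np.array(
        [clonal_gene, subclonal_gene, clonal_rest, subclonal_rest], dtype=float
    )
    if (cells < 0).any():
        raise InvalidInputError("negative counts")
    a, b, c, d = cells + 0.5
    odds_ratio = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(odds_ratio)
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return float(odds_ratio), ci


def driver_clonality_or(cohort, gene: str) -> tuple:
    """Clonality odds ratio for one driver gene across a cohort.

    Mutations annotated with the gene form the focal group; all other
    gene-annotated mutations with a clonality flag form the background.
    """
    cg = sg = cr = sr = 0
    for sample in cohort:
        for v in sample.variants:
            if v.gene is None or v.clonal is None:
                continue
            if v.gene == gene:
                cg, sg = cg + v.clonal, sg + (not v.clonal)
            else:
                cr, sr = cr + v.clonal, sr + (not v.clonal)
    if cg + sg == 0:
        raise AbsentGeneError(f"gene {gene!r} has no clonality-annotated mutations")
    return clonality_odds_ratio(cg, sg, cr, sr)


def _connected_components(events, pair_counts):
    adj = defaultdict(set)
    for (a, b) in pair_counts:
        adj[a].add(b)
        adj[b].add(a)
    seen, components = set(), []
    for ev in events:
        if ev in seen:
            continue
        stack, comp = [ev], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        components.append(sorted(comp))
    return components


def relative_event_ordering(
    precedence_pairs,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prior: float = 0.5,
):
    """Rank events from (earlier, later) precedence pairs.

    Bradley-Terry strengths are fitted by minorization-maximization; a small
    symmetric prior count keeps strengths finite when an event always wins.
    Disconnected comparison graphs are ranked per component with a warning.
    Returns a list of (event, strength, component_index) sorted earliest first
    within components.
    """
    if not precedence_pairs:
        raise InvalidInputError("at least one precedence pair required")
    wins = defaultdict(float)
    pair_counts = defaultdict(float)
    events = []
    for earlier, later in precedence_pairs:
        if earlier == later:
            raise InvalidInputError(f"self-comparison for event {earlier!r}")
        wins[(earlier, later)] += 1.0
        key = tuple(sorted((earlier, later)))
        pair_counts[key] += 1.0
        for ev in (earlier, later):
            if ev not in events:
                events.append(ev)

    # symmetric prior on every compared pair
    for a, b in list(pair_counts):
        wins[(a, b)] += prior
        wins[(b, a)] += prior
        pair_counts[(a, b)] += 2 * prior

    components = _connected_components(events, pair_counts)
    if len(components) > 1:
        warnings.warn(
            f"comparison graph has {len(components)} disconnected components; "
            "events are ranked within components only",
            stacklevel=2,
        )

    results = []
    for ci, comp in enumerate(components):
        strengths = {ev: 1.0 for ev in comp}
        total_wins = {
            ev: sum(wins[(ev, other)] for other in comp if other != ev) for ev in comp
        }
        for _ in range(max_iter):
            new = {}
            for ev in comp:
                denom = 0.0
                for other in comp:
                    if other == ev:
                        continue
                    n = pair_counts.get(tuple(sorted((ev, other))), 0.0)
                    if n > 0:
                        denom += n / (strengths[ev] + strengths[other])
                new[ev] = total_wins[ev] / denom if denom > 0 else strengths[ev]
            norm = sum(new.values()) / len(new)
            new = {ev: v / norm for ev, v in new.items()}
            delta = max(abs(new[ev] - strengths[ev]) for ev in comp)
            strengths = new
            if delta < tol:
                break
        for ev in sorted(comp, key=lambda e: -strengths[e]):
            results.append((ev, strengths[ev], ci))
    return results
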