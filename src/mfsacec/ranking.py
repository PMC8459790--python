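"""Occurrence-frequency gene ranking.

A gene's importance is the number of reduced sub-datasets (bootstrap
replicate x filter) of a fitted ensemble in which it is a member of any
of the Q selected clusters.  Because clusters within one sub-dataset are
disjoint, presence counting and membership-multiplicity counting
coincide.  Genes in discarded (non-selected) clusters do not count by
default; ``selected_only=False`` counts them too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import EnsembleModel

__all__ = ["GeneRanking", "count_occurrences", "top_k"]


@dataclass
class GeneRanking:
    """Per-gene occurrence counts with a derived stable rank order."""

    counts: np.ndarray
    gene_ids: list[str]

    def ordered_indices(self) -> np.ndarray:
        """Gene indices by descending count, ties by ascending index."""
        return np.argsort(-self.counts, kind="stable")

    def as_dict(self) -> dict[str, int]:
        return {g: int(c) for g, c in zip(self.gene_ids, self.counts)}


def count_occurrences(model: EnsembleModel, selected_only: bool = True) -> GeneRanking:
    """Count, for every gene, the sub-datasets that selected it."""
    counts = np.zeros(len(model.gene_ids), dtype=int)
    for bm in model.base_models:
        seen: set[int] = set()
        for cluster, _ in bm.rsd.clusters:
            seen.update(cluster.members)
        if not selected_only:
            for cluster in bm.rsd.discarded:
                seen.update(cluster.members)
        counts[list(seen)] += 1
    return GeneRanking(counts=counts, gene_ids=list(model.gene_ids))


def top_k(ranking: GeneRanking, k: int) -> list[str]:
    """The k most frequently selected gene ids."""
    if k < 0 or k > len(ranking.gene_ids):
        raise ValueError(f"k={k} must be in 0..{len(ranking.gene_ids)}")
    order = ranking.ordered_indices()[:k]
    return [ranking.gene_ids[i] for i in order]
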