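"""Greedy supervised attribute clustering with signed representatives.

Starting from a pool of genes ranked by a filter score, clusters are grown
one at a time around the highest-scoring remaining gene (the seed).  The
cluster representative R starts as the seed profile; each remaining pool
gene g is considered once, in descending score order, by forming the two
temporary augmented representatives R + g and R - g, scoring both, and
keeping the better-scoring one only if it *strictly* improves on the
current score of R.  Accepted genes are absorbed with their sign (+1 for a
direct merge, -1 for a sign-flipped merge, so negatively co-expressed
genes reinforce rather than cancel the class signal); rejected genes stay
in the pool for later clusters.  After the pass R is divided by the member
count, giving the signed mean of the member profiles -- the augmented
cluster representative used as a single derived feature.  The procedure
repeats until the pool is empty, so the clusters partition the pool.

The Q strongest representatives (by their score recomputed on the divided
vector) define a reduced sub-dataset of Q derived features; unseen samples
are projected into that space by the same signed-mean map.

Everything here is deterministic: ties between R + g and R - g go to the
direct merge, seed ties go to the lowest gene index, and representative
score ties during Q-selection go to the earlier-created cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterSpec, GeneSubset, Scorer

__all__ = [
    "Cluster",
    "Representative",
    "ReducedSubDataset",
    "refine_cluster",
    "cluster_subset",
    "select_top_q",
    "project",
]


@dataclass
class Cluster:
    """One signed gene cluster.

    ``members`` are gene indices into the parent dataset's gene axis, in
    absorption order (seed first); ``signs`` align with members, the seed
    always carrying +1.  ``score_trace`` records the score of R at the
    seed and after each accepted merge (pre-division), so the strictly
    increasing refinement is checkable after the fact.
    """

    members: list[int]
    signs: list[int]
    order: int
    score_trace: list[float] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class Representative:
    """Augmented cluster representative: the signed mean of the member
    profiles over the (bootstrapped) training samples, with its filter
    score recomputed on the divided vector."""

    vector: np.ndarray | None
    score: float
    pre_division_score: float
    cluster: Cluster


@dataclass
class ReducedSubDataset:
    """The Q selected clusters of one (replicate, filter) pair, ordered by
    descending representative score.  ``discarded`` keeps the unselected
    clusters (membership only) for occurrence-ranking variants."""

    clusters: list[tuple[Cluster, Representative]]
    filter_id: str
    replicate: int
    n_genes: int
    discarded: list[Cluster] = field(default_factory=list)

    @property
    def q(self) -> int:
        return len(self.clusters)

    def to_dict(self) -> dict:
        return {
            "filter_id": self.filter_id,
            "replicate": self.replicate,
            "n_genes": self.n_genes,
            "clusters": [
                {
                    "order": c.order,
                    "members": [int(m) for m in c.members],
                    "signs": [int(s) for s in c.signs],
                    "count": c.count,
                    "score": rep.score,
                    "pre_division_score": rep.pre_division_score,
                }
                for c, rep in self.clusters
            ],
            "discarded": [
                {
                    "order": c.order,
                    "members": [int(m) for m in c.members],
                    "signs": [int(s) for s in c.signs],
                }
                for c in self.discarded
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedSubDataset":
        clusters = []
        for cd in d["clusters"]:
            c = Cluster(members=list(cd["members"]), signs=list(cd["signs"]), order=cd["order"])
            rep = Representative(
                vector=None,
                score=cd["score"],
                pre_division_score=cd["pre_division_score"],
                cluster=c,
            )
            clusters.append((c, rep))
        return cls(
            clusters=clusters,
            filter_id=d["filter_id"],
            replicate=d["replicate"],
            n_genes=d["n_genes"],
            discarded=[
                Cluster(members=list(cd["members"]), signs=list(cd["signs"]), order=cd["order"])
                for cd in d.get("discarded", [])
            ],
        )


def _order_pool(pool: GeneSubset) -> list[int]:
    # descending score, ties by ascending gene index
    order = np.lexsort((pool.indices, -pool.scores))
    return [int(pool.indices[i]) for i in order]


def _refine(ordered: list[int], X: np.ndarray, scorer: Scorer, order_k: int):
    seed = ordered[0]
    R = X[:, seed].astype(float).copy()
    score_r = scorer.score(R)
    cluster = Cluster(members=[seed], signs=[1], order=order_k, score_trace=[score_r])
    snapshot = ordered[1:]
    absorbed: set[int] = set()
    i = 0
    # Candidates are scanned in snapshot order; scoring is batched against
    # the current R and the batch restarts after every accepted merge.
    while i < len(snapshot):
        cols = snapshot[i:]
        G = X[:, cols].astype(float)
        sp = scorer.score_batch(R[:, None] + G)
        sm = scorer.score_batch(R[:, None] - G)
        accepted = False
        for j, g in enumerate(cols):
            if sp[j] >= sm[j]:
                cand_score, sign = sp[j], 1
            else:
                cand_score, sign = sm[j], -1
            if cand_score > score_r:
                R = R + sign * X[:, g]
                score_r = float(cand_score)
                cluster.members.append(g)
                cluster.signs.append(sign)
                cluster.score_trace.append(score_r)
                absorbed.add(g)
                i += j + 1
                accepted = True
                break
        if not accepted:
            break
    remaining = [g for g in snapshot if g not in absorbed]
    rep_vec = R / cluster.count
    rep = Representative(
        vector=rep_vec,
        score=scorer.score(rep_vec),
        pre_division_score=score_r,
        cluster=cluster,
    )
    return cluster, rep, remaining


def refine_cluster(pool: GeneSubset, X: np.ndarray, classes, spec: FilterSpec):
    """Grow one cluster from the pool.

    Returns ``(cluster, representative, remaining)`` where ``remaining``
    is the unabsorbed tail of the pool (a :class:`GeneSubset` preserving
    the original scores).  ``X`` is the full samples x genes matrix the
    pool indices refer to.
    """
    if len(pool) == 0:
        raise ValueError("cannot refine an empty pool")
    scorer = Scorer(classes, spec)
    ordered = _order_pool(pool)
    cluster, rep, remaining = _refine(ordered, np.asarray(X, dtype=float), scorer, order_k=1)
    score_of = {int(g): float(s) for g, s in zip(pool.indices, pool.scores)}
    rem = GeneSubset(
        indices=np.array(remaining, dtype=np.intp),
        scores=np.array([score_of[g] for g in remaining]),
    )
    return cluster, rep, rem


def cluster_subset(pool: GeneSubset, X: np.ndarray, classes, spec: FilterSpec,
                   scorer: Scorer | None = None) -> list[tuple[Cluster, Representative]]:
    """Exhaust the pool into disjoint clusters (a partition of the pool)."""
    if scorer is None:
        scorer = Scorer(classes, spec)
    X = np.ascontiguousarray(X, dtype=float)
    ordered = _order_pool(pool)
    out: list[tuple[Cluster, Representative]] = []
    k = 0
    while ordered:
        k += 1
        cluster, rep, ordered = _refine(ordered, X, scorer, order_k=k)
        out.append((cluster, rep))
    return out


def select_top_q(clusters: list[tuple[Cluster, Representative]], Q: int,
                 filter_id: str = "", replicate: int = 0,
                 n_genes: int = 0) -> ReducedSubDataset:
    """Keep the Q clusters with the highest representative scores; ties
    resolved in favour of earlier creation order."""
    if Q < 1 or Q > len(clusters):
        raise ValueError(
            f"Q={Q} exceeds the {len(clusters)} clusters formed "
            f"(replicate={replicate}, filter={filter_id!r})"
        )
    ranked = sorted(clusters, key=lambda cr: (-cr[1].score, cr[0].order))
    return ReducedSubDataset(
        clusters=ranked[:Q],
        filter_id=filter_id,
        replicate=replicate,
        n_genes=n_genes,
        discarded=[c for c, _ in ranked[Q:]],
    )


def project(rsd: ReducedSubDataset, samples: np.ndarray) -> np.ndarray:
    """Project samples (rows over the original genes) into the Q-feature
    space: feature q = (sum over members of sign * gene value) / count.

    Accumulation runs in member order, so projecting a training sample of
    the owning bootstrap reproduces its stored representative coordinate
    exactly.
    """
    S = np.asarray(samples, dtype=float)
    one_d = S.ndim == 1
    if one_d:
        S = S[None, :]
    if rsd.n_genes and S.shape[1] != rsd.n_genes:
        raise ValueError(f"samples have {S.shape[1]} genes; expected {rsd.n_genes}")
    out = np.empty((S.shape[0], rsd.q))
    for q, (cluster, _) in enumerate(rsd.clusters):
        acc = np.zeros(S.shape[0])
        for g, sign in zip(cluster.members, cluster.signs):
            acc = acc + sign * S[:, g]
        out[:, q] = acc / cluster.count
    return out[0] if one_d else out
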