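"""Naive reference implementation of the greedy supervised attribute
clustering loop, used as an independent oracle.

Written as a literal, list-based transcription of the procedure: while
the pool is non-empty, seed a cluster with the highest-scoring remaining
gene, walk the remaining genes once in descending score order, form
R + g and R - g, score both, keep the direct merge on ties, accept only
strict improvements, and finally divide R by the member count.  It shares
only the scalar score function with the production code; all clustering
logic is independent.
"""

from __future__ import annotations

import numpy as np

from mfsacec.filters import FilterSpec, score_feature


def sac_oracle(pool_indices, pool_scores, X, classes, spec: FilterSpec):
    """Returns a list of (members, signs, count, representative_vector,
    representative_score) tuples, one per cluster in creation order."""
    X = np.asarray(X, dtype=float)
    items = sorted(zip(pool_indices, pool_scores), key=lambda t: (-t[1], t[0]))
    pool = [int(g) for g, _ in items]
    clusters = []
    while pool:
        seed = pool.pop(0)
        R = X[:, seed].copy()
        members = [seed]
        signs = [1]
        score_r = score_feature(R, classes, spec)
        for g in list(pool):
            gv = X[:, g]
            tr_plus = R + gv
            tr_minus = R - gv
            s_plus = score_feature(tr_plus, classes, spec)
            s_minus = score_feature(tr_minus, classes, spec)
            if s_plus >= s_minus:
                cand, cand_score, sign = tr_plus, s_plus, 1
            else:
                cand, cand_score, sign = tr_minus, s_minus, -1
            if cand_score > score_r:
                R = cand
                score_r = cand_score
                members.append(g)
                signs.append(sign)
                pool.remove(g)
        count = len(members)
        rep = R / count
        clusters.append((members, signs, count, rep, score_feature(rep, classes, spec)))
    return clusters
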