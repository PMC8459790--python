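"""Class-relevance filter scores for expression features.

Seven classical filter statistics are provided, each mapping one feature
vector (a gene's expression profile over samples) and the sample class
labels to a single nonnegative relevance score: Fisher score, Welch
t-statistic, chi-square, mutual information, Pearson correlation against
the class indicator, signal-to-noise ratio (SNR), and Relief-F.  Signed
statistics (Pearson, t) are returned as absolute values so that "maximum
relevance" is direction-free; negatively co-expressed genes are handled
downstream by sign-flipped merging, not by the score.

Numerical conventions shared by all scores:

* population (divide-by-n) variances throughout, for determinism;
* denominators guarded with ``EPS = 1e-12``; a constant feature scores 0;
* chi-square and mutual information operate on an equal-frequency
  (rank-based) discretization, so both are invariant under strictly
  monotone transforms of the feature;
* inherently two-class scores (t, Pearson, SNR) extend to N > 2 classes
  by one-vs-rest aggregation (max or mean, per :class:`FilterSpec`).

All batch reductions deliberately avoid BLAS kernels and 1-D pairwise
summation: every sum runs along axis 0 of a 2-D array, so scoring a
feature alone or as one column of a batch yields bit-identical results.
The greedy clustering stage relies on this for its exact, order-sensitive
accept/reject comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "FILTER_IDS",
    "FilterSpec",
    "GeneSubset",
    "Scorer",
    "encode_labels",
    "score_feature",
    "score_all_genes",
    "score_matrix",
    "select_top_p",
]

FILTER_IDS = ("fisher", "ttest", "chi2", "mi", "pearson", "snr", "relief_f")
EPS = 1e-12


@dataclass(frozen=True)
class FilterSpec:
    """Configuration of one filter score function.

    Parameters
    ----------
    id:
        One of :data:`FILTER_IDS`.
    bins:
        Number of equal-frequency bins for chi2/mi discretization.
        ``None`` selects ``max(2, ceil(log2 U) + 1)`` per scored vector.
    relief_k:
        Neighbours per class for Relief-F.  ``None`` selects
        ``max(1, min(10, smallest class size - 1))``.
    relief_m:
        Number of Relief-F sampling rounds; ``"all"`` uses every sample
        (deterministic), an integer uses the first ``m`` samples.
    multiclass_mode:
        One-vs-rest aggregation for two-class statistics when N > 2:
        ``"ovr_max"`` or ``"ovr_mean"``.
    """

    id: str
    bins: int | None = None
    relief_k: int | None = None
    relief_m: int | str = "all"
    multiclass_mode: str = "ovr_max"

    def __post_init__(self) -> None:
        if self.id not in FILTER_IDS:
            raise ValueError(f"unknown filter id {self.id!r}; expected one of {FILTER_IDS}")
        if self.bins is not None and self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.relief_k is not None and self.relief_k < 1:
            raise ValueError("relief_k must be >= 1")
        if self.relief_m != "all" and (not isinstance(self.relief_m, int) or self.relief_m < 1):
            raise ValueError("relief_m must be 'all' or a positive integer")
        if self.multiclass_mode not in ("ovr_max", "ovr_mean"):
            raise ValueError("multiclass_mode must be 'ovr_max' or 'ovr_mean'")


@dataclass
class GeneSubset:
    """Top-P genes of one filter: indices ordered by descending score."""

    indices: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def encode_labels(classes: Sequence) -> tuple[np.ndarray, list]:
    """Map labels to 0..N-1 in order of first appearance.

    Returns the integer class vector and the label order (the fixed class
    set DC used for tie-breaking everywhere downstream).
    """
    arr = np.asarray(classes)
    uniq, first = np.unique(arr, return_index=True)
    order = uniq[np.argsort(first)]
    lut = {lab: i for i, lab in enumerate(order)}
    y = np.fromiter((lut[c] for c in arr), dtype=np.intp, count=len(arr))
    return y, list(order)


def _axis0_sum(a: np.ndarray) -> np.ndarray:
    # a is (u, m); reduce each column as a contiguous 1-D pairwise sum so
    # the result for a column is identical whatever the batch width m
    return np.ascontiguousarray(a.T).sum(axis=1)


class Scorer:
    """Scores feature vectors (or batches of column vectors) against a
    fixed class vector under one :class:`FilterSpec`.

    Built once per (labels, filter) pair; caches class masks, counts and
    derived Relief-F / binning parameters.  ``score_batch`` evaluates each
    column independently, and each column's value is bit-identical to the
    value ``score`` returns for that column alone.
    """

    def __init__(self, classes: Sequence, spec: FilterSpec):
        self.spec = spec
        self.y, self.labels = encode_labels(classes)
        self.n = len(self.y)
        self.n_classes = len(self.labels)
        if self.n_classes < 2:
            raise ValueError("scoring requires at least 2 classes")
        self.class_idx = [np.flatnonzero(self.y == j) for j in range(self.n_classes)]
        self.counts = np.array([len(ix) for ix in self.class_idx])
        self.priors = self.counts / self.n
        if spec.bins is not None:
            self.bins = spec.bins
        else:
            self.bins = max(2, math.ceil(math.log2(self.n)) + 1)
        if spec.relief_k is not None:
            self.relief_k = spec.relief_k
        else:
            self.relief_k = max(1, min(10, int(self.counts.min()) - 1))
        if spec.relief_m == "all":
            self.relief_rows = np.arange(self.n)
        else:
            self.relief_rows = np.arange(min(int(spec.relief_m), self.n))

    # -- public ----------------------------------------------------------

    def score(self, v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        if v.ndim != 1 or len(v) != self.n:
            raise ValueError(f"feature vector must have length {self.n}")
        return float(self.score_batch(v[:, None])[0])

    def score_batch(self, M: np.ndarray) -> np.ndarray:
        """Score each column of the (n_samples, n_features) matrix ``M``."""
        M = np.ascontiguousarray(M, dtype=float)
        if M.ndim != 2 or M.shape[0] != self.n:
            raise ValueError(f"expected matrix with {self.n} rows")
        if not np.isfinite(M).all():
            raise ValueError("non-finite value in feature matrix")
        fn = getattr(self, "_" + self.spec.id)
        out = np.asarray(fn(M), dtype=float)
        const = np.ptp(M, axis=0) == 0
        if const.any():
            out[const] = 0.0
        return out

    # -- helpers ---------------------------------------------------------

    def _class_moments(self, M: np.ndarray):
        means = np.empty((self.n_classes, M.shape[1]))
        variances = np.empty_like(means)
        for j, ix in enumerate(self.class_idx):
            sub = M[ix]
            mu = _axis0_sum(sub) / len(ix)
            means[j] = mu
            variances[j] = _axis0_sum((sub - mu) ** 2) / len(ix)
        return means, variances

    def _ovr(self, per_class: np.ndarray) -> np.ndarray:
        # per_class is (n_classes, m) of one-vs-rest statistics
        if self.n_classes == 2:
            return per_class[0]
        if self.spec.multiclass_mode == "ovr_max":
            return per_class.max(axis=0)
        return per_class.mean(axis=0)

    def _rest_moments(self, M: np.ndarray, means, variances):
        # mean/variance of the complement of each class, from class moments
        total_mu = _axis0_sum(M) / self.n
        total_sq = _axis0_sum(M * M) / self.n
        rest_mu = np.empty_like(means)
        rest_var = np.empty_like(means)
        for j in range(self.n_classes):
            n_r = self.n - self.counts[j]
            rest_mu[j] = (self.n * total_mu - self.counts[j] * means[j]) / n_r
            ex2 = (self.n * total_sq - self.counts[j] * (variances[j] + means[j] ** 2)) / n_r
            rest_var[j] = np.maximum(ex2 - rest_mu[j] ** 2, 0.0)
        return rest_mu, rest_var

    # -- score functions -------------------------------------------------

    def _fisher(self, M: np.ndarray) -> np.ndarray:
        means, variances = self._class_moments(M)
        overall = _axis0_sum(M) / self.n
        num = np.zeros(M.shape[1])
        den = np.zeros(M.shape[1])
        for j in range(self.n_classes):
            num += self.counts[j] * (means[j] - overall) ** 2
            den += self.counts[j] * variances[j]
        return num / (den + EPS)

    def _ttest(self, M: np.ndarray) -> np.ndarray:
        means, variances = self._class_moments(M)
        if self.n_classes == 2:
            se = np.sqrt(variances[0] / self.counts[0] + variances[1] / self.counts[1] + EPS)
            return np.abs(means[0] - means[1]) / se
        rest_mu, rest_var = self._rest_moments(M, means, variances)
        stats = np.empty((self.n_classes, M.shape[1]))
        for j in range(self.n_classes):
            n_r = self.n - self.counts[j]
            se = np.sqrt(variances[j] / self.counts[j] + rest_var[j] / n_r + EPS)
            stats[j] = np.abs(means[j] - rest_mu[j]) / se
        return self._ovr(stats)

    def _snr(self, M: np.ndarray) -> np.ndarray:
        means, variances = self._class_moments(M)
        sds = np.sqrt(variances)
        if self.n_classes == 2:
            return np.abs(means[0] - means[1]) / (sds[0] + sds[1] + EPS)
        rest_mu, rest_var = self._rest_moments(M, means, variances)
        stats = np.empty((self.n_classes, M.shape[1]))
        for j in range(self.n_classes):
            stats[j] = np.abs(means[j] - rest_mu[j]) / (sds[j] + np.sqrt(rest_var[j]) + EPS)
        return self._ovr(stats)

    def _pearson(self, M: np.ndarray) -> np.ndarray:
        mu = _axis0_sum(M) / self.n
        Mc = M - mu
        sd = np.sqrt(_axis0_sum(Mc * Mc) / self.n)
        stats = np.empty((self.n_classes, M.shape[1]))
        for j in range(self.n_classes):
            z = (self.y == j).astype(float)
            zc = z - z.mean()
            sz = math.sqrt(float(np.add.reduce(zc * zc)) / self.n)
            cov = _axis0_sum(Mc * zc[:, None]) / self.n
            den = sd * sz
            # no epsilon here: an exact zero denominator only arises for a
            # constant column (scored 0 anyway), and keeping the quotient
            # exact makes |r| of a·v scale-invariant bit-for-bit
            with np.errstate(divide="ignore", invalid="ignore"):
                stats[j] = np.where(den > 0, np.abs(cov) / den, 0.0)
            if self.n_classes == 2:
                return stats[0]
        return self._ovr(stats)

    def _bin_ids(self, M: np.ndarray) -> np.ndarray:
        ranks = rankdata(M, axis=0, method="average")
        ids = np.floor((ranks - 0.5) * self.bins / self.n).astype(np.intp)
        return np.clip(ids, 0, self.bins - 1)

    def _contingency(self, M: np.ndarray) -> np.ndarray:
        b = self._bin_ids(M)  # (n, m)
        m = M.shape[1]
        code = b * self.n_classes + self.y[:, None] + np.arange(m) * (self.bins * self.n_classes)
        flat = np.bincount(code.ravel(), minlength=m * self.bins * self.n_classes)
        return flat.reshape(m, self.bins, self.n_classes).astype(float)

    def _chi2(self, M: np.ndarray) -> np.ndarray:
        counts = self._contingency(M)
        row = counts.sum(axis=2, keepdims=True)
        col = counts.sum(axis=1, keepdims=True)
        expected = row * col / self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
        return terms.sum(axis=(1, 2))

    def _mi(self, M: np.ndarray) -> np.ndarray:
        counts = self._contingency(M)
        p = counts / self.n
        pr = p.sum(axis=2, keepdims=True)
        pc = p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / (pr * pc)), 0.0)
        return terms.sum(axis=(1, 2))

    def _relief_f(self, M: np.ndarray) -> np.ndarray:
        # Relief-F in the 1-D space of each column: neighbours by |v_i - v_j|,
        # diffs normalized by the feature range, miss terms weighted by
        # P(class)/(1 - P(class of the probe)).
        out = np.empty(M.shape[1])
        m_rounds = len(self.relief_rows)
        for col in range(M.shape[1]):
            v = M[:, col]
            rng_ = float(v.max() - v.min())
            if rng_ == 0.0:
                out[col] = 0.0
                continue
            D = np.abs(v[:, None] - v[None, :]) / rng_
            w = 0.0
            for c, ix_c in enumerate(self.class_idx):
                rows_c = np.intersect1d(ix_c, self.relief_rows, assume_unique=True)
                if len(rows_c) == 0:
                    continue
                # hits
                kh = min(self.relief_k, len(ix_c) - 1)
                if kh > 0:
                    sub = D[np.ix_(rows_c, ix_c)].copy()
                    pos = np.searchsorted(ix_c, rows_c)
                    sub[np.arange(len(rows_c)), pos] = np.inf
                    hit = np.partition(sub, kh - 1, axis=1)[:, :kh]
                    w -= float(hit.sum()) / (m_rounds * kh)
                # misses, per contrasting class
                for c2, ix_c2 in enumerate(self.class_idx):
                    if c2 == c:
                        continue
                    km = min(self.relief_k, len(ix_c2))
                    sub = D[np.ix_(rows_c, ix_c2)]
                    miss = np.partition(sub, km - 1, axis=1)[:, :km]
                    weight = self.priors[c2] / (1.0 - self.priors[c])
                    w += weight * float(miss.sum()) / (m_rounds * km)
            out[col] = max(w, 0.0)
        return out


def score_feature(v: np.ndarray, classes: Sequence, spec: FilterSpec) -> float:
    """Relevance of one feature vector to the class labels; larger is
    more class-relevant.  Signed statistics return their absolute value;
    a constant vector scores 0."""
    return Scorer(classes, spec).score(np.asarray(v, dtype=float))


def _relief_f_matrix(X: np.ndarray, scorer: Scorer) -> np.ndarray:
    """Native multivariate Relief-F over the whole matrix (Manhattan
    distance in the range-normalized feature space)."""
    n, V = X.shape
    rng_ = np.ptp(X, axis=0)
    safe = np.where(rng_ > 0, rng_, 1.0)
    Xn = (X - X.min(axis=0)) / safe
    Xn[:, rng_ == 0] = 0.0
    W = np.zeros(V)
    k = scorer.relief_k
    m_rounds = len(scorer.relief_rows)
    # pairwise Manhattan distances, row by row to bound memory
    for i in scorer.relief_rows:
        c = scorer.y[i]
        dist_i = np.abs(Xn - Xn[i]).sum(axis=1)
        for c2, ix in enumerate(scorer.class_idx):
            if c2 == c:
                cand = ix[ix != i]
                kh = min(k, len(cand))
                if kh == 0:
                    continue
                sel = cand[np.argpartition(dist_i[cand], kh - 1)[:kh]]
                W -= np.abs(Xn[sel] - Xn[i]).sum(axis=0) / (m_rounds * kh)
            else:
                km = min(k, len(ix))
                sel = ix[np.argpartition(dist_i[ix], km - 1)[:km]]
                weight = scorer.priors[c2] / (1.0 - scorer.priors[c])
                W += weight * np.abs(Xn[sel] - Xn[i]).sum(axis=0) / (m_rounds * km)
    return np.maximum(W, 0.0)


def score_matrix(X: np.ndarray, classes: Sequence, spec: FilterSpec) -> np.ndarray:
    """Score every column of a samples x genes matrix.

    Equals ``score_feature`` column by column for every filter except
    Relief-F, which is computed in its native multivariate form here
    (neighbours in the full gene space rather than per single gene).
    """
    X = np.ascontiguousarray(X, dtype=float)
    scorer = Scorer(classes, spec)
    if spec.id == "relief_f":
        if not np.isfinite(X).all():
            raise ValueError("non-finite value in expression matrix")
        out = _relief_f_matrix(X, scorer)
        out[np.ptp(X, axis=0) == 0] = 0.0
        return out
    return scorer.score_batch(X)


def score_all_genes(ds, spec: FilterSpec) -> pd.Series:
    """Per-gene relevance scores for a dataset, aligned to its gene ids."""
    try:
        scores = score_matrix(ds.values, ds.classes, spec)
    except ValueError as exc:  # re-raise with gene context when possible
        raise ValueError(f"scoring failed for dataset: {exc}") from exc
    return pd.Series(scores, index=list(ds.gene_ids), name=spec.id)


def select_top_p(scores: np.ndarray | pd.Series, P: int) -> GeneSubset:
    """The P genes with the highest scores, ordered descending; ties
    broken by ascending original gene index."""
    arr = np.asarray(scores, dtype=float)
    if P < 1 or P > len(arr):
        raise ValueError(f"P={P} must be in 1..{len(arr)}")
    order = np.argsort(-arr, kind="stable")[:P]
    return GeneSubset(indices=order, scores=arr[order])
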