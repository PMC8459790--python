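"""Class-balanced bootstrap replicates.

Each replicate starts as a plain bootstrap draw (U indices, uniform with
replacement) and is then balanced by random oversampling: minority-class
entries already present in the draw are replicated uniformly at random
until every class matches the majority-class count.  A draw that misses a
class entirely is redrawn (bounded retries) and, failing that, replaced by
a stratified per-class draw, since oversampling is undefined on an absent
class.  Replicate seeds derive deterministically from the master seed
(master + replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BootstrapSet",
    "draw_bootstrap",
    "balance_by_oversampling",
    "make_bootstrap_sets",
]

_MAX_REDRAWS = 100


@dataclass
class BootstrapSet:
    """D balanced index vectors into the parent dataset's samples."""

    replicates: list[np.ndarray]
    seed: int
    n_samples: int

    @property
    def d(self) -> int:
        return len(self.replicates)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _classes_of(ds_or_labels) -> np.ndarray:
    return np.asarray(getattr(ds_or_labels, "classes", ds_or_labels))


def draw_bootstrap(ds, seed) -> np.ndarray:
    """U indices drawn uniformly with replacement, guaranteed to cover
    every class (redraw up to 100 times, then a stratified fallback with
    per-class sizes proportional to class frequency, minimum 1)."""
    classes = _classes_of(ds)
    u = len(classes)
    labels = _label_order(classes)
    if u < len(labels):
        raise ValueError("need at least one sample per class")
    rng = _rng(seed)
    for _ in range(_MAX_REDRAWS):
        idx = rng.integers(0, u, size=u)
        if len(np.unique(classes[idx])) == len(labels):
            return idx
    parts = []
    for lab in labels:
        pool = np.flatnonzero(classes == lab)
        parts.append(rng.choice(pool, size=max(1, len(pool)), replace=True))
    return np.concatenate(parts)


def _label_order(classes: np.ndarray) -> list:
    uniq, first = np.unique(classes, return_index=True)
    return list(uniq[np.argsort(first)])


def balance_by_oversampling(idx: np.ndarray, classes, seed) -> np.ndarray:
    """Replicate minority-class entries of ``idx`` (uniformly at random,
    from the entries already drawn) until all class counts equal the
    majority count.  Already-balanced input is returned unchanged."""
    idx = np.asarray(idx)
    classes = np.asarray(classes)
    drawn = classes[idx]
    labels = _label_order(classes)
    counts = {lab: int(np.sum(drawn == lab)) for lab in labels}
    missing = [lab for lab, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"class(es) absent from bootstrap draw: {missing}")
    m = max(counts.values())
    if all(c == m for c in counts.values()):
        return idx
    rng = _rng(seed)
    extras = []
    for lab in labels:
        deficit = m - counts[lab]
        if deficit > 0:
            pool = idx[drawn == lab]
            extras.append(rng.choice(pool, size=deficit, replace=True))
    return np.concatenate([idx] + extras)


def make_bootstrap_sets(ds, D: int, seed: int) -> BootstrapSet:
    """D class-balanced bootstrap replicates of a dataset."""
    if D < 1:
        raise ValueError("D must be >= 1")
    classes = _classes_of(ds)
    replicates = []
    for l in range(D):
        rng = np.random.default_rng(seed + l)
        idx = draw_bootstrap(classes, rng)
        replicates.append(balance_by_oversampling(idx, classes, rng))
    return BootstrapSet(replicates=replicates, seed=seed, n_samples=len(classes))
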