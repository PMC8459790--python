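"""The MFSAC-EC ensemble: fit, vote, predict, save/load.

Fitting builds D class-balanced bootstrap replicates of the training
data.  For each replicate and each configured filter, genes are scored on
the replicate, the top P form a pool, greedy supervised attribute
clustering reduces the pool to signed clusters, and the Q strongest
cluster representatives become the derived features on which one base
learner is trained.  The fitted model therefore holds D x |filters| base
learners; prediction projects a sample through every reduced sub-dataset,
collects one vote per base learner, and returns the modal label (ties
broken by the label earliest in the training data's first-appearance
order).

All feature selection happens inside ``fit`` on training data only, so
cross-validation wrappers that re-fit per fold are leakage-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import ExpressionDataset, RunConfig
from .filters import Scorer, score_matrix, select_top_p
from .resampling import make_bootstrap_sets
from .sac import ReducedSubDataset, cluster_subset, project, select_top_q

__all__ = ["BaseModel", "EnsembleModel", "make_learner", "fit", "predict_votes", "predict"]


def make_learner(cfg: RunConfig, seed: int = 0):
    """Instantiate the configured base learner.

    Defaults: Gaussian naive Bayes; k-nearest-neighbour with k=5
    (sensible range 3..7); CART decision tree with Gini splitting;
    support vector machine with an RBF kernel.
    """
    params = dict(cfg.learner_params)
    if cfg.base_learner == "nb":
        return GaussianNB(**params)
    if cfg.base_learner == "knn":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if cfg.base_learner == "dt":
        params.setdefault("criterion", "gini")
        params.setdefault("random_state", seed % (2**31))
        return DecisionTreeClassifier(**params)
    if cfg.base_learner == "svm":
        params.setdefault("kernel", "rbf")
        params.setdefault("random_state", seed % (2**31))
        return SVC(**params)
    raise ValueError(f"unknown base learner {cfg.base_learner!r}")


@dataclass
class BaseModel:
    """One fitted base learner bound to its reduced sub-dataset."""

    learner: object
    rsd: ReducedSubDataset
    replicate: int
    filter_id: str


class EnsembleModel:
    """The fitted ensemble: D x |filters| base models plus the label map
    and configuration needed for voting and gene ranking."""

    def __init__(self, base_models: list[BaseModel], label_order: list,
                 gene_ids: list[str], config: RunConfig):
        self.base_models = base_models
        self.label_order = list(label_order)
        self.gene_ids = list(gene_ids)
        self.config = config

    @property
    def n_base_models(self) -> int:
        return len(self.base_models)

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "label_order": [str(l) for l in self.label_order],
            "gene_ids": self.gene_ids,
            "n_base_models": self.n_base_models,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        for b, bm in enumerate(self.base_models):
            (directory / f"base_{b:03d}.json").write_text(json.dumps(bm.rsd.to_dict()))
            joblib.dump(bm.learner, directory / f"base_{b:03d}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg = RunConfig.from_dict(meta["config"])
        base_models = []
        for b in range(meta["n_base_models"]):
            rsd = ReducedSubDataset.from_dict(
                json.loads((directory / f"base_{b:03d}.json").read_text())
            )
            learner = joblib.load(directory / f"base_{b:03d}.joblib")
            base_models.append(
                BaseModel(learner=learner, rsd=rsd,
                          replicate=rsd.replicate, filter_id=rsd.filter_id)
            )
        return cls(base_models, meta["label_order"], meta["gene_ids"], cfg)


def _as_matrix(model: EnsembleModel, samples) -> np.ndarray:
    if isinstance(samples, ExpressionDataset):
        if list(samples.gene_ids) != model.gene_ids:
            raise ValueError("sample gene ids do not match the fitted model")
        return samples.values
    S = np.asarray(samples, dtype=float)
    if S.ndim == 1:
        S = S[None, :]
    if S.shape[1] != len(model.gene_ids):
        raise ValueError(
            f"samples have {S.shape[1]} genes; model expects {len(model.gene_ids)}"
        )
    return S


def fit(ds: ExpressionDataset, cfg: RunConfig) -> EnsembleModel:
    """Fit the full ensemble on a training dataset."""
    if cfg.P > ds.n_genes:
        raise ValueError(f"P={cfg.P} exceeds the {ds.n_genes} genes available")
    label_order = ds.label_order
    boots = make_bootstrap_sets(ds, cfg.D, cfg.seed)
    base_models: list[BaseModel] = []
    for l, idx in enumerate(boots.replicates):
        Xb = np.ascontiguousarray(ds.values[idx])
        yb = ds.classes[idx]
        for x, filter_id in enumerate(cfg.filters):
            spec = cfg.filter_spec(filter_id)
            try:
                scores = score_matrix(Xb, yb, spec)
                pool = select_top_p(scores, cfg.P)
                scorer = Scorer(yb, spec)
                clusters = cluster_subset(pool, Xb, yb, spec, scorer=scorer)
                rsd = select_top_q(clusters, cfg.Q, filter_id=filter_id,
                                   replicate=l, n_genes=ds.n_genes)
                F = np.column_stack([rep.vector for _, rep in rsd.clusters])
                learner = make_learner(cfg, seed=cfg.seed + 101 * l + x)
                learner.fit(F, yb)
            except Exception as exc:
                raise RuntimeError(
                    f"fit failed at replicate {l}, filter {filter_id!r}: {exc}"
                ) from exc
            base_models.append(
                BaseModel(learner=learner, rsd=rsd, replicate=l, filter_id=filter_id)
            )
    return EnsembleModel(base_models, label_order, ds.gene_ids, cfg)


def predict_votes(model: EnsembleModel, samples) -> np.ndarray:
    """One vote (a label) per sample per base model; shape
    (n_samples, n_base_models)."""
    S = _as_matrix(model, samples)
    votes = np.empty((S.shape[0], model.n_base_models), dtype=object)
    for b, bm in enumerate(model.base_models):
        F = project(bm.rsd, S)
        votes[:, b] = bm.learner.predict(F)
    return votes


def majority_vote(votes: np.ndarray, label_order: list) -> np.ndarray:
    """Modal label per row; ties go to the label earliest in the fixed
    class order."""
    counts = np.stack(
        [(votes == lab).sum(axis=1) for lab in label_order], axis=1
    )
    winners = counts.argmax(axis=1)  # argmax takes the first maximum
    return np.asarray(label_order, dtype=object)[winners]


def predict(model: EnsembleModel, samples) -> np.ndarray:
    """Majority-vote label per sample."""
    return majority_vote(predict_votes(model, samples), model.label_order)


def vote_fractions(model: EnsembleModel, samples, label) -> np.ndarray:
    """Fraction of base-model votes for ``label`` per sample (the score
    used for ROC analysis)."""
    votes = predict_votes(model, samples)
    return (votes == label).sum(axis=1) / model.n_base_models
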