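"""Reading and writing expression matrices, labels, rankings and run
configuration.

The canonical on-disk form is delimited text (comma or tab) with one
header row, samples as rows and genes as columns, plus a label column or
a separate label file.  Matrices stored genes-as-rows are transposed on
load; the orientation flag changes parsing only, never values.  Genes
with missing values are dropped by default (with a logged count); strict
mode errors instead.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .filters import FILTER_IDS, FilterSpec, encode_labels

__all__ = [
    "ExpressionDataset",
    "RunConfig",
    "load_expression",
    "write_expression",
    "write_ranking",
]

logger = logging.getLogger("mfsacec")

LEARNERS = ("nb", "knn", "dt", "svm")


@dataclass
class ExpressionDataset:
    """A samples x genes real-valued expression matrix with per-sample
    class labels.

    ``values`` is U x V; ``gene_ids`` and ``sample_ids`` are unique;
    ``classes`` holds the original label strings, mapped internally to
    0..N-1 in first-appearance order wherever an index is needed.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.classes = np.asarray(self.classes)
        u, v = self.values.shape
        if u < 2:
            raise ValueError("need at least 2 samples")
        if v < 1:
            raise ValueError("need at least 1 gene")
        if len(self.gene_ids) != v:
            raise ValueError("gene_ids length does not match matrix width")
        if len(self.sample_ids) != u or len(self.classes) != u:
            raise ValueError("sample_ids/classes length does not match matrix height")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes[:5]}")
        if np.isnan(self.values).any():
            raise ValueError("missing values present after load")
        if len(self.label_order) < 2:
            raise ValueError("classification requires >= 2 classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def label_order(self) -> list:
        """The class set DC, in order of first appearance."""
        return encode_labels(self.classes)[1]

    def subset(self, idx: Sequence[int]) -> "ExpressionDataset":
        """A new dataset restricted to the given sample indices (indices
        may repeat; repeated sample ids are disambiguated)."""
        idx = np.asarray(idx)
        sample_ids = [self.sample_ids[i] for i in idx]
        if len(set(sample_ids)) != len(sample_ids):
            sample_ids = [f"{s}#{k}" for k, s in enumerate(sample_ids)]
        return ExpressionDataset(
            values=self.values[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=sample_ids,
            classes=self.classes[idx],
        )


@dataclass
class RunConfig:
    """Everything a fit needs: ensemble size D, genes per filter P,
    representatives per sub-dataset Q, the filter roster, the base
    learner, and the master seed.

    Defaults follow the method's reference settings: D=10 bootstrap
    replicates, P=200 top genes per filter, Q=3 representatives, all
    seven filters, a 5-nearest-neighbour base learner.
    """

    D: int = 10
    P: int = 200
    Q: int = 3
    filters: tuple[str, ...] = FILTER_IDS
    base_learner: str = "knn"
    learner_params: dict = field(default_factory=dict)
    seed: int = 0
    bins: int | None = None
    relief_k: int | None = None
    relief_m: int | str = "all"
    multiclass_mode: str = "ovr_max"
    zscore: bool = False

    def __post_init__(self) -> None:
        self.filters = tuple(self.filters)
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if not (1 <= self.Q <= self.P):
            raise ValueError("need 1 <= Q <= P")
        if not self.filters:
            raise ValueError("at least one filter is required")
        unknown = [f for f in self.filters if f not in FILTER_IDS]
        if unknown:
            raise ValueError(f"unknown filter id(s) {unknown}; expected among {FILTER_IDS}")
        if self.base_learner not in LEARNERS:
            raise ValueError(f"unknown base learner {self.base_learner!r}; expected one of {LEARNERS}")

    def filter_spec(self, filter_id: str) -> FilterSpec:
        return FilterSpec(
            id=filter_id,
            bins=self.bins,
            relief_k=self.relief_k,
            relief_m=self.relief_m,
            multiclass_mode=self.multiclass_mode,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def _detect_sep(path: Path, configured: str | None) -> str:
    if configured is not None:
        return configured
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _read_labels_file(path: Path, sep: str | None) -> pd.Series:
    df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"label file {path} needs an id column and a label column")
    return df.iloc[:, 0]


def load_expression(
    path: str | Path,
    orientation: str = "samples_as_rows",
    labels: str | Path = "label",
    delimiter: str | None = None,
    missing: str = "drop",
    zscore: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path:
        CSV/TSV file with one header row and an id column first.
    orientation:
        ``"samples_as_rows"`` or ``"genes_as_rows"`` (transposed on load).
    labels:
        Name of the label column (samples-as-rows) / label row
        (genes-as-rows), or the path of a two-column side file mapping
        sample id to label.
    missing:
        ``"drop"`` removes genes with any missing value (logged);
        ``"error"`` rejects the file instead.
    zscore:
        Optional per-gene standardization (mean 0, population SD 1)
        applied after loading; off by default.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError("orientation must be 'samples_as_rows' or 'genes_as_rows'")
    if missing not in ("drop", "error"):
        raise ValueError("missing must be 'drop' or 'error'")
    sep = _detect_sep(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)

    label_series = None
    label_is_file = isinstance(labels, Path) or (
        isinstance(labels, str) and Path(labels).is_file()
    )
    if label_is_file:
        label_series = _read_labels_file(Path(labels), delimiter)
    elif orientation == "samples_as_rows":
        if labels not in df.columns:
            raise ValueError(f"label column {labels!r} not found in {path}")
        label_series = df[labels]
        df = df.drop(columns=[labels])
    else:
        if labels not in df.index:
            raise ValueError(f"label row {labels!r} not found in {path}")
        label_series = df.loc[labels]
        df = df.drop(index=labels)

    if orientation == "genes_as_rows":
        df = df.T

    # numeric validation with cell-level context
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at sample {df.index[r]!r}, "
            f"gene {df.columns[c]!r}"
        )
    missing_mask = numeric.isna().any(axis=0)
    if missing_mask.any():
        if missing == "error":
            raise ValueError(
                f"{int(missing_mask.sum())} gene(s) contain missing values "
                f"(first: {numeric.columns[missing_mask][0]!r})"
            )
        dropped = list(numeric.columns[missing_mask])
        logger.info("dropped %d gene(s) with missing values: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
        numeric = numeric.loc[:, ~missing_mask]

    sample_ids = [str(s) for s in numeric.index]
    label_series.index = label_series.index.map(str)
    try:
        classes = np.asarray([label_series[s] for s in sample_ids])
    except KeyError as exc:
        raise ValueError(f"label missing for sample {exc.args[0]!r}") from exc
    if len(label_series) != len(sample_ids):
        raise ValueError(
            f"label count {len(label_series)} does not match sample count {len(sample_ids)}"
        )

    values = numeric.to_numpy(dtype=float)
    if zscore:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    return ExpressionDataset(
        values=values,
        gene_ids=[str(g) for g in numeric.columns],
        sample_ids=sample_ids,
        classes=classes,
    )


def write_expression(ds: ExpressionDataset, path: str | Path,
                     label_column: str = "label", sep: str = ",") -> None:
    """Write samples-as-rows CSV/TSV with the labels as a trailing column."""
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    df[label_column] = ds.classes
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def write_ranking(ranking, path: str | Path) -> None:
    """Write a gene ranking as CSV with columns gene_id, occurrence_count,
    rank (1-based, ordered by descending count, ties by gene index)."""
    order = ranking.ordered_indices()
    if len(order) == 0:
        raise ValueError("cannot write an empty ranking")
    df = pd.DataFrame(
        {
            "gene_id": [ranking.gene_ids[i] for i in order],
            "occurrence_count": ranking.counts[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    df.to_csv(path, index=False)
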