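"""Per-protein embeddings and the fine-tune/evaluate pipeline.

A protein embedding is the global average pool (mean over non-pad
positions) of the encoder's final hidden states.  Downstream heads are
two-layer perceptrons (one hidden layer, default width 256) trained with
an Adam-family optimizer; tasks cover binary, ten-class, multi-label and
regression targets.  Evaluation uses k-fold cross-validation (default
k=10) with accuracy for single-label classification, micro-averaged F1
for multi-label, and Spearman correlation for regression.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .sequence_io import TokenSequence
from .student import StudentModel

TASK_KINDS = ("binary", "multiclass", "multilabel", "regression")


@dataclass(frozen=True)
class EmbeddingMatrix:
    ids: tuple[str, ...]
    vectors: np.ndarray  # n x hidden_dim

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in embedding matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")

    def subset(self, ids: list[str]) -> np.ndarray:
        index = {i: r for r, i in enumerate(self.ids)}
        return self.vectors[[index[i] for i in ids]]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for rid, vec in zip(self.ids, self.vectors):
                fh.write(rid + "\t" + "\t".join(f"{x:.8g}" for x in vec) + "\n")


@dataclass(frozen=True)
class TaskDataset:
    ids: tuple[str, ...]
    labels: np.ndarray
    task_kind: str

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if len(self.ids) != len(self.labels):
            raise ValueError("ids/labels length mismatch")
        if self.task_kind == "multilabel" and np.asarray(self.labels).ndim != 2:
            raise ValueError("multilabel targets must be a 2-D indicator array")


@dataclass(frozen=True)
class HeadConfig:
    hidden_width: int = 256
    max_epochs: int = 500
    learning_rate: float = 1e-3
    tol: float = 1e-5


@dataclass
class CVResult:
    metric_name: str
    per_fold: list[float]
    fold_assignments: dict[str, int] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))


def embed(records: list[TokenSequence], model: StudentModel) -> EmbeddingMatrix:
    """Global-average-pooled hidden states, one row per sequence."""
    for ts in records:
        if max(ts.tokens) >= model.vocab.size:
            raise ValueError(f"sequence {ts.id!r} uses an incompatible vocabulary")
    vectors = np.stack([model.encode(ts).hidden.mean(axis=0) for ts in records])
    return EmbeddingMatrix(ids=tuple(ts.id for ts in records), vectors=vectors)


def fit_head(train_vectors: np.ndarray, train_labels: np.ndarray,
             task_kind: str, head: HeadConfig | None = None, seed: int = 0):
    """Train a two-layer MLP head on frozen embeddings."""
    head = head or HeadConfig()
    y = np.asarray(train_labels)
    common = dict(
        hidden_layer_sizes=(head.hidden_width,), solver="adam",
        learning_rate_init=head.learning_rate, max_iter=head.max_epochs,
        tol=head.tol, n_iter_no_change=20, random_state=seed,
    )
    if task_kind == "regression":
        est = MLPRegressor(**common)
    else:
        if task_kind in ("binary", "multiclass") and len(np.unique(y)) < 2:
            raise ValueError("classification needs at least two classes")
        if task_kind == "multilabel" and y.ndim != 2:
            raise ValueError("multilabel targets must be 2-D")
        est = MLPClassifier(**common)
    est.fit(np.asarray(train_vectors), y)
    return est


def score(estimator, vectors: np.ndarray, labels: np.ndarray,
          task_kind: str) -> tuple[str, float]:
    pred = estimator.predict(np.asarray(vectors))
    y = np.asarray(labels)
    if task_kind in ("binary", "multiclass"):
        return "accuracy", float(accuracy_score(y, pred))
    if task_kind == "multilabel":
        return "micro_f1", float(f1_score(y, pred, average="micro",
                                          zero_division=0))
    rho = spearmanr(y, pred).statistic
    return "spearman", float(0.0 if np.isnan(rho) else rho)


def cross_validate(data: TaskDataset, emb: EmbeddingMatrix, k: int = 10,
                   seed: int = 0, head: HeadConfig | None = None) -> CVResult:
    """Seeded k-fold cross-validation of the MLP head on frozen embeddings."""
    n = len(data.ids)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    x = emb.subset(list(data.ids))
    y = np.asarray(data.labels)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold, assignments, name = [], {}, ""
    for fold, (tr, te) in enumerate(splitter.split(x)):
        assert not set(te) & set(tr)
        est = fit_head(x[tr], y[tr], data.task_kind, head=head, seed=seed)
        name, value = score(est, x[te], y[te], data.task_kind)
        per_fold.append(value)
        for i in te:
            assignments[data.ids[i]] = fold
    return CVResult(metric_name=name, per_fold=per_fold,
                    fold_assignments=assignments)


# -- label file I/O --------------------------------------------------------------


def read_labels(path, task_kind: str) -> TaskDataset:
    """Tab-separated ``id<TAB>label``; multilabel uses comma-separated indices."""
    ids, raw = [], []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            ids.append(row[0])
            raw.append(row[1])
    if task_kind == "regression":
        labels = np.array([float(v) for v in raw])
    elif task_kind == "multilabel":
        parsed = [tuple(int(x) for x in v.split(",") if x != "") for v in raw]
        width = max((max(p) for p in parsed if p), default=-1) + 1
        labels = np.zeros((len(parsed), width), dtype=np.int64)
        for i, p in enumerate(parsed):
            labels[i, list(p)] = 1
    else:
        labels = np.array([int(v) for v in raw])
    return TaskDataset(ids=tuple(ids), labels=labels, task_kind=task_kind)


def write_labels(data: TaskDataset, path) -> None:
    with open(path, "w") as fh:
        for rid, lab in zip(data.ids, np.asarray(data.labels)):
            if data.task_kind == "multilabel":
                val = ",".join(str(i) for i in np.flatnonzero(lab))
            elif data.task_kind == "regression":
                val = f"{float(lab):.6g}"
            else:
                val = str(int(lab))
            fh.write(f"{rid}\t{val}\n")
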