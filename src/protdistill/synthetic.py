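"""Toy protein corpora with planted motifs, plus matching teachers.

Sequences draw background residues i.i.d. from the 20 canonical amino
acids (uniform by default; a frequency table can be supplied) and carry a
class-defining motif inserted at a random position.  Labels are derived
per task kind: the class index for single-label tasks, motif-presence
indicators for the multi-label task, and motif copy-count plus Gaussian
noise for regression.  Together with the synthetic teachers this makes
every training and evaluation path exercisable without any external data.

Default motifs are 8-mers whose 3-mer contents are mutually disjoint, so
the classification signal is unambiguous and a simple k-mer baseline can
verify the task is solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import (CANONICAL_AA, ProteinRecord, Vocabulary, tokenize)
from .downstream import TaskDataset
from .teacher_store import TeacherStore, make_synthetic_teacher, export_teacher

DEFAULT_MOTIFS = ("ACDEFGHI", "IHGFEDCA", "KLMNPQRS", "SRQPNMLK")


@dataclass(frozen=True)
class SyntheticSpec:
    n_sequences: int = 200
    min_length: int = 40
    max_length: int = 80
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    insertion_probability: float = 1.0
    task_kind: str = "multiclass"
    regression_noise_sd: float = 0.1
    max_copies: int = 3  # regression only: copies drawn uniformly in [0, max]
    background: tuple[float, ...] | None = None  # residue frequencies, len 20
    seed: int = 0

    def __post_init__(self):
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("bad length range")
        if not 0.0 <= self.insertion_probability <= 1.0:
            raise ValueError("insertion probability must be in [0, 1]")
        for m in self.motifs:
            if len(m) > self.min_length:
                raise ValueError(f"motif {m!r} longer than min sequence length")
            if any(c not in CANONICAL_AA for c in m):
                raise ValueError(f"motif {m!r} uses non-canonical letters")
        if self.background is not None and len(self.background) != 20:
            raise ValueError("background table must cover the 20 residues")


def _background(spec: SyntheticSpec, length: int,
                rng: np.random.Generator) -> list[str]:
    p = None if spec.background is None else np.asarray(spec.background, float)
    if p is not None:
        p = p / p.sum()
    idx = rng.choice(20, size=length, p=p)
    return [CANONICAL_AA[i] for i in idx]


def _insert(seq: list[str], motif: str, rng: np.random.Generator) -> list[str]:
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    seq[start:start + len(motif)] = list(motif)
    return seq


def _insert_nonoverlapping(seq: list[str], motif: str,
                           rng: np.random.Generator,
                           occupied: list[tuple[int, int]],
                           max_tries: int = 50) -> bool:
    """Place a motif avoiding previously placed windows; False if crowded out."""
    m = len(motif)
    for _ in range(max_tries):
        start = int(rng.integers(0, len(seq) - m + 1))
        if all(start + m <= lo or start >= hi for lo, hi in occupied):
            seq[start:start + m] = list(motif)
            occupied.append((start, start + m))
            return True
    return False


def generate_corpus(spec: SyntheticSpec
                    ) -> tuple[list[ProteinRecord], TaskDataset]:
    """Deterministic corpus + labels for the spec's task kind."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    records: list[ProteinRecord] = []
    labels: list = []

    if spec.task_kind in ("binary", "multiclass"):
        k = 2 if spec.task_kind == "binary" else len(spec.motifs)
        if k > len(spec.motifs):
            raise ValueError("not enough motifs for the class count")
        # balanced sampler: class counts as equal as integer-possible
        counts = [n // k + (1 if i < n % k else 0) for i in range(k)]
        classes = np.repeat(np.arange(k), counts)
        rng.shuffle(classes)
        for i, cls in enumerate(classes):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            seq = _background(spec, length, rng)
            if rng.random() < spec.insertion_probability:
                seq = _insert(seq, spec.motifs[cls], rng)
            records.append(ProteinRecord(id=f"s{i:05d}", sequence="".join(seq)))
            labels.append(int(cls))
        label_arr = np.array(labels, dtype=np.int64)

    elif spec.task_kind == "multilabel":
        for i in range(n):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            seq = _background(spec, length, rng)
            present = np.zeros(len(spec.motifs), dtype=np.int64)
            occupied: list[tuple[int, int]] = []
            for m_idx, motif in enumerate(spec.motifs):
                if rng.random() < spec.insertion_probability:
                    placed = _insert_nonoverlapping(seq, motif, rng, occupied)
                    present[m_idx] = int(placed)
            records.append(ProteinRecord(id=f"s{i:05d}", sequence="".join(seq)))
            labels.append(present)
        label_arr = np.stack(labels)

    elif spec.task_kind == "regression":
        motif = spec.motifs[0]
        for i in range(n):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            seq = _background(spec, length, rng)
            copies = int(rng.integers(0, spec.max_copies + 1))
            placed = 0
            for _ in range(copies):
                # non-overlapping placement on a segment grid
                slot = placed * len(motif)
                if slot + len(motif) <= length:
                    seq[slot:slot + len(motif)] = list(motif)
                    placed += 1
            target = placed + rng.normal(0.0, spec.regression_noise_sd)
            records.append(ProteinRecord(id=f"s{i:05d}", sequence="".join(seq)))
            labels.append(float(target))
        label_arr = np.array(labels, dtype=np.float64)

    else:
        raise ValueError(f"unknown task kind {spec.task_kind!r}")

    dataset = TaskDataset(ids=tuple(r.id for r in records), labels=label_arr,
                          task_kind=spec.task_kind)
    return records, dataset


def build_test_store(corpus: list[ProteinRecord],
                     teacher_specs: list[tuple[str, dict]],
                     vocab: Vocabulary | None = None, seed: int = 0,
                     path=None, max_length: int = 1000) -> TeacherStore:
    """Materialize synthetic teachers over a corpus into a store.

    With ``path=None`` the store lives in memory (HDF5 core driver), which
    is convenient for tests; give a path to persist it.
    """
    vocab = vocab or Vocabulary()
    if path is None:
        store = TeacherStore.in_memory(vocab)
    else:
        store = TeacherStore(path, vocab, mode="w")
    sequences = [tokenize(r, vocab, max_length) for r in corpus]
    for kind, params in teacher_specs:
        fn = make_synthetic_teacher(kind, params, vocab,
                                    rng=np.random.default_rng(seed))
        export_teacher(store, fn, sequences)
    return store


# -- solvability baseline --------------------------------------------------------


def kmer_features(records: list[ProteinRecord], k: int = 3) -> np.ndarray:
    """Bag-of-k-mers count matrix (hashed over the observed k-mer inventory)."""
    inventory: dict[str, int] = {}
    rows = []
    for rec in records:
        counts: dict[int, int] = {}
        for i in range(len(rec.sequence) - k + 1):
            kmer = rec.sequence[i:i + k]
            col = inventory.setdefault(kmer, len(inventory))
            counts[col] = counts.get(col, 0) + 1
        rows.append(counts)
    mat = np.zeros((len(records), len(inventory)))
    for r, counts in enumerate(rows):
        for c, v in counts.items():
            mat[r, c] = v
    return mat
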