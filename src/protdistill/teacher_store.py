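"""Offline teacher-output storage and synthetic teacher construction.

Teachers are consumed only through precomputed per-sequence outputs: each
record holds the teacher's per-position vocabulary distribution (and
optionally a per-position embedding matrix) for one sequence.  Records
live in an HDF5 container keyed ``teacher_id/sequence_id`` with the
vocabulary recorded in the file manifest, so a store is self-describing
and the teacher models themselves never run during student training.

Synthetic teachers provide controllable stand-ins for large pre-trained
models: an ``oracle`` that concentrates probability q on the true residue,
a ``uniform`` know-nothing teacher, a ``motif`` teacher that is oracle-like
only inside occurrences of declared motifs, and a ``noisy_oracle`` alias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .sequence_io import TokenSequence, Vocabulary, detokenize

_ROW_SUM_TOL = 1e-6
STORE_DTYPE = np.float32


@dataclass(frozen=True)
class TeacherOutput:
    teacher_id: str
    sequence_id: str
    dists: np.ndarray  # N x V, rows sum to 1
    embedding: np.ndarray | None = None  # optional N x d_T

    def __post_init__(self):
        d = np.asarray(self.dists)
        if d.ndim != 2:
            raise ValueError("dists must be a 2-D (positions x vocab) array")
        sums = d.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"teacher {self.teacher_id!r} sequence {self.sequence_id!r}: "
                f"rows must sum to 1 (worst deviation {worst:.3g})"
            )


class TeacherStoreError(KeyError):
    pass


class TeacherStore:
    """HDF5-backed keyed store of teacher outputs for a fixed vocabulary."""

    def __init__(self, path, vocab: Vocabulary | None = None, mode: str = "a"):
        self.path = str(path)
        self._file = h5py.File(self.path, mode)
        if "vocab" in self._file.attrs:
            stored = tuple(json.loads(self._file.attrs["vocab"]))
            if vocab is not None and tuple(vocab.tokens) != stored:
                raise ValueError("store vocabulary does not match supplied one")
            self.vocab = Vocabulary(tokens=stored)
        else:
            self.vocab = vocab or Vocabulary()
            self._file.attrs["vocab"] = json.dumps(list(self.vocab.tokens))

    _mem_counter = 0

    @classmethod
    def in_memory(cls, vocab: Vocabulary | None = None) -> "TeacherStore":
        """Anonymous store backed by the HDF5 core driver (never written out)."""
        cls._mem_counter += 1
        store = cls.__new__(cls)
        store.path = f"<memory-{cls._mem_counter}>"
        store._file = h5py.File(
            f"protdistill-mem-{cls._mem_counter}.h5", "w",
            driver="core", backing_store=False,
        )
        store.vocab = vocab or Vocabulary()
        store._file.attrs["vocab"] = json.dumps(list(store.vocab.tokens))
        return store

    # -- lifecycle -------------------------------------------------------------

    def close(self) -> None:
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- inventory -------------------------------------------------------------

    @property
    def teachers(self) -> list[str]:
        return sorted(k for k in self._file.keys())

    def sequence_ids(self, teacher_id: str) -> list[str]:
        if teacher_id not in self._file:
            return []
        return sorted(self._file[teacher_id].keys())

    def has(self, teacher_id: str, sequence_id: str) -> bool:
        return teacher_id in self._file and sequence_id in self._file[teacher_id]

    # -- I/O -------------------------------------------------------------------

    def write_outputs(self, outputs: list[TeacherOutput]) -> None:
        for out in outputs:
            if np.asarray(out.dists).shape[1] != self.vocab.size:
                raise ValueError(
                    f"teacher {out.teacher_id!r}: vocab width "
                    f"{np.asarray(out.dists).shape[1]} != store vocab "
                    f"{self.vocab.size}"
                )
            group = self._file.require_group(out.teacher_id)
            if out.sequence_id in group:
                raise TeacherStoreError(
                    f"duplicate record ({out.teacher_id!r}, {out.sequence_id!r})"
                )
            sub = group.create_group(out.sequence_id)
            sub.create_dataset("dists", data=np.asarray(out.dists, STORE_DTYPE))
            if out.embedding is not None:
                sub.create_dataset(
                    "embedding", data=np.asarray(out.embedding, STORE_DTYPE)
                )
        self._file.flush()

    def read_outputs(self, teacher_id: str,
                     sequence_ids: list[str]) -> list[TeacherOutput]:
        out = []
        for sid in sequence_ids:
            if not self.has(teacher_id, sid):
                raise TeacherStoreError(
                    f"no stored output for teacher {teacher_id!r}, "
                    f"sequence {sid!r}"
                )
            sub = self._file[teacher_id][sid]
            emb = sub["embedding"][()] if "embedding" in sub else None
            out.append(TeacherOutput(
                teacher_id=teacher_id, sequence_id=sid,
                dists=sub["dists"][()], embedding=emb,
            ))
        return out

    def read_dists(self, teacher_id: str, sequence_id: str) -> np.ndarray:
        return self.read_outputs(teacher_id, [sequence_id])[0].dists


# -- synthetic teachers ----------------------------------------------------------


def _oracle_dists(tokens: np.ndarray, q: float, v: int) -> np.ndarray:
    d = np.full((len(tokens), v), (1.0 - q) / (v - 1), dtype=np.float64)
    d[np.arange(len(tokens)), tokens] = q
    return d


def _motif_positions(sequence: str, motifs: list[str]) -> np.ndarray:
    """Boolean mask of positions covered by any motif occurrence."""
    covered = np.zeros(len(sequence), dtype=bool)
    for motif in motifs:
        start = sequence.find(motif)
        while start != -1:
            covered[start:start + len(motif)] = True
            start = sequence.find(motif, start + 1)
    return covered


def make_synthetic_teacher(kind: str, params: dict | None = None,
                           vocab: Vocabulary | None = None,
                           rng: np.random.Generator | int | None = None):
    """Build a pure teacher function TokenSequence -> TeacherOutput.

    kinds:
      oracle / noisy_oracle: probability ``q`` on the true token, remainder
        spread uniformly (q = 1 gives one-hot rows).
      uniform: 1/V everywhere.
      motif: oracle-like (confidence ``q``) inside occurrences of the
        declared ``motifs`` strings, uniform elsewhere.
    """
    params = dict(params or {})
    vocab = vocab or Vocabulary()
    v = vocab.size
    teacher_id = params.pop("teacher_id", kind)

    if kind in ("oracle", "noisy_oracle"):
        q = float(params.get("q", 1.0))
        if not (1.0 / v) < q <= 1.0:
            raise ValueError(f"confidence q must be in (1/V, 1], got {q}")

        def teacher(ts: TokenSequence) -> TeacherOutput:
            tokens = np.asarray(ts.tokens)
            return TeacherOutput(teacher_id, ts.id, _oracle_dists(tokens, q, v))

    elif kind == "uniform":

        def teacher(ts: TokenSequence) -> TeacherOutput:
            d = np.full((len(ts), v), 1.0 / v, dtype=np.float64)
            return TeacherOutput(teacher_id, ts.id, d)

    elif kind == "motif":
        q = float(params.get("q", 0.95))
        motifs = list(params.get("motifs", []))
        if not (1.0 / v) < q <= 1.0:
            raise ValueError(f"confidence q must be in (1/V, 1], got {q}")

        def teacher(ts: TokenSequence) -> TeacherOutput:
            tokens = np.asarray(ts.tokens)
            d = np.full((len(ts), v), 1.0 / v, dtype=np.float64)
            seq = detokenize(ts, vocab)
            inside = _motif_positions(seq, motifs)
            if inside.any():
                d[inside] = _oracle_dists(tokens[inside], q, v)
            return TeacherOutput(teacher_id, ts.id, d)

    else:
        raise ValueError(f"unknown synthetic teacher kind {kind!r}")

    return teacher


def export_teacher(store: TeacherStore, teacher_fn,
                   sequences: list[TokenSequence]) -> None:
    """Materialize a teacher function over a corpus into the store."""
    store.write_outputs([teacher_fn(ts) for ts in sequences])
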