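"""Masked-language-model corruption of token sequences.

Two schemes are provided.  The default ``token`` scheme selects each
position independently with the masking probability (15% by default
elsewhere), so per-sequence masked counts are Binomial(N, rate).  The
``span`` scheme masks contiguous runs with geometric lengths of mean 3
while matching the expected masked fraction via a per-sequence budget.

Selected positions are replaced by the mask token.  The BERT-style
80/10/10 replace/random/keep convention is available behind
``bert_corruption=True`` but is off by default: the objective only
requires predicting originals at masked positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import TokenSequence, Vocabulary

SPAN_MEAN_LENGTH = 3


@dataclass(frozen=True)
class MaskedBatch:
    """Corrupted sequences plus what was masked and what was there."""

    sequences: tuple[TokenSequence, ...]
    mask_positions: tuple[tuple[int, ...], ...]  # strictly increasing, per sequence
    targets: tuple[tuple[int, ...], ...]  # original token at each masked position
    rng_seed: int

    def __post_init__(self):
        for seq, pos, tgt in zip(self.sequences, self.mask_positions, self.targets):
            if len(pos) != len(tgt):
                raise ValueError("mask_positions and targets length mismatch")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("mask_positions must be strictly increasing")
            if pos and pos[-1] >= len(seq):
                raise ValueError("mask position beyond sequence length")

    @property
    def n_masked(self) -> int:
        return sum(len(p) for p in self.mask_positions)


def _select_token(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(n) < rate)


def _select_span(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Geometric spans (mean SPAN_MEAN_LENGTH) up to a budget of rate*n positions."""
    budget = int(round(rate * n))
    masked = np.zeros(n, dtype=bool)
    count = 0
    # cap iterations to guarantee termination on adversarial inputs
    for _ in range(4 * n + 16):
        if count >= budget:
            break
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / SPAN_MEAN_LENGTH))
        end = min(n, start + min(length, budget - count + SPAN_MEAN_LENGTH))
        span = np.arange(start, end)
        fresh = span[~masked[span]][: budget - count]
        masked[fresh] = True
        count += len(fresh)
    return np.flatnonzero(masked)


def apply_mask(batch: list[TokenSequence], rate: float,
               rng: np.random.Generator | int, scheme: str = "token",
               vocab: Vocabulary | None = None,
               bert_corruption: bool = False) -> MaskedBatch:
    """Corrupt a batch of token sequences at the given masking probability."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate must be in [0, 1], got {rate}")
    if not batch:
        raise ValueError("cannot mask an empty batch")
    vocab = vocab or Vocabulary()
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1  # externally owned generator; seed unknown
    select = _select_token if scheme == "token" else _select_span
    if scheme not in ("token", "span"):
        raise ValueError(f"unknown masking scheme {scheme!r}")

    corrupted, all_pos, all_tgt = [], [], []
    for ts in batch:
        n = len(ts)
        pos = select(n, rate, rng)
        tokens = np.array(ts.tokens, dtype=np.int64)
        targets = tokens[pos].tolist()
        if bert_corruption:
            u = rng.random(len(pos))
            n_canonical = vocab.unknown_index  # canonical residues precede specials
            for p, draw in zip(pos, u):
                if draw < 0.8:
                    tokens[p] = vocab.mask_index
                elif draw < 0.9:
                    tokens[p] = int(rng.integers(0, n_canonical))
                # else: keep original
        else:
            tokens[pos] = vocab.mask_index
        corrupted.append(
            TokenSequence(id=ts.id, tokens=tuple(int(t) for t in tokens),
                          original_length=ts.original_length)
        )
        all_pos.append(tuple(int(p) for p in pos))
        all_tgt.append(tuple(int(t) for t in targets))
    return MaskedBatch(
        sequences=tuple(corrupted), mask_positions=tuple(all_pos),
        targets=tuple(all_tgt), rng_seed=seed,
    )


def restore(masked: MaskedBatch) -> list[TokenSequence]:
    """Write targets back at the mask positions, recovering the originals."""
    out = []
    for ts, pos, tgt in zip(masked.sequences, masked.mask_positions, masked.targets):
        tokens = list(ts.tokens)
        for p, t in zip(pos, tgt):
            tokens[p] = t
        out.append(TokenSequence(id=ts.id, tokens=tuple(tokens),
                                 original_length=ts.original_length))
    return out
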