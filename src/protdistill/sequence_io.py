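"""FASTA input, the amino-acid vocabulary, and integer tokenization.

The default vocabulary holds the 20 canonical amino acids in alphabetical
order plus three special symbols (unknown, mask, pad), giving a vocabulary
size of 23.  Ambiguity codes (B, J, O, U, X, Z) map to the unknown symbol.
Sequences longer than ``max_length`` (default 1000 residues) are truncated
to their first ``max_length`` residues, with the original length retained
for auditing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_SYMBOL = "<unk>"
MASK_SYMBOL = "<mask>"
PAD_SYMBOL = "<pad>"

DEFAULT_MAX_LENGTH = 1000


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the record invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (uppercase A-Z)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory: canonical residues then special symbols."""

    tokens: tuple[str, ...] = field(
        default=tuple(CANONICAL_AA) + (UNKNOWN_SYMBOL, MASK_SYMBOL, PAD_SYMBOL)
    )

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary symbols must be unique")
        for sym in (UNKNOWN_SYMBOL, MASK_SYMBOL, PAD_SYMBOL):
            if sym not in self.tokens:
                raise ValueError(f"vocabulary is missing {sym}")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def unknown_index(self) -> int:
        return self.tokens.index(UNKNOWN_SYMBOL)

    @property
    def mask_index(self) -> int:
        return self.tokens.index(MASK_SYMBOL)

    @property
    def pad_index(self) -> int:
        return self.tokens.index(PAD_SYMBOL)

    def index_of(self, residue: str) -> int:
        """Map one residue letter to its token index (unknown if non-canonical)."""
        try:
            return self.tokens.index(residue)
        except ValueError:
            return self.unknown_index

    def fingerprint(self) -> str:
        """Stable hash of the token ordering, used to guard checkpoints."""
        return hashlib.sha256("|".join(self.tokens).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TokenSequence:
    """Integer-encoded sequence; ``original_length`` records pre-truncation size."""

    id: str
    tokens: tuple[int, ...]
    original_length: int

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise ValueError(f"token sequence {self.id!r} is empty")
        if self.original_length < len(self.tokens):
            raise ValueError("original_length smaller than token count")

    def __len__(self) -> int:
        return len(self.tokens)


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into validated records (order preserved).

    Sequences are uppercased and whitespace-stripped.  Duplicate ids and
    empty sequences raise :class:`FastaParseError` naming the offending
    record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        seq = str(entry.seq).replace(" ", "").replace("\t", "").upper()
        if not rid:
            raise FastaParseError(f"{path}: record with empty id")
        if not seq:
            raise FastaParseError(f"{path}: record {rid!r} has an empty sequence")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(ProteinRecord(id=rid, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def tokenize(record: ProteinRecord, vocab: Vocabulary | None = None,
             max_length: int = DEFAULT_MAX_LENGTH) -> TokenSequence:
    """Encode the first ``max_length`` residues as vocabulary indices.

    Non-canonical letters (e.g. B, X, Z) map to the unknown index.
    Characters outside A-Z are rejected.
    """
    vocab = vocab or Vocabulary()
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    clipped = record.sequence[:max_length]
    tokens = []
    for ch in clipped:
        if not ("A" <= ch <= "Z"):
            raise ValueError(
                f"record {record.id!r}: character {ch!r} is not an uppercase letter"
            )
        tokens.append(vocab.index_of(ch))
    return TokenSequence(
        id=record.id, tokens=tuple(tokens), original_length=len(record.sequence)
    )


def detokenize(ts: TokenSequence, vocab: Vocabulary | None = None) -> str:
    """Inverse of :func:`tokenize` for sequences without special tokens."""
    vocab = vocab or Vocabulary()
    out = []
    for tok in ts.tokens:
        if tok in (vocab.mask_index, vocab.pad_index):
            raise ValueError(
                f"sequence {ts.id!r} contains a special token (index {tok}); "
                "cannot detokenize"
            )
        sym = vocab.tokens[tok]
        out.append("X" if sym == UNKNOWN_SYMBOL else sym)
    return "".join(out)
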