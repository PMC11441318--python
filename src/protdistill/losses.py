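"""Masked-LM, KL-distillation, and combined training objectives.

The training objective is

    L = alpha * L_MLM + (1 - alpha) * L_Distill

where L_MLM is the mean negative log-probability of the original residue
at each scored (masked) position, and L_Distill is the mean over positions
of KL(teacher || student) between per-position vocabulary distributions.
Both losses are means over their scored positions rather than raw sums, so
the alpha trade-off does not depend on batch or sequence length.  alpha
defaults to 0.2, weighting distillation more heavily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, constant
from .masking import MaskedBatch

DEFAULT_ALPHA = 0.2


@dataclass(frozen=True)
class LossConfig:
    alpha: float = DEFAULT_ALPHA
    distill_positions: str = "all"  # or "masked_only"
    distill_space: str = "distribution"  # or "embedding"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.distill_positions not in ("all", "masked_only"):
            raise ValueError(f"bad distill_positions {self.distill_positions!r}")
        if self.distill_space not in ("distribution", "embedding"):
            raise ValueError(f"bad distill_space {self.distill_space!r}")


@dataclass(frozen=True)
class LossReport:
    l_mlm: float
    l_distill: float
    l_total: float
    n_masked: int
    per_teacher: dict[str, float] = field(default_factory=dict)
    distill_overflow: bool = False  # True when a KL term was infinite


# -- masked language modeling (scored at masked positions) ----------------------


def mlm_loss_logprobs(log_dists: Tensor, positions, targets) -> Tensor:
    """Differentiable mean negative log-likelihood at scored positions.

    log_dists: (B, N, V) tensor of per-position log-distributions computed
    on the corrupted tokens; positions/targets: per-sequence tuples.
    """
    rows, cols, toks = [], [], []
    for b, (pos, tgt) in enumerate(zip(positions, targets)):
        rows.extend([b] * len(pos))
        cols.extend(pos)
        toks.extend(tgt)
    if not rows:
        raise ValueError("mlm loss is undefined with zero scored positions")
    idx = (np.array(rows), np.array(cols), np.array(toks))
    return -log_dists[idx].mean()


def mlm_loss(student_log_dists: np.ndarray | list[np.ndarray],
             masked: MaskedBatch, scored: str = "masked_only") -> float:
    """Mean −log p(original residue) over scored positions.

    ``student_log_dists`` holds one (N_s, V) log-distribution array per
    sequence in the batch (computed on the corrupted inputs).  By default
    only masked positions are scored; ``scored="all"`` scores every
    position against the restored originals.
    """
    if isinstance(student_log_dists, np.ndarray) and student_log_dists.ndim == 2:
        student_log_dists = [student_log_dists]
    total, count = 0.0, 0
    if scored == "masked_only":
        per_seq = zip(student_log_dists, masked.mask_positions, masked.targets)
    elif scored == "all":
        from .masking import restore

        originals = restore(masked)
        per_seq = (
            (lp, tuple(range(len(ts))), ts.tokens)
            for lp, ts in zip(student_log_dists, originals)
        )
    else:
        raise ValueError(f"bad scored mode {scored!r}")
    for lp, pos, tgt in per_seq:
        for p, t in zip(pos, tgt):
            total -= lp[p, t]
            count += 1
    if count == 0:
        raise ValueError("mlm loss is undefined with zero scored positions")
    return total / count


# -- KL distillation -------------------------------------------------------------


def kl_divergence_rows(p: np.ndarray, q_log: np.ndarray) -> np.ndarray:
    """Row-wise KL(p || q) with the 0*log(0) := 0 convention.

    q is given in log space.  Returns one value per row; +inf where q
    places zero mass on a supported symbol.
    """
    p = np.asarray(p, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        terms = np.where(p > 0, p * (log_p - q_log), 0.0)
    return terms.sum(axis=-1)


def distill_loss(teacher_dists: np.ndarray, student_log_dists: np.ndarray,
                 positions=None) -> float:
    """Mean per-position KL(teacher || student) over the given positions.

    Both arguments are (N, V); ``positions`` defaults to all positions.
    Returns +inf when the student places zero probability on a symbol the
    teacher supports (flagged upstream in the loss report).
    """
    teacher_dists = np.asarray(teacher_dists, dtype=np.float64)
    student_log_dists = np.asarray(student_log_dists, dtype=np.float64)
    if teacher_dists.shape != student_log_dists.shape:
        raise ValueError("teacher/student shape mismatch")
    per_pos = kl_divergence_rows(teacher_dists, student_log_dists)
    if positions is not None:
        positions = np.asarray(positions, dtype=np.int64)
        if len(positions) == 0:
            raise ValueError("distill loss needs at least one position")
        per_pos = per_pos[positions]
    return float(per_pos.mean())


def distill_loss_t(teacher_dists: np.ndarray, student_log_dists: Tensor,
                   positions=None) -> Tensor:
    """Differentiable version over a (B, N, V) student log-distribution tensor.

    teacher_dists: (B, N, V) array; positions: optional boolean (B, N) mask
    of scored positions (e.g. non-pad, or masked-only).
    """
    p = np.asarray(teacher_dists, dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    neg_entropy = float((np.where(p > 0, p * log_p, 0.0)).sum(axis=-1).mean()) \
        if positions is None else None
    cross = -(student_log_dists * constant(p)).sum(axis=-1)  # (B, N)
    if positions is None:
        return cross.mean() + neg_entropy
    mask = np.asarray(positions, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("distill loss needs at least one position")
    neg_ent_masked = float(
        np.where(p > 0, p * log_p, 0.0).sum(axis=-1)[mask].sum() / n
    )
    return (cross * constant(mask.astype(np.float64))).sum() * (1.0 / n) \
        + neg_ent_masked


def embedding_distill_loss_t(teacher_emb: np.ndarray, student_hidden: Tensor,
                             projection: Tensor,
                             positions=None) -> Tensor:
    """Optional embedding-space distillation: MSE through a learned projection.

    student_hidden (B, N, d) is mapped by ``projection`` (d, d_T) onto the
    teacher embedding space and compared by mean squared error.
    """
    target = constant(np.asarray(teacher_emb, dtype=np.float64))
    diff = student_hidden @ projection - target
    sq = diff * diff
    if positions is None:
        return sq.mean()
    mask = np.asarray(positions, dtype=float)[..., None]
    n = float(mask.sum() * target.shape[-1])
    return (sq * constant(mask)).sum() * (1.0 / n)


# -- combination -----------------------------------------------------------------


def combined_loss(l_mlm: float, l_distill: float,
                  cfg: LossConfig | None = None, n_masked: int = 0,
                  per_teacher: dict[str, float] | None = None) -> LossReport:
    """alpha-weighted total: L = alpha*L_MLM + (1-alpha)*L_Distill."""
    cfg = cfg or LossConfig()
    overflow = bool(np.isinf(l_distill))
    total = cfg.alpha * l_mlm + (1.0 - cfg.alpha) * l_distill
    return LossReport(
        l_mlm=float(l_mlm), l_distill=float(l_distill), l_total=float(total),
        n_masked=int(n_masked), per_teacher=dict(per_teacher or {}),
        distill_overflow=overflow,
    )
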