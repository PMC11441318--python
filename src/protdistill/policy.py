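"""Per-instance adaptive teacher selection.

Each teacher k receives a logistic score sigma(w_k . f_k + b_k) computed
from instance features (pooled student hidden state, summaries of that
teacher's predictions, and its current distillation loss).  The scores
are normalized into a categorical distribution, one teacher is sampled,
and after the training step the policy parameters are updated with a
REINFORCE rule: the gradient of log(normalized weight of the chosen
teacher), scaled by the learning rate and the baseline-centred reward.
The baseline is an exponential moving average of rewards (decay 0.9).

An exploration floor (default 0.02) is applied to the sampling
distribution during training so no teacher is starved early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BASELINE_DECAY = 0.9
EXPLORATION_FLOOR = 0.02


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class PolicyFeatures:
    """Per-teacher feature vectors for one training instance.

    ``matrix`` has one row per teacher: the pooled input representation
    concatenated with that teacher's prediction summaries and current loss.
    """

    matrix: np.ndarray  # K x F

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("features must be a (teachers x features) matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError("policy features must be finite")

    @property
    def n_teachers(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def build_features(pooled_hidden: np.ndarray,
                   teacher_dists: list[np.ndarray],
                   teacher_losses: list[float]) -> PolicyFeatures:
    """Assemble the feature matrix from raw per-instance quantities.

    Per teacher: [pooled hidden (d), mean prediction entropy, mean max
    probability, current distillation loss].  The three per-teacher summary
    columns are centred across teachers: what identifies the right teacher
    for an instance is how it compares to the alternatives, not the shared
    baseline level, and centring removes that common mode.
    """
    pooled = np.asarray(pooled_hidden, dtype=np.float64).ravel()
    summaries = []
    for dists, loss in zip(teacher_dists, teacher_losses):
        p = np.asarray(dists, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(-(np.where(p > 0, p * np.log(np.where(p > 0, p, 1)), 0.0)
                          ).sum(axis=-1).mean())
        summaries.append([ent, float(p.max(axis=-1).mean()), float(loss)])
    summaries = np.asarray(summaries)
    if summaries.shape[0] > 1:
        summaries = summaries - summaries.mean(axis=0, keepdims=True)
    rows = [np.concatenate([pooled, s]) for s in summaries]
    return PolicyFeatures(matrix=np.stack(rows))


@dataclass(frozen=True)
class PolicyState:
    weights: np.ndarray  # K x F logistic weight vectors
    bias: np.ndarray  # K
    baseline: float = 0.0
    step: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if self.weights.shape[0] != self.bias.shape[0]:
            raise ValueError("weights/bias teacher count mismatch")
        if self.weights.shape[0] < 1:
            raise ValueError("need at least one teacher")
        if not np.isfinite(self.baseline):
            raise ValueError("baseline must be finite")

    @property
    def n_teachers(self) -> int:
        return self.weights.shape[0]


def init_policy(n_teachers: int, feature_dim: int, seed: int = 0) -> PolicyState:
    """Zero-initialized policy: every teacher starts at weight 1/K."""
    return PolicyState(
        weights=np.zeros((n_teachers, feature_dim)),
        bias=np.zeros(n_teachers),
        baseline=0.0, step=0, rng_seed=seed,
    )


def teacher_weights(state: PolicyState, feats: PolicyFeatures,
                    floor: float = 0.0) -> np.ndarray:
    """Normalized per-teacher selection probabilities."""
    if feats.n_teachers != state.n_teachers:
        raise ValueError("feature rows do not match teacher count")
    if feats.dim != state.weights.shape[1]:
        raise ValueError(
            f"feature dimension {feats.dim} != policy dimension "
            f"{state.weights.shape[1]}"
        )
    raw = _sigmoid((state.weights * feats.matrix).sum(axis=1) + state.bias)
    probs = raw / raw.sum()
    if floor > 0.0 and state.n_teachers > 1:
        probs = np.maximum(probs, floor)
        probs = probs / probs.sum()
    return probs


def sample_teacher(weights: np.ndarray, rng: np.random.Generator | int) -> int:
    """Categorical draw from a normalized weight vector."""
    weights = np.asarray(weights, dtype=np.float64)
    if abs(weights.sum() - 1.0) > 1e-8 or (weights < 0).any():
        raise ValueError("weights must be a probability vector")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    # inverse-CDF draw keeps the stream consumption at one uniform per call
    u = rng.random()
    return int(np.searchsorted(np.cumsum(weights), u, side="right").clip(
        0, len(weights) - 1))


def policy_update(state: PolicyState, feats: PolicyFeatures, chosen: int,
                  reward: float, lr: float) -> PolicyState:
    """REINFORCE step on log(normalized weight of the chosen teacher).

    advantage = reward - baseline; baseline is an EMA of rewards.  With
    lr = 0 or zero advantage the parameters are returned unchanged.
    """
    if not np.isfinite(reward):
        raise ValueError("reward must be finite")
    advantage = reward - state.baseline
    new_baseline = BASELINE_DECAY * state.baseline + (1 - BASELINE_DECAY) * reward
    if lr == 0.0 or advantage == 0.0:
        return replace(state, baseline=new_baseline, step=state.step + 1)
    z = (state.weights * feats.matrix).sum(axis=1) + state.bias
    s = _sigmoid(z)
    total = s.sum()
    # d log p_chosen / d z_k = [k == chosen](1 - s_chosen) - s_k(1 - s_k)/sum(s)
    grad_z = -(s * (1.0 - s)) / total
    grad_z[chosen] += 1.0 - s[chosen]
    scale = lr * advantage
    new_w = state.weights + scale * grad_z[:, None] * feats.matrix
    new_b = state.bias + scale * grad_z
    return PolicyState(weights=new_w, bias=new_b, baseline=new_baseline,
                       step=state.step + 1, rng_seed=state.rng_seed)
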