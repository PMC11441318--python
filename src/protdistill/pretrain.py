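"""Distillation pre-training: masking, student updates, teacher selection.

Each step masks a batch, runs the student on the corrupted tokens,
computes the masked-LM loss and the KL distillation loss against a
teacher chosen per instance by the selection policy, takes an AdamW step
under a linear warm-up / linear decay schedule, and finally updates the
policy with a REINFORCE rule.

Defaults mirror the reference training recipe: ten epochs, batch size 16,
AdamW at 3e-4, warm-up ratio 0.1, masking probability 15%, alpha 0.2.

The policy reward defaults to the decrease, across the optimizer step, of
the instance's own masked-LM loss (``instance_mlm``): it is attributable
to the chosen teacher and it is task-aligned, so a know-nothing teacher
earns negative reward as soon as the student beats the uniform predictor.
Two alternatives are provided: ``holdout_mlm`` (decrease of the masked-LM
loss on a small fixed held-out batch; stable but a weak per-step signal)
and ``instance_combined`` (decrease of the instance's combined loss;
self-referential, since stepping on any teacher's own distillation loss
reduces it, which can reward uninformative teachers).  Rewards are
standardized by a running scale estimate before the policy update so the
policy learning rate is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import AdamW
from .losses import (LossConfig, combined_loss, distill_loss_t, mlm_loss,
                     mlm_loss_logprobs)
from .masking import MaskedBatch, apply_mask
from .policy import (PolicyState, build_features,
                     init_policy, policy_update, sample_teacher,
                     teacher_weights)
from .sequence_io import TokenSequence, Vocabulary
from .student import StudentConfig, StudentModel, save_checkpoint, load_checkpoint
from .teacher_store import TeacherStore


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 10
    batch_size: int = 16
    base_lr: float = 3e-4
    warmup_ratio: float = 0.1
    mask_rate: float = 0.15
    mask_scheme: str = "token"
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    checkpoint_every: int = 0  # steps; 0 = final checkpoint only
    max_steps: int | None = None
    val_fraction: float = 0.1
    weight_decay: float = 0.01
    policy_lr: float = 0.1
    policy_mode: str = "sample"  # or "mixture"
    exploration_floor: float = 0.1  # min sampling weight per teacher
    reward: str = "instance_mlm"  # or "holdout_mlm" / "instance_combined"
    reward_batch_size: int = 8

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 <= self.warmup_ratio < 1.0:
            raise ValueError("warmup_ratio must be in [0, 1)")
        if self.policy_mode not in ("sample", "mixture"):
            raise ValueError(f"bad policy_mode {self.policy_mode!r}")
        if self.reward not in ("instance_mlm", "holdout_mlm",
                               "instance_combined"):
            raise ValueError(f"bad reward {self.reward!r}")


@dataclass
class StepRecord:
    step: int
    l_mlm: float
    l_distill: float
    l_total: float
    lr: float
    chosen_teacher: str
    weights: tuple[float, ...] | None = None


@dataclass
class EpochValidation:
    epoch: int
    val_mlm: float
    val_distill: dict[str, float]


@dataclass
class TrainLog:
    steps: list[StepRecord] = field(default_factory=list)
    validation: list[EpochValidation] = field(default_factory=list)

    def append(self, rec: StepRecord) -> None:
        if self.steps and rec.step <= self.steps[-1].step:
            raise ValueError("steps must be strictly increasing")
        if not all(np.isfinite([rec.l_mlm, rec.l_distill, rec.l_total])):
            raise ValueError("losses must be finite")
        self.steps.append(rec)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tl_mlm\tl_distill\tl_total\tlr\tchosen_teacher"
                     "\tweights\n")
            for r in self.steps:
                w = "" if r.weights is None else ",".join(
                    f"{x:.6f}" for x in r.weights)
                fh.write(f"{r.step}\t{r.l_mlm:.8f}\t{r.l_distill:.8f}\t"
                         f"{r.l_total:.8f}\t{r.lr:.3e}\t{r.chosen_teacher}\t{w}\n")


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, checkpoint_path: str | None = None):
        super().__init__(message)
        self.checkpoint_path = checkpoint_path


def lr_schedule(step: int, total_steps: int, cfg: PretrainConfig) -> float:
    """Linear warm-up to base_lr over warmup_ratio*total, then linear decay to 0."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    warm = math.ceil(cfg.warmup_ratio * total_steps)
    if step <= warm and warm > 0:
        return cfg.base_lr * step / warm
    if total_steps == warm:
        return cfg.base_lr
    return cfg.base_lr * (total_steps - step) / (total_steps - warm)


# -- batching -------------------------------------------------------------------


def _batches(order: np.ndarray, lengths: np.ndarray, batch_size: int,
             rng: np.random.Generator) -> list[np.ndarray]:
    """Length-grouped batches in a shuffled order."""
    by_len = order[np.argsort(lengths[order], kind="stable")]
    chunks = [by_len[i:i + batch_size] for i in range(0, len(by_len), batch_size)]
    rng.shuffle(chunks)
    return chunks


def _pad_batch(seqs: list[TokenSequence], vocab: Vocabulary
               ) -> tuple[np.ndarray, np.ndarray]:
    n = max(len(s) for s in seqs)
    tokens = np.full((len(seqs), n), vocab.pad_index, dtype=np.int64)
    valid = np.zeros((len(seqs), n), dtype=bool)
    for i, s in enumerate(seqs):
        tokens[i, : len(s)] = s.tokens
        valid[i, : len(s)] = True
    return tokens, valid


def _padded_teacher_dists(dists_list: list[np.ndarray], n: int, v: int
                          ) -> np.ndarray:
    out = np.full((len(dists_list), n, v), 1.0 / v, dtype=np.float64)
    for i, d in enumerate(dists_list):
        out[i, : d.shape[0]] = d
    return out


def _distill_mask(cfg: PretrainConfig, valid: np.ndarray,
                  masked: MaskedBatch) -> np.ndarray:
    if cfg.loss.distill_positions == "all":
        return valid
    mask = np.zeros_like(valid)
    for i, pos in enumerate(masked.mask_positions):
        mask[i, list(pos)] = True
    return mask


# -- evaluation helpers ----------------------------------------------------------


def evaluate_mlm(model: StudentModel, seqs: list[TokenSequence],
                 cfg: PretrainConfig, mask_seed: int) -> float:
    """Masked-LM loss on a fixed corruption of the given sequences."""
    masked = apply_mask(list(seqs), cfg.mask_rate, mask_seed,
                        scheme=cfg.mask_scheme, vocab=model.vocab)
    if masked.n_masked == 0:
        masked = apply_mask(list(seqs), max(cfg.mask_rate, 0.15), mask_seed + 1,
                            scheme=cfg.mask_scheme, vocab=model.vocab)
    tokens, _ = _pad_batch(list(masked.sequences), model.vocab)
    _, log_dists = model.forward(tokens)
    per_seq = [log_dists.data[i] for i in range(len(seqs))]
    return mlm_loss(per_seq, masked)


def evaluate_distill(model: StudentModel, seqs: list[TokenSequence],
                     store: TeacherStore, teacher_id: str) -> float:
    """Mean per-position KL(teacher || student) on clean (unmasked) sequences."""
    from .losses import distill_loss

    total, count = 0.0, 0
    for ts in seqs:
        out = model.encode(ts)
        d = store.read_dists(teacher_id, ts.id)
        total += distill_loss(d, out.log_dists) * len(ts)
        count += len(ts)
    return total / count


# -- the loop --------------------------------------------------------------------


def _preflight(store: TeacherStore, corpus: list[TokenSequence],
               teacher_ids: list[str]) -> None:
    for tid in teacher_ids:
        have = set(store.sequence_ids(tid))
        missing = [ts.id for ts in corpus if ts.id not in have]
        if missing:
            raise KeyError(
                f"teacher {tid!r} is missing outputs for "
                f"{len(missing)} sequences (first: {missing[0]!r})"
            )


def _split_validation(corpus: list[TokenSequence], frac: float, seed: int
                      ) -> tuple[list[TokenSequence], list[TokenSequence]]:
    if frac <= 0.0 or len(corpus) < 2:
        return list(corpus), []
    rng = np.random.default_rng([seed, 901])
    order = rng.permutation(len(corpus))
    n_val = max(1, int(round(frac * len(corpus))))
    val_idx = set(order[:n_val].tolist())
    train = [corpus[i] for i in range(len(corpus)) if i not in val_idx]
    val = [corpus[i] for i in sorted(val_idx)]
    return train, val


def pretrain(corpus: list[TokenSequence], store: TeacherStore,
             cfg: PretrainConfig,
             student_config: StudentConfig | None = None,
             teacher_ids: list[str] | None = None,
             out_dir=None,
             resume_from=None,
             ) -> tuple[StudentModel, PolicyState | None, TrainLog]:
    """Run the joint MLM + distillation loop with adaptive teacher selection."""
    vocab = store.vocab
    teacher_ids = list(teacher_ids or store.teachers)
    if not teacher_ids:
        raise ValueError("store holds no teachers")
    _preflight(store, corpus, teacher_ids)

    if out_dir is not None:
        from pathlib import Path

        Path(out_dir).mkdir(parents=True, exist_ok=True)
    student_config = student_config or StudentConfig(vocab_size=vocab.size)
    train_seqs, val_seqs = _split_validation(corpus, cfg.val_fraction, cfg.seed)
    k = len(teacher_ids)
    use_policy = k > 1

    start_epoch = 0
    if resume_from is not None:
        model, extra = load_checkpoint(resume_from, vocab)
        opt = AdamW(model.parameters(), lr=cfg.base_lr,
                    weight_decay=cfg.weight_decay)
        opt.load_state_dict({
            "t": extra["train_state"]["opt_t"],
            "m": [extra[f"opt_m_{i}"] for i in range(len(model.parameters()))],
            "v": [extra[f"opt_v_{i}"] for i in range(len(model.parameters()))],
        })
        start_epoch = int(extra["train_state"]["epoch"])
        reward_var = float(extra["train_state"]["reward_var"])
        global_step = int(extra["train_state"]["global_step"])
        if use_policy and "policy_weights" in extra:
            pol = PolicyState(
                weights=np.asarray(extra["policy_weights"], dtype=np.float64),
                bias=np.asarray(extra["policy_bias"], dtype=np.float64),
                baseline=float(extra["train_state"]["policy_baseline"]),
                step=int(extra["train_state"]["policy_step"]),
                rng_seed=cfg.seed,
            )
        else:
            pol = None
    else:
        model = StudentModel(student_config, vocab=vocab, seed=cfg.seed)
        opt = AdamW(model.parameters(), lr=cfg.base_lr,
                    weight_decay=cfg.weight_decay)
        pol = None
        reward_var = 1.0
        global_step = 0

    # feature dim: pooled hidden + [entropy, max-prob, loss] per teacher
    feat_dim = student_config.hidden_dim + 3
    if use_policy and pol is None:
        pol = init_policy(k, feat_dim, seed=cfg.seed)

    n_batches = math.ceil(len(train_seqs) / cfg.batch_size)
    total_steps = cfg.epochs * n_batches
    if cfg.max_steps is not None:
        total_steps = min(total_steps, cfg.max_steps)

    # fixed held-out batch for the policy reward
    reward_seqs = (val_seqs or train_seqs)[: cfg.reward_batch_size]
    reward_before: float | None = None

    log = TrainLog()
    lengths = np.array([len(s) for s in train_seqs])
    done = global_step >= total_steps

    for epoch in range(start_epoch, cfg.epochs):
        if done:
            break
        shuffle_rng = np.random.default_rng([cfg.seed, epoch, 11])
        policy_rng = np.random.default_rng([cfg.seed, epoch, 23])
        batches = _batches(np.arange(len(train_seqs)), lengths,
                           cfg.batch_size, shuffle_rng)
        for b_idx, batch_ids in enumerate(batches):
            if global_step >= total_steps:
                done = True
                break
            seqs = [train_seqs[i] for i in batch_ids]
            masked = apply_mask(seqs, cfg.mask_rate,
                                np.random.default_rng([cfg.seed, epoch, b_idx, 7]),
                                scheme=cfg.mask_scheme, vocab=vocab)
            if masked.n_masked == 0:
                continue  # nothing to score; vanishingly rare at 15%
            tokens, valid = _pad_batch(list(masked.sequences), vocab)
            bsz, n = tokens.shape

            snapshot = [p.data.copy() for p in model.parameters()]
            hidden, log_dists = model.forward(tokens, valid)

            # teacher payloads and per-instance per-teacher KL
            t_dists = {
                tid: _padded_teacher_dists(
                    [store.read_dists(tid, s.id) for s in seqs], n, vocab.size)
                for tid in teacher_ids
            }
            d_mask = _distill_mask(cfg, valid, masked)
            lp = log_dists.data
            per_inst_kl = np.zeros((bsz, k))
            for j, tid in enumerate(teacher_ids):
                p = t_dists[tid]
                with np.errstate(divide="ignore", invalid="ignore"):
                    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
                    terms = np.where(p > 0, p * (logp - lp), 0.0).sum(axis=-1)
                counts = np.maximum(d_mask.sum(axis=1), 1)
                per_inst_kl[:, j] = (terms * d_mask).sum(axis=1) / counts

            # select a teacher per instance
            feats_list, chosen = [], np.zeros(bsz, dtype=np.int64)
            weights_mean = None
            if use_policy:
                pooled = (hidden.data * valid[..., None]).sum(axis=1) \
                    / valid.sum(axis=1)[:, None]
                all_w = np.zeros((bsz, k))
                for i in range(bsz):
                    feats = build_features(
                        pooled[i],
                        [t_dists[tid][i] for tid in teacher_ids],
                        per_inst_kl[i].tolist(),
                    )
                    w = teacher_weights(pol, feats, floor=cfg.exploration_floor)
                    all_w[i] = w
                    feats_list.append(feats)
                    if cfg.policy_mode == "sample":
                        chosen[i] = sample_teacher(w, policy_rng)
                weights_mean = tuple(all_w.mean(axis=0))

            # differentiable distillation term
            if use_policy and cfg.policy_mode == "mixture":
                mix = np.einsum("bk,bknv->bnv",
                                all_w,
                                np.stack([t_dists[t] for t in teacher_ids], 1))
                l_distill_t = distill_loss_t(mix, log_dists, d_mask)
                chosen_name = "mixture"
            else:
                sel = np.stack([t_dists[teacher_ids[c]][i]
                                for i, c in enumerate(chosen)])
                l_distill_t = distill_loss_t(sel, log_dists, d_mask)
                counts = np.bincount(chosen, minlength=k)
                chosen_name = teacher_ids[int(np.argmax(counts))] if use_policy \
                    else teacher_ids[0]

            l_mlm_t = mlm_loss_logprobs(log_dists, masked.mask_positions,
                                        masked.targets)
            alpha = cfg.loss.alpha
            l_total_t = alpha * l_mlm_t + (1.0 - alpha) * l_distill_t

            report = combined_loss(l_mlm_t.item(), l_distill_t.item(), cfg.loss,
                                   n_masked=masked.n_masked)
            if not np.isfinite(report.l_total):
                ckpt = None
                if out_dir is not None:
                    for p_t, snap in zip(model.parameters(), snapshot):
                        p_t.data = snap
                    ckpt = str(out_dir) + "/last_good.npz"
                    save_checkpoint(ckpt, model)
                raise TrainingDiverged(
                    f"non-finite loss at step {global_step}", ckpt)

            lr = lr_schedule(global_step + 1, total_steps, cfg)
            opt.zero_grad()
            l_total_t.backward()
            opt.step(lr=lr)
            global_step += 1

            # policy reward and update
            if use_policy and cfg.policy_mode == "sample":
                if cfg.reward == "holdout_mlm":
                    if reward_before is None:
                        # evaluate once at the pre-step parameters; afterwards
                        # each step's "after" value is the next step's "before"
                        params_now = [p_t.data for p_t in model.parameters()]
                        for p_t, snap in zip(model.parameters(), snapshot):
                            p_t.data = snap
                        before = evaluate_mlm(model, reward_seqs, cfg,
                                              mask_seed=cfg.seed + 5001)
                        for p_t, cur in zip(model.parameters(), params_now):
                            p_t.data = cur
                    else:
                        before = reward_before
                    after = evaluate_mlm(model, reward_seqs, cfg,
                                         mask_seed=cfg.seed + 5001)
                    reward_before = after
                    reward = before - after
                elif cfg.reward == "instance_mlm":
                    _, lp_after = model.forward(tokens, valid)
                    l_m_after = mlm_loss_logprobs(
                        lp_after, masked.mask_positions, masked.targets)
                    reward = report.l_mlm - l_m_after.item()
                else:  # instance_combined
                    _, lp_after = model.forward(tokens, valid)
                    sel_after = np.stack(
                        [t_dists[teacher_ids[c]][i]
                         for i, c in enumerate(chosen)])
                    l_d_after = distill_loss_t(sel_after, lp_after, d_mask)
                    l_m_after = mlm_loss_logprobs(
                        lp_after, masked.mask_positions, masked.targets)
                    reward = report.l_total - (
                        alpha * l_m_after.item()
                        + (1 - alpha) * l_d_after.item())
                reward_var = 0.9 * reward_var + 0.1 * reward * reward
                scaled = reward / math.sqrt(reward_var + 1e-12)
                for i in range(bsz):
                    pol = policy_update(pol, feats_list[i], int(chosen[i]),
                                        scaled, cfg.policy_lr)

            log.append(StepRecord(
                step=global_step, l_mlm=report.l_mlm,
                l_distill=report.l_distill, l_total=report.l_total, lr=lr,
                chosen_teacher=chosen_name, weights=weights_mean,
            ))

            if (out_dir is not None and cfg.checkpoint_every > 0
                    and global_step % cfg.checkpoint_every == 0):
                save_checkpoint(f"{out_dir}/step_{global_step}.npz", model,
                                extra=_train_extra(opt, pol, epoch + 1,
                                                   reward_var, global_step))

        # per-epoch validation
        if val_seqs:
            val_mlm = evaluate_mlm(model, val_seqs, cfg,
                                   mask_seed=cfg.seed + 9001)
            val_d = {tid: evaluate_distill(model, val_seqs, store, tid)
                     for tid in teacher_ids}
            log.validation.append(EpochValidation(
                epoch=epoch, val_mlm=val_mlm, val_distill=val_d))
        if out_dir is not None:
            save_checkpoint(f"{out_dir}/epoch_{epoch + 1}.npz", model,
                            extra=_train_extra(opt, pol, epoch + 1,
                                               reward_var, global_step))

    if out_dir is not None:
        save_checkpoint(f"{out_dir}/final.npz", model,
                        extra=_train_extra(opt, pol, cfg.epochs,
                                           reward_var, global_step))
    return model, pol, log


def _train_extra(opt: AdamW, pol: PolicyState | None, epoch: int,
                 reward_var: float, global_step: int) -> dict:
    extra: dict = {
        "train_state": {
            "epoch": epoch, "opt_t": opt.t, "reward_var": reward_var,
            "global_step": global_step,
            "policy_baseline": pol.baseline if pol else 0.0,
            "policy_step": pol.step if pol else 0,
        },
    }
    for i, (m, v) in enumerate(zip(opt.m, opt.v)):
        extra[f"opt_m_{i}"] = m
        extra[f"opt_v_{i}"] = v
    if pol is not None:
        extra["policy_weights"] = pol.weights
        extra["policy_bias"] = pol.bias
    return extra


def single_teacher_pretrain(corpus: list[TokenSequence], store: TeacherStore,
                            teacher_id: str, cfg: PretrainConfig,
                            student_config: StudentConfig | None = None,
                            out_dir=None,
                            ) -> tuple[StudentModel, None, TrainLog]:
    """Distill from one named teacher; the selection policy is disabled."""
    if teacher_id not in store.teachers:
        raise KeyError(f"unknown teacher {teacher_id!r}")
    model, _, log = pretrain(corpus, store, cfg, student_config=student_config,
                             teacher_ids=[teacher_id], out_dir=out_dir)
    return model, None, log
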