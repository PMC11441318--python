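"""Reference desk-scale experiments.

Each function builds a synthetic corpus and teacher store, runs the
relevant training path end to end, and returns summary numbers.  These
are the study configurations the test suite asserts against; they are
deliberately small enough to run on one CPU core in minutes.

Problem sizes and optimizer settings per experiment:

* distillation_recovery — 200 training + 20 held-out sequences of 30-60
  residues, one noisy-oracle teacher (q=0.9), pure distillation
  (alpha=0), up to 2000 steps at the default 3e-4 learning rate.
* policy_convergence — 120 sequences of 30-60 residues, an informative
  noisy-oracle teacher (q=0.9) against a know-nothing uniform teacher,
  single-instance batches for clean per-step credit, 1000 policy steps.
* multi_teacher_ablation — 180 training + 40 validation sequences of
  24-40 residues over two classes with letter-disjoint motifs; two
  complementary motif teachers (each covers one class's motif) and a
  combined-oracle reference; 2000 steps per run.
* end_to_end_recovery — 200 sequences of 40-80 residues over four
  letter-disjoint motif classes; the teacher is a motif teacher covering
  all four motifs (its outputs are context-dependent, so matching it
  forces the student to recognize motifs rather than copy residues);
  3000 steps at 1e-3, then 10-fold cross-validation of an MLP head on
  mean-pooled embeddings, against an untrained student of the same size.
"""

from __future__ import annotations

import numpy as np

from .downstream import HeadConfig, cross_validate, embed
from .losses import LossConfig
from .pretrain import (PretrainConfig, evaluate_distill, pretrain,
                       single_teacher_pretrain)
from .sequence_io import tokenize
from .student import StudentConfig, StudentModel
from .synthetic import SyntheticSpec, build_test_store, generate_corpus

#: the small encoder used throughout the desk-scale experiments
TINY_STUDENT = dict(num_layers=2, hidden_dim=32, num_heads=4,
                    feedforward_dim=64, vocab_size=23, max_length=200)

DISJOINT_MOTIFS_2 = ("ACDEFGHI", "KLMNPQRS")
DISJOINT_MOTIFS_4 = ("ACDEF", "GHIKL", "MNPQR", "STVWY")


def _tokenized(records, vocab, max_length=200):
    return [tokenize(r, vocab, max_length) for r in records]


def distillation_recovery(seed: int = 21, max_steps: int = 2000) -> dict:
    """Train a tiny student purely by distillation; measure held-out KL."""
    spec = SyntheticSpec(n_sequences=220, min_length=30, max_length=60,
                         seed=seed)
    records, _ = generate_corpus(spec)
    train_recs, held_recs = records[:200], records[200:]
    store = build_test_store(records, [
        ("noisy_oracle", {"q": 0.9, "teacher_id": "T"})])
    train = _tokenized(train_recs, store.vocab)
    held = _tokenized(held_recs, store.vocab)
    cfg = PretrainConfig(epochs=200, batch_size=16, seed=seed,
                         max_steps=max_steps, loss=LossConfig(alpha=0.0),
                         val_fraction=0.0)
    model, _, log = pretrain(train, store, cfg,
                             student_config=StudentConfig(**TINY_STUDENT))
    return {
        "held_out_kl": evaluate_distill(model, held, store, "T"),
        "steps": len(log.steps),
        "n_train": len(train),
    }


def policy_convergence(seed: int = 31, policy_steps: int = 1000) -> dict:
    """Informative vs uniform teacher; report the informative teacher's
    mean selection weight over the last tenth of training."""
    spec = SyntheticSpec(n_sequences=120, min_length=30, max_length=60,
                         seed=seed)
    records, _ = generate_corpus(spec)
    store = build_test_store(records, [
        ("noisy_oracle", {"q": 0.9, "teacher_id": "informative"}),
        ("uniform", {"teacher_id": "uniform"}),
    ])
    corpus = _tokenized(records, store.vocab)
    cfg = PretrainConfig(epochs=10 * policy_steps, batch_size=1, seed=seed,
                         max_steps=policy_steps, policy_lr=0.1,
                         val_fraction=0.1)
    _, pol, log = pretrain(corpus, store, cfg,
                           student_config=StudentConfig(**TINY_STUDENT))
    informative = store.teachers.index("informative")
    tail = max(1, policy_steps // 10)
    weights = np.array([r.weights for r in log.steps[-tail:]])
    return {
        "mean_informative_weight": float(weights[:, informative].mean()),
        "policy_updates": pol.step,
        "steps": len(log.steps),
    }


def multi_teacher_ablation(seed: int = 41, max_steps: int = 2000) -> dict:
    """Two complementary motif teachers vs each alone, scored against a
    combined oracle on held-out sequences."""
    motif_a, motif_b = DISJOINT_MOTIFS_2
    spec = SyntheticSpec(n_sequences=220, min_length=24, max_length=40,
                         motifs=DISJOINT_MOTIFS_2, task_kind="binary",
                         seed=seed)
    records, _ = generate_corpus(spec)
    store = build_test_store(records, [
        ("motif", {"q": 0.9, "motifs": [motif_a], "teacher_id": "A"}),
        ("motif", {"q": 0.9, "motifs": [motif_b], "teacher_id": "B"}),
        ("motif", {"q": 0.9, "motifs": [motif_a, motif_b],
                   "teacher_id": "oracle_both"}),
    ])
    corpus = _tokenized(records, store.vocab)
    train, val = corpus[:180], corpus[180:]
    scfg = StudentConfig(**TINY_STUDENT)
    cfg = PretrainConfig(epochs=200, batch_size=8, seed=seed,
                         max_steps=max_steps, val_fraction=0.0)
    multi, _, _ = pretrain(train, store, cfg, teacher_ids=["A", "B"],
                           student_config=scfg)
    only_a, _, _ = single_teacher_pretrain(train, store, "A", cfg,
                                           student_config=scfg)
    only_b, _, _ = single_teacher_pretrain(train, store, "B", cfg,
                                           student_config=scfg)
    return {
        "multi": evaluate_distill(multi, val, store, "oracle_both"),
        "single_A": evaluate_distill(only_a, val, store, "oracle_both"),
        "single_B": evaluate_distill(only_b, val, store, "oracle_both"),
        "n_val": len(val),
    }


def end_to_end_recovery(seed: int = 51, max_steps: int = 3000) -> dict:
    """Distill from a motif teacher, then cross-validate an MLP head on
    pooled embeddings; compare against an untrained student."""
    spec = SyntheticSpec(n_sequences=200, min_length=40, max_length=80,
                         motifs=DISJOINT_MOTIFS_4, seed=seed)
    records, data = generate_corpus(spec)
    store = build_test_store(records, [
        ("motif", {"q": 0.95, "motifs": list(DISJOINT_MOTIFS_4),
                   "teacher_id": "T"})])
    corpus = _tokenized(records, store.vocab)
    scfg = StudentConfig(**TINY_STUDENT)
    cfg = PretrainConfig(epochs=400, batch_size=16, seed=seed,
                         max_steps=max_steps, base_lr=1e-3, val_fraction=0.1)
    trained, _, _ = pretrain(corpus, store, cfg, student_config=scfg)
    untrained = StudentModel(scfg, vocab=store.vocab, seed=seed)
    head = HeadConfig(max_epochs=400)
    out = {}
    for name, model in (("trained", trained), ("untrained", untrained)):
        emb = embed(corpus, model)
        result = cross_validate(data, emb, k=10, seed=seed, head=head)
        out[f"{name}_cv_accuracy"] = result.mean
    out["n"] = len(corpus)
    return out
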