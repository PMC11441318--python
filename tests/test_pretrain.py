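import numpy as np
import pytest

from protdistill.losses import LossConfig
from protdistill.masking import apply_mask
from protdistill.pretrain import (PretrainConfig, TrainLog, StepRecord,
                                  lr_schedule, pretrain,
                                  single_teacher_pretrain)
from protdistill.sequence_io import Vocabulary, tokenize
from protdistill.student import StudentConfig, load_checkpoint
from protdistill.synthetic import SyntheticSpec, build_test_store, \
    generate_corpus
from protdistill.losses import mlm_loss_logprobs, distill_loss_t
from protdistill.pretrain import _pad_batch


TINY = dict(num_layers=2, hidden_dim=32, num_heads=4, feedforward_dim=64,
            vocab_size=23, max_length=200)


@pytest.fixture(scope="module")
def small_setup():
    spec = SyntheticSpec(n_sequences=24, min_length=20, max_length=40, seed=2)
    records, _ = generate_corpus(spec)
    store = build_test_store(records, [("noisy_oracle", {"q": 0.9,
                                                         "teacher_id": "A"})])
    vocab = store.vocab
    corpus = [tokenize(r, vocab, 200) for r in records]
    return corpus, store


def test_lr_schedule_shape():
    cfg = PretrainConfig(base_lr=3e-4, warmup_ratio=0.1)
    total = 1000
    assert lr_schedule(0, total, cfg) == 0.0
    warm = int(np.ceil(0.1 * total))
    assert lr_schedule(warm, total, cfg) == pytest.approx(3e-4)
    assert lr_schedule(total, total, cfg) == 0.0
    values = [lr_schedule(s, total, cfg) for s in range(total + 1)]
    diffs = np.diff(values)
    assert np.all(diffs[:warm] >= 0)  # non-decreasing on warm-up
    assert np.all(diffs[warm:] <= 0)  # non-increasing after


def test_lr_schedule_rejects_out_of_range():
    cfg = PretrainConfig()
    with pytest.raises(ValueError):
        lr_schedule(11, 10, cfg)


def test_smoke_run_all_losses_finite(small_setup):
    corpus, store = small_setup
    cfg = PretrainConfig(epochs=2, batch_size=8, seed=1)
    model, pol, log = pretrain(corpus, store, cfg,
                               student_config=StudentConfig(**TINY))
    assert pol is None  # single teacher: no policy
    assert len(log.steps) > 0
    for rec in log.steps:
        assert np.isfinite([rec.l_mlm, rec.l_distill, rec.l_total]).all()
    assert len(log.validation) == 2


def test_identical_seed_gives_bitwise_identical_parameters(small_setup):
    corpus, store = small_setup
    cfg = PretrainConfig(epochs=1, batch_size=8, seed=5)
    scfg = StudentConfig(**TINY)
    m1, _, log1 = pretrain(corpus, store, cfg, student_config=scfg)
    m2, _, log2 = pretrain(corpus, store, cfg, student_config=scfg)
    for a, b in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(a.data, b.data)
    assert [r.l_total for r in log1.steps] == [r.l_total for r in log2.steps]


def test_preflight_rejects_missing_teacher_records(small_setup):
    corpus, store = small_setup
    from protdistill.sequence_io import TokenSequence

    stranger = TokenSequence("not-in-store", (1, 2, 3), 3)
    with pytest.raises(KeyError, match="not-in-store"):
        pretrain(corpus + [stranger], store, PretrainConfig(epochs=1),
                 student_config=StudentConfig(**TINY))


def test_single_teacher_equals_pretrain_with_one_teacher(small_setup):
    corpus, store = small_setup
    cfg = PretrainConfig(epochs=1, batch_size=8, seed=3)
    scfg = StudentConfig(**TINY)
    m1, p1, log1 = pretrain(corpus, store, cfg, student_config=scfg)
    m2, p2, log2 = single_teacher_pretrain(corpus, store, "A", cfg,
                                           student_config=scfg)
    assert p2 is None
    for a, b in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(a.data, b.data)
    assert [(r.step, r.l_total, r.chosen_teacher) for r in log1.steps] == \
        [(r.step, r.l_total, r.chosen_teacher) for r in log2.steps]
    assert all(r.weights is None for r in log2.steps)


def test_single_teacher_unknown_id_rejected(small_setup):
    corpus, store = small_setup
    with pytest.raises(KeyError, match="ghost"):
        single_teacher_pretrain(corpus, store, "ghost", PretrainConfig())


def test_checkpoint_resume_equals_straight_run(tmp_path, small_setup):
    corpus, store = small_setup
    scfg = StudentConfig(**TINY)
    straight_dir = tmp_path / "straight"
    cfg4 = PretrainConfig(epochs=4, batch_size=8, seed=9)
    m_straight, _, _ = pretrain(corpus, store, cfg4, student_config=scfg,
                                out_dir=straight_dir)
    # replaying epochs 3-4 from the mid-run checkpoint must land on the
    # same final parameters as the uninterrupted run
    m_resumed, _, _ = pretrain(corpus, store, cfg4, student_config=scfg,
                               resume_from=straight_dir / "epoch_2.npz")
    for a, b in zip(m_straight.parameters(), m_resumed.parameters()):
        assert np.array_equal(a.data, b.data)


def test_alpha_extremes_control_gradient_flow(small_setup):
    """alpha=1 is pure MLM, alpha=0 pure distillation (gradient accounting)."""
    corpus, store = small_setup
    vocab = store.vocab
    from protdistill.student import StudentModel

    masked = apply_mask(corpus[:4], 0.15, 3, vocab=vocab)
    tokens, valid = _pad_batch(list(masked.sequences), vocab)
    teacher = np.stack([
        np.pad(store.read_dists("A", s.id).astype(np.float64),
               ((0, tokens.shape[1] - len(s)), (0, 0)),
               constant_values=1.0 / vocab.size)
        for s in corpus[:4]
    ])

    def grads(alpha):
        model = StudentModel(StudentConfig(**TINY), vocab=vocab, seed=4)
        _, lp = model.forward(tokens, valid)
        l_m = mlm_loss_logprobs(lp, masked.mask_positions, masked.targets)
        l_d = distill_loss_t(teacher, lp, valid)
        (alpha * l_m + (1 - alpha) * l_d).backward()
        return [p.grad.copy() for p in model.parameters()]

    def grads_single(term):
        model = StudentModel(StudentConfig(**TINY), vocab=vocab, seed=4)
        _, lp = model.forward(tokens, valid)
        if term == "mlm":
            loss = mlm_loss_logprobs(lp, masked.mask_positions, masked.targets)
        else:
            loss = distill_loss_t(teacher, lp, valid)
        loss.backward()
        return [p.grad.copy() for p in model.parameters()]

    for g_combined, g_pure in zip(grads(1.0), grads_single("mlm")):
        assert np.allclose(g_combined, g_pure, atol=1e-12)
    for g_combined, g_pure in zip(grads(0.0), grads_single("distill")):
        assert np.allclose(g_combined, g_pure, atol=1e-12)


def test_training_reduces_loss_on_toy_corpus():
    # 200-sequence corpus, noisy oracle teacher, ten epochs
    spec = SyntheticSpec(n_sequences=200, min_length=20, max_length=40, seed=2)
    records, _ = generate_corpus(spec)
    store = build_test_store(records, [("noisy_oracle",
                                        {"q": 0.9, "teacher_id": "A"})])
    corpus = [tokenize(r, store.vocab, 200) for r in records]
    cfg = PretrainConfig(epochs=10, batch_size=8, seed=7, val_fraction=0.0)
    _, _, log = pretrain(corpus, store, cfg,
                         student_config=StudentConfig(**TINY))
    n_per_epoch = len(log.steps) // 10
    first = np.mean([r.l_total for r in log.steps[:n_per_epoch]])
    last = np.mean([r.l_total for r in log.steps[-n_per_epoch:]])
    assert last < 0.7 * first


def test_train_log_rejects_bad_records():
    log = TrainLog()
    log.append(StepRecord(1, 0.1, 0.1, 0.1, 1e-4, "A"))
    with pytest.raises(ValueError, match="increasing"):
        log.append(StepRecord(1, 0.1, 0.1, 0.1, 1e-4, "A"))
    with pytest.raises(ValueError, match="finite"):
        log.append(StepRecord(2, np.nan, 0.1, 0.1, 1e-4, "A"))


def test_train_log_tsv_round_trip(tmp_path):
    log = TrainLog()
    log.append(StepRecord(1, 0.5, 0.25, 0.3, 3e-4, "A", (0.6, 0.4)))
    path = tmp_path / "log.tsv"
    log.write_tsv(path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].startswith("step\t")
    assert lines[1].split("\t")[5] == "A"


def test_checkpoint_written_and_loadable(tmp_path, small_setup):
    corpus, store = small_setup
    cfg = PretrainConfig(epochs=1, batch_size=8, seed=2)
    model, _, _ = pretrain(corpus, store, cfg,
                           student_config=StudentConfig(**TINY),
                           out_dir=tmp_path)
    loaded, extra = load_checkpoint(tmp_path / "final.npz", Vocabulary())
    for a, b in zip(model.parameters(), loaded.parameters()):
        assert np.array_equal(a.data, b.data)
    assert extra["train_state"]["epoch"] == 1
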