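import numpy as np
import pytest
from hypothesis import given, strategies as st

from protdistill.losses import LossConfig, distill_loss_t, mlm_loss_logprobs
from protdistill.masking import apply_mask
from protdistill.sequence_io import TokenSequence, Vocabulary
from protdistill.student import (StudentConfig, StudentModel, count_parameters,
                                 load_checkpoint, save_checkpoint)

from conftest import random_token_sequences


def test_output_rows_are_distributions(tiny_model, vocab):
    rng = np.random.default_rng(0)
    for ts in random_token_sequences(5, vocab, rng):
        out = tiny_model.encode(ts)
        assert out.dists.shape == (len(ts), vocab.size)
        assert np.allclose(out.dists.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out.dists > 0) and np.all(out.dists < 1)
        assert np.all(np.isfinite(out.hidden))


@given(st.integers(0, 2**31 - 1))
def test_distributions_valid_for_random_inputs(seed):
    vocab = Vocabulary()
    model = StudentModel(
        StudentConfig(num_layers=1, hidden_dim=16, num_heads=2,
                      feedforward_dim=32, vocab_size=vocab.size), seed=3)
    (ts,) = random_token_sequences(1, vocab, np.random.default_rng(seed))
    dists = model.encode(ts).dists
    assert np.allclose(dists.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(dists > 0)


def test_eval_forward_is_deterministic(tiny_model, vocab):
    (ts,) = random_token_sequences(1, vocab, np.random.default_rng(1))
    a, b = tiny_model.encode(ts), tiny_model.encode(ts)
    assert np.array_equal(a.hidden, b.hidden)
    assert np.array_equal(a.dists, b.dists)


def test_position_sensitivity(tiny_model, vocab):
    # swapping two distinct tokens changes the hidden rows at those positions
    toks = list(range(10))
    ts1 = TokenSequence("a", tuple(toks), 10)
    toks[2], toks[7] = toks[7], toks[2]
    ts2 = TokenSequence("a", tuple(toks), 10)
    h1 = tiny_model.encode(ts1).hidden
    h2 = tiny_model.encode(ts2).hidden
    assert not np.allclose(h1[2], h2[2])
    assert not np.allclose(h1[7], h2[7])


def test_over_length_input_rejected(tiny_model):
    ts = TokenSequence("a", tuple([0] * 201), 201)
    with pytest.raises(ValueError, match="max_length"):
        tiny_model.encode(ts)


def test_out_of_vocab_token_rejected(tiny_model):
    with pytest.raises(ValueError, match="vocabulary"):
        tiny_model.forward(np.array([[0, 23]]))


def test_count_parameters_embedding_only_closed_form(vocab):
    cfg = StudentConfig(num_layers=0, hidden_dim=32, num_heads=4,
                        feedforward_dim=64, vocab_size=vocab.size)
    assert count_parameters(cfg) == vocab.size * 32  # tied head: V*d only
    model = StudentModel(cfg, seed=0)
    assert sum(p.data.size for p in model.parameters()) == vocab.size * 32


def test_count_parameters_monotone_in_layers():
    counts = [
        count_parameters(StudentConfig(num_layers=n, hidden_dim=32,
                                       num_heads=4, feedforward_dim=64))
        for n in range(5)
    ]
    assert all(a < b for a, b in zip(counts, counts[1:]))


def test_count_matches_instantiated_model(tiny_config):
    model = StudentModel(tiny_config, seed=0)
    assert count_parameters(tiny_config) == \
        sum(p.data.size for p in model.parameters())


def test_default_depth_is_six_layers():
    assert StudentConfig().num_layers == 6


def test_heads_must_divide_hidden_dim():
    with pytest.raises(ValueError):
        StudentConfig(hidden_dim=30, num_heads=4)


def test_combined_loss_gradient_matches_finite_difference(vocab):
    """Autodiff gradient of the full objective vs central differences."""
    cfg = StudentConfig(num_layers=1, hidden_dim=8, num_heads=2,
                        feedforward_dim=16, vocab_size=vocab.size)
    model = StudentModel(cfg, seed=5)
    rng = np.random.default_rng(5)
    batch = random_token_sequences(2, vocab, rng, min_len=6, max_len=9)
    masked = apply_mask(batch, 0.3, 2, vocab=vocab)
    teacher = rng.dirichlet(np.ones(vocab.size),
                            size=(2, max(len(s) for s in batch)))
    tokens = np.full((2, teacher.shape[1]), vocab.pad_index)
    valid = np.zeros(tokens.shape, dtype=bool)
    for i, s in enumerate(masked.sequences):
        tokens[i, :len(s)] = s.tokens
        valid[i, :len(s)] = True
    loss_cfg = LossConfig(alpha=0.2)

    def objective():
        _, lp = model.forward(tokens, valid)
        l_m = mlm_loss_logprobs(lp, masked.mask_positions, masked.targets)
        l_d = distill_loss_t(teacher, lp, valid)
        return loss_cfg.alpha * l_m + (1 - loss_cfg.alpha) * l_d

    loss = objective()
    loss.backward()
    layer = model.layers[0]
    eps = 1e-6
    check_rng = np.random.default_rng(0)
    for param in (model.embedding, layer["wq"], layer["wf"], model.rel_bias):
        flat = param.data.reshape(-1)
        gflat = param.grad.reshape(-1)
        for idx in check_rng.choice(flat.size, size=5, replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            fp = objective().item()
            flat[idx] = orig - eps
            fm = objective().item()
            flat[idx] = orig
            num = (fp - fm) / (2 * eps)
            denom = max(abs(num), abs(gflat[idx]), 1e-8)
            assert abs(num - gflat[idx]) / denom < 1e-4


def test_checkpoint_round_trip(tmp_path, tiny_model, vocab):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_model, extra={"note": {"epoch": 3}})
    loaded, extra = load_checkpoint(path, vocab)
    for a, b in zip(tiny_model.parameters(), loaded.parameters()):
        assert np.array_equal(a.data, b.data)
    assert loaded.config == tiny_model.config
    assert extra["note"] == {"epoch": 3}


def test_checkpoint_refuses_vocabulary_mismatch(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_model)
    other = Vocabulary(tokens=tuple(reversed(Vocabulary().tokens)))
    with pytest.raises(ValueError, match="vocabulary"):
        load_checkpoint(path, other)
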