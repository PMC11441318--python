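import numpy as np
import pytest
from hypothesis import given, strategies as st

from protdistill.autodiff import constant
from protdistill.losses import (LossConfig, combined_loss, distill_loss,
                                distill_loss_t, kl_divergence_rows, mlm_loss,
                                mlm_loss_logprobs)
from protdistill.masking import MaskedBatch
from protdistill.sequence_io import TokenSequence


# -- independent naive oracles ---------------------------------------------------


def naive_mlm(log_dists, positions, targets):
    """Double loop over scored positions: -(1/M) sum log p(y_i)."""
    total, count = 0.0, 0
    for lp, pos, tgt in zip(log_dists, positions, targets):
        for p, t in zip(pos, tgt):
            total += -lp[p][t]
            count += 1
    return total / count


def naive_kl(p_rows, q_rows):
    """Per-position sum_j p*(ln p - ln q), then mean over positions."""
    acc = []
    for p_row, q_row in zip(p_rows, q_rows):
        s = 0.0
        for pj, qj in zip(p_row, q_row):
            if pj > 0:
                s += pj * (np.log(pj) - np.log(qj))
        acc.append(s)
    return float(np.mean(acc))


def _random_instance(rng, n_max=10, v_max=5):
    n = int(rng.integers(1, n_max + 1))
    v = int(rng.integers(2, v_max + 1))
    student = rng.dirichlet(np.ones(v), size=n)
    teacher = rng.dirichlet(np.ones(v), size=n)
    n_masked = int(rng.integers(1, n + 1))
    pos = np.sort(rng.choice(n, size=n_masked, replace=False))
    tgt = rng.integers(0, v, size=n_masked)
    return student, teacher, pos, tgt


def _masked_stub(n, pos, tgt):
    ts = TokenSequence("s", tuple([0] * n), n)
    return MaskedBatch((ts,), (tuple(int(p) for p in pos),),
                       (tuple(int(t) for t in tgt),), 0)


def test_losses_match_naive_loop_oracles_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        student, teacher, pos, tgt = _random_instance(rng)
        lp = np.log(student)
        masked = _masked_stub(student.shape[0], pos, tgt)
        assert mlm_loss(lp, masked) == pytest.approx(
            naive_mlm([lp], [pos], [tgt]), abs=1e-6)
        assert distill_loss(teacher, lp) == pytest.approx(
            naive_kl(teacher, student), abs=1e-6)


def test_mlm_perfect_prediction_gives_zero():
    # probability 1 on the true token at every masked position
    lp = np.full((4, 3), -np.inf)
    lp[:, 1] = 0.0  # log 1
    masked = _masked_stub(4, [0, 2], [1, 1])
    assert mlm_loss(lp, masked) == 0.0


def test_mlm_uniform_binary_vocabulary_is_ln2():
    lp = np.log(np.full((1, 2), 0.5))
    masked = _masked_stub(1, [0], [1])
    assert mlm_loss(lp, masked) == pytest.approx(np.log(2), abs=1e-12)


def test_mlm_zero_masked_positions_is_an_error():
    lp = np.zeros((3, 2))
    ts = TokenSequence("s", (0, 0, 0), 3)
    masked = MaskedBatch((ts,), ((),), ((),), 0)
    with pytest.raises(ValueError, match="zero scored"):
        mlm_loss(lp, masked)


def test_mlm_scored_all_positions_option():
    rng = np.random.default_rng(5)
    student = rng.dirichlet(np.ones(3), size=4)
    lp = np.log(student)
    ts = TokenSequence("s", (0, 1, 2, 1), 4)
    masked = MaskedBatch((ts,), ((1,),), ((1,),), 0)
    expected = naive_mlm([lp], [range(4)], [(0, 1, 2, 1)])
    assert mlm_loss(lp, masked, scored="all") == pytest.approx(expected)


def test_kl_identical_distributions_is_zero():
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(5), size=7)
    assert distill_loss(p, np.log(p)) == pytest.approx(0.0, abs=1e-12)


def test_kl_hand_value_two_symbol():
    p = np.array([[0.75, 0.25]])
    q = np.array([[0.5, 0.5]])
    assert distill_loss(p, np.log(q)) == pytest.approx(0.130812, abs=1e-6)


def test_kl_zero_student_support_is_infinite():
    p = np.array([[0.5, 0.5]])
    with np.errstate(divide="ignore"):
        q_log = np.log(np.array([[1.0, 0.0]]))
    assert np.isinf(distill_loss(p, q_log))
    report = combined_loss(1.0, distill_loss(p, q_log))
    assert report.distill_overflow


def test_kl_zero_teacher_mass_contributes_nothing():
    p = np.array([[1.0, 0.0]])
    q = np.array([[0.7, 0.3]])
    assert distill_loss(p, np.log(q)) == pytest.approx(np.log(1 / 0.7))


@given(st.integers(0, 10_000))
def test_kl_nonnegative_random_pairs(seed):
    rng = np.random.default_rng(seed)
    v = int(rng.integers(2, 8))
    p = rng.dirichlet(np.ones(v), size=3)
    q = rng.dirichlet(np.ones(v), size=3)
    val = distill_loss(p, np.log(q))
    assert val >= 0.0
    # zero iff equal (within tolerance)
    if val < 1e-12:
        assert np.allclose(p, q)


def test_distill_positions_subset():
    rng = np.random.default_rng(9)
    p = rng.dirichlet(np.ones(4), size=6)
    q = rng.dirichlet(np.ones(4), size=6)
    sub = [1, 4]
    expected = naive_kl(p[sub], q[sub])
    assert distill_loss(p, np.log(q), positions=sub) == pytest.approx(expected)


def test_differentiable_paths_equal_numpy_values():
    rng = np.random.default_rng(3)
    student = rng.dirichlet(np.ones(5), size=(2, 6))
    teacher = rng.dirichlet(np.ones(5), size=(2, 6))
    lp_t = constant(np.log(student))
    mask = np.ones((2, 6), dtype=bool)
    t_val = distill_loss_t(teacher, lp_t, mask).item()
    n_val = np.mean([naive_kl(teacher[i], student[i]) for i in range(2)])
    assert t_val == pytest.approx(n_val, abs=1e-9)
    pos = [(0, 3), (2,)]
    tgt = [(1, 2), (4,)]
    m_val = mlm_loss_logprobs(lp_t, pos, tgt).item()
    assert m_val == pytest.approx(
        naive_mlm(np.log(student), pos, tgt), abs=1e-9)


def test_combined_loss_boundaries_and_mixture():
    assert combined_loss(1.0, 0.5, LossConfig(alpha=1.0)).l_total == 1.0
    assert combined_loss(1.0, 0.5, LossConfig(alpha=0.0)).l_total == 0.5
    report = combined_loss(1.0, 0.5, LossConfig(alpha=0.2))
    assert report.l_total == pytest.approx(0.6, abs=1e-12)
    assert report.l_total == pytest.approx(
        0.2 * report.l_mlm + 0.8 * report.l_distill, abs=1e-9)


@given(st.floats(0, 1), st.floats(0, 5), st.floats(0, 5), st.floats(0, 5))
def test_combined_loss_linear_and_monotone(alpha, a, b, delta):
    cfg = LossConfig(alpha=alpha)
    base = combined_loss(a, b, cfg).l_total
    assert combined_loss(a + delta, b, cfg).l_total >= base - 1e-12
    assert combined_loss(a, b + delta, cfg).l_total >= base - 1e-12
    # linearity in each argument
    assert combined_loss(2 * a, b, cfg).l_total - base == pytest.approx(
        alpha * a, abs=1e-9)


def test_alpha_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        LossConfig(alpha=1.2)


def test_default_alpha_is_selected_best():
    assert LossConfig().alpha == 0.2
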