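"""Loss formulas checked against independent brute-force oracles and their
closed-form special cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leopard import (
    LossWeights,
    contrastive_loss,
    cosine_sim,
    masked_reconstruction_loss,
    ntxent,
    representation_loss,
    total_loss,
)
from leopard.errors import ConfigError, DataError, NumericError
from leopard.objectives import adversarial_loss, d_step_loss, g_step_loss, mse


# -------------------------------------------------------- brute-force oracles


def oracle_cosine(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def oracle_ntxent(z, pairs, tau):
    """Literal per-anchor evaluation with an explicit double loop."""
    z = np.asarray(z, float)
    n = z.shape[0]
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    losses = []
    for i in range(n):
        num = np.exp(oracle_cosine(z[i], z[partner[i]]) / tau)
        den = sum(np.exp(oracle_cosine(z[i], z[k]) / tau)
                  for k in range(n) if k != i)
        losses.append(-np.log(num / den))
    return float(np.mean(losses))


# ------------------------------------------------------------------- cosine


def test_cosine_trivials(rng):
    a = rng.normal(size=8)
    assert cosine_sim(a, a) == pytest.approx(1.0)
    assert cosine_sim(a, -a) == pytest.approx(-1.0)
    assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)
    with pytest.raises(NumericError):
        cosine_sim(a, np.zeros(8))


# ------------------------------------------------------------------- NT-Xent


def test_ntxent_single_pair_is_exactly_zero(rng):
    z = rng.normal(size=(2, 16))
    assert ntxent(z, [(0, 1)], tau=0.05) == 0.0


def test_ntxent_orthogonal_pairs_closed_form():
    z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
    expected = -np.log(np.e / (np.e + 2.0))
    assert ntxent(z, [(0, 1), (2, 3)], tau=1.0) == pytest.approx(expected,
                                                                 rel=1e-12)


def test_ntxent_identical_embeddings_is_log3():
    z = np.ones((4, 5))
    assert ntxent(z, [(0, 1), (2, 3)], tau=0.5) == pytest.approx(np.log(3.0),
                                                                 rel=1e-12)


def test_ntxent_matches_brute_force_oracle(rng):
    for _ in range(30):
        n_pairs = rng.integers(2, 6)
        d = rng.integers(2, 10)
        tau = float(rng.uniform(0.05, 2.0))
        z = rng.normal(size=(2 * n_pairs, d))
        order = rng.permutation(2 * n_pairs)
        pairs = [(int(order[2 * i]), int(order[2 * i + 1]))
                 for i in range(n_pairs)]
        assert ntxent(z, pairs, tau) == pytest.approx(
            oracle_ntxent(z, pairs, tau), rel=1e-10)


def test_ntxent_scale_invariance(rng):
    z = rng.normal(size=(6, 8))
    pairs = [(0, 1), (2, 3), (4, 5)]
    assert ntxent(z, pairs, 0.1) == pytest.approx(ntxent(3.7 * z, pairs, 0.1),
                                                  rel=1e-10)


def test_ntxent_decreases_when_positive_similarity_rises():
    base = np.array([[1.0, 0.0], [0.6, 0.8], [0.0, 1.0], [-1.0, 0.2]])
    tighter = base.copy()
    tighter[1] = [0.99, np.sqrt(1 - 0.99**2)]  # pull positive partner closer
    pairs = [(0, 1), (2, 3)]
    assert ntxent(tighter, pairs, 0.5) < ntxent(base, pairs, 0.5)


def test_ntxent_validation_errors(rng):
    z = rng.normal(size=(4, 3))
    with pytest.raises(ConfigError):
        ntxent(z, [(0, 1), (1, 2)], 0.5)  # index in two pairs
    with pytest.raises(ConfigError):
        ntxent(z, [(0, 1), (2, 3)], -1.0)


# ----------------------------------------------------- composite contrastive


def test_contrastive_loss_is_mean_of_kinds(rng):
    zc = rng.normal(size=(4, 8))
    zt = rng.normal(size=(4, 8))
    pairs = [(0, 1), (2, 3)]
    expected = (oracle_ntxent(zc, pairs, 0.05) +
                oracle_ntxent(zt, pairs, 0.05)) / 2
    assert contrastive_loss(zc, pairs, zt, pairs, 0.05) == pytest.approx(
        expected, rel=1e-10)


def test_representation_loss_arithmetic(rng):
    a = rng.normal(size=(5, 4))
    b = rng.normal(size=(5, 4))
    c = rng.normal(size=(3, 4))
    d = rng.normal(size=(3, 4))
    expected = (np.mean((a - b) ** 2) + np.mean((c - d) ** 2)) / 2
    assert representation_loss(a, b, c, d) == pytest.approx(expected, rel=1e-12)
    assert representation_loss(a, a, c, c) == 0.0
    with pytest.raises(ConfigError):
        representation_loss(a, b, c, d[:2])


# -------------------------------------------------------- masked reconstruction


def test_masked_reconstruction_trivials(rng):
    actual = rng.normal(size=(4, 3))
    assert masked_reconstruction_loss(actual, actual.copy()) == 0.0
    # mean-encoded cell excluded: deviation there contributes nothing
    mask = np.zeros((1, 2), bool)
    mask[0, 1] = True
    assert masked_reconstruction_loss(np.array([[1.0, 2.0]]),
                                      np.array([[1.0, 5.0]]), mask) == 0.0


def test_masked_reconstruction_matches_cell_loop(rng):
    for _ in range(20):
        shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
        actual = rng.normal(size=shape)
        recon = rng.normal(size=shape)
        mask = rng.random(shape) < 0.3
        if mask.all():
            mask[0, 0] = False
        total, count = 0.0, 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                if not mask[i, j]:
                    total += (actual[i, j] - recon[i, j]) ** 2
                    count += 1
        assert masked_reconstruction_loss(actual, recon, mask) == pytest.approx(
            total / count, rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**16), scale=st.floats(-100, 100))
def test_masked_cells_never_influence_loss(seed, scale):
    rng = np.random.default_rng(seed)
    actual = rng.normal(size=(5, 4))
    recon = rng.normal(size=(5, 4))
    mask = rng.random((5, 4)) < 0.4
    if mask.all():
        mask[0, 0] = False
    perturbed_actual = actual + np.where(mask, scale, 0.0)
    perturbed_recon = recon + np.where(mask, -scale * 2, 0.0)
    assert masked_reconstruction_loss(actual, recon, mask) == \
        masked_reconstruction_loss(perturbed_actual, perturbed_recon, mask)


def test_all_cells_masked_is_data_error():
    with pytest.raises(DataError):
        masked_reconstruction_loss(np.ones((2, 2)), np.ones((2, 2)),
                                   np.ones((2, 2), bool))


# ------------------------------------------------------------- adversarial


def test_adversarial_trivials():
    scores = {("v1", "t1"): (np.array([1.0]), np.array([0.0]))}
    assert adversarial_loss(scores, "discriminator-step", ("v1", "t1")) == 0.0
    scores = {("v1", "t1"): (None, np.array([1.0]))}
    assert adversarial_loss(scores, "generator-step", ("v1", "t1")) == 0.0
    scores = {("v1", "t1"): (np.array([0.5]), np.array([0.5]))}
    assert adversarial_loss(scores, "discriminator-step",
                            ("v1", "t1")) == pytest.approx(0.5)
    with pytest.raises(ConfigError):
        adversarial_loss(scores, "discriminator-step", ("v9", "t9"))


def test_d_and_g_step_forms(rng):
    real = rng.random(6)
    fake = rng.random(6)
    assert d_step_loss(real, fake) == pytest.approx(
        np.mean((real - 1) ** 2) + np.mean(fake**2))
    assert g_step_loss(fake) == pytest.approx(np.mean((fake - 1) ** 2))


# ------------------------------------------------------------------ totals


def test_total_loss_default_weights_example():
    comps = {"rec": 0.2, "con": 0.5, "rep": 0.3, "adv": 0.1}
    assert total_loss(comps, LossWeights()) == pytest.approx(0.38)


def test_total_loss_zero_cases():
    zeros = {"rec": 0.0, "con": 0.0, "rep": 0.0, "adv": 0.0}
    assert total_loss(zeros, LossWeights()) == 0.0
    comps = {"rec": 5.0, "con": 2.0, "rep": 9.0, "adv": 1.0}
    assert total_loss(comps, LossWeights(0, 0, 0, 0)) == 0.0


def test_total_loss_linear_in_each_component(rng):
    w = LossWeights(*rng.uniform(0.1, 2.0, size=4))
    base = {k: float(rng.uniform(0, 2)) for k in ("rec", "con", "rep", "adv")}
    for key, weight in zip(("rec", "con", "rep", "adv"),
                           (w.w_rec, w.w_con, w.w_rep, w.w_adv)):
        bumped = dict(base)
        bumped[key] += 1.0
        assert total_loss(bumped, w) - total_loss(base, w) == pytest.approx(
            weight, rel=1e-12)


def test_total_loss_rejects_non_finite():
    comps = {"rec": np.nan, "con": 0.0, "rep": 0.0, "adv": 0.0}
    with pytest.raises(NumericError):
        total_loss(comps, LossWeights())


def test_mse_matches_numpy(rng):
    a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
    assert mse(a, b) == pytest.approx(np.mean((a - b) ** 2), rel=1e-12)
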