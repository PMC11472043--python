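"""Network contract: activation ranges, determinism, splits, training
behaviour and small-scale distribution-parameter consistency."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import guidepost as gp
from guidepost.network import (DataError, OffTargetNetwork, ShapeError,
                               head_loss, split_dataset)
from guidepost.distributions import ZINBParams, zinb_nll


def _random_features(n, seed):
    rng = np.random.default_rng(seed)
    xs = (rng.random((n, 6, 23)) > 0.5).astype(float)
    xp = rng.random((n, 4, 23))
    return xs, xp


def test_forward_output_ranges_and_determinism():
    net = OffTargetNetwork(gp.NetworkConfig.compact(), "zinb", seed=0)
    net.set_training(False)
    xs, xp = _random_features(7, 1)
    model = gp.TrainedModel(network=net, head="zinb",
                            net_config=gp.NetworkConfig.compact(),
                            train_config=gp.TrainConfig())
    params = model.predict_params(xs, xp)
    assert np.all((params.pi >= 0) & (params.pi <= 1))
    assert np.all(params.mu > 0) and np.all(params.theta > 0)
    params2 = model.predict_params(xs, xp)
    assert np.array_equal(params.pi, params2.pi)
    assert np.array_equal(params.mu, params2.mu)


def test_zeroed_heads_give_neutral_parameters():
    """sigmoid(0)=0.5 and exp(0)=1 when the head layer is zeroed."""
    net = OffTargetNetwork(gp.NetworkConfig.compact(), "zinb", seed=0)
    net.heads.weight.data[:] = 0.0
    net.heads.bias.data[:] = 0.0
    net.set_training(False)
    model = gp.TrainedModel(network=net, head="zinb",
                            net_config=gp.NetworkConfig.compact(),
                            train_config=gp.TrainConfig())
    xs, xp = _random_features(3, 2)
    params = model.predict_params(xs, xp)
    assert np.allclose(params.pi, 0.5)
    assert np.allclose(params.mu, 1.0)
    assert np.allclose(params.theta, 1.0)


def test_forward_shape_errors():
    net = OffTargetNetwork(gp.NetworkConfig.compact(), "zinb", seed=0)
    with pytest.raises(ShapeError):
        net.forward(np.zeros((2, 5, 23)), np.zeros((2, 4, 23)))


def test_head_loss_matches_distribution_module():
    """The autograd NLL agrees with the closed-form numpy NLL."""
    rng = np.random.default_rng(3)
    n = 40
    raw = gp.nn.Tensor(rng.normal(size=(n, 3)))
    y = rng.integers(0, 20, n).astype(float)
    loss = float(head_loss("zinb", raw, y).data)
    pi = 1 / (1 + np.exp(-raw.data[:, 0]))
    mu = np.exp(raw.data[:, 1])
    theta = np.exp(raw.data[:, 2])
    expected = zinb_nll(ZINBParams(pi, mu, theta), y) / n
    assert loss == pytest.approx(expected, rel=1e-9)


def test_split_sizes_and_multiset_equality():
    tr, va, te = split_dataset(1000, (0.70, 0.20, 0.10), seed=5)
    assert (len(tr), len(va), len(te)) == (700, 200, 100)
    assert sorted(np.concatenate([tr, va, te]).tolist()) == list(range(1000))
    tr2, va2, te2 = split_dataset(10, (1.0, 0.0, 0.0), seed=5)
    assert len(tr2) == 10 and len(va2) == 0 and len(te2) == 0
    with pytest.raises(DataError):
        split_dataset(10, (0.5, 0.2, 0.2), seed=1)


def test_training_loss_decreases_and_is_reproducible(sim_world):
    xs, xp, y = sim_world["xs"][:600], sim_world["xp"][:600], sim_world["y"][:600]
    cfg = gp.TrainConfig(learning_rate=1e-3, max_epochs=3,
                         early_stopping_patience=3, seed=7)
    m1 = gp.train((xs, xp, y), cfg, head="zinb",
                  net_config=gp.NetworkConfig.compact())
    assert m1.history["train_loss"][-1] < m1.history["train_loss"][0]
    m2 = gp.train((xs, xp, y), cfg, head="zinb",
                  net_config=gp.NetworkConfig.compact())
    assert m1.history["monitor_loss"] == m2.history["monitor_loss"]


def test_training_without_covariate_signal_recovers_marginal_zinb():
    """MLE consistency: with no covariate signal the average predicted
    (pi, mean) approach the generating values."""
    true = ZINBParams(0.35, 40.0, 1.5)
    n = 3000
    y = gp.zinb_sample(true, n, seed=21).astype(float)
    xs, xp = _random_features(n, 22)
    cfg = gp.TrainConfig(learning_rate=1e-3, max_epochs=30,
                         early_stopping_patience=30, seed=23,
                         split_fractions=(0.9, 0.1, 0.0))
    model = gp.train((xs, xp, y), cfg, head="zinb",
                     net_config=gp.NetworkConfig.compact())
    params = model.predict_params(xs, xp)
    mean_pred = float(np.mean((1 - params.pi) * params.mu))
    mean_true = (1 - true.pi) * true.mu
    assert mean_pred == pytest.approx(mean_true, rel=0.10)
    assert float(np.mean(params.pi)) == pytest.approx(true.pi, abs=0.10)


def test_predicted_mean_tracks_truth_on_shared_world(sim_world, trained_zinb):
    """Smoke-scale parameter recovery on the shared synthetic dataset."""
    params = trained_zinb.predict_params(sim_world["xs"], sim_world["xp"])
    mean_pred = (1 - params.pi) * params.mu
    sc = sim_world["sidecar"]
    mean_true = ((1 - sc["pi_true"]) * sc["mu_true"]).to_numpy()
    rho = spearmanr(mean_true, mean_pred).statistic
    assert rho > 0.6


def test_empty_dataset_raises():
    with pytest.raises(DataError):
        gp.train((np.zeros((0, 6, 23)), np.zeros((0, 4, 23)), np.zeros(0)),
                 gp.TrainConfig(), head="zinb")
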