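"""The CNN + bi-LSTM fusion regressor mapping interface features to
count-distribution parameters, with its training loop.

The sequence branch runs the 6 x 23 interface matrix through two
convolution stages (128 kernels of width 1, then 32 of width 3, each
batch-normalized and rectified), max-pools with window 2 / stride 2, feeds
the result to a bi-directional LSTM (128 hidden units per direction) and
projects the concatenated final states to 128 units.  The descriptor branch
runs the 4 x 23 matrix through one rectified convolution stage and a
128-unit projection.  The two 128-d encodings are concatenated (256-d),
passed through a 64-unit joint layer, and read out by one scalar head per
distribution parameter: sigmoid for the zero-inflation weight pi,
exponential for the mean mu and dispersion theta (clamped to keep the
likelihood finite).

Alternative heads (``zip``, ``nb``, ``poisson``) share the same trunk and
differ only in the number of outputs and the likelihood they optimize; they
serve as ablation baselines for the full zero-inflated negative binomial
head.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln as _gammaln

from . import distributions as dist
from .distributions import ZINBParams
from .nn.autograd import Tensor, concat, max_pool1d
from .nn.layers import Adam, BatchNorm1d, BiLSTM, Conv1d, Dense, Module

HEADS = ("zinb", "zip", "nb", "poisson")
_HEAD_OUTPUTS = {"zinb": 3, "zip": 2, "nb": 2, "poisson": 1}

_LOG_PARAM_MIN = np.log(dist.PARAM_MIN)
_LOG_PARAM_MAX = np.log(dist.PARAM_MAX)


class ShapeError(ValueError):
    pass


class DataError(ValueError):
    pass


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class NetworkConfig:
    """Layer sizes of the two-branch architecture."""

    conv1_kernels: int = 128
    conv2_kernels: int = 32
    conv1_width: int = 1
    conv2_width: int = 3
    lstm_hidden: int = 128
    fc_seq: int = 128
    phys_kernels: int = 32
    phys_width: int = 3
    fc_phys: int = 128
    fc_joint: int = 64

    @classmethod
    def default(cls) -> "NetworkConfig":
        return cls()

    @classmethod
    def compact(cls) -> "NetworkConfig":
        """A scaled-down preset with the same topology, for CPU-sized runs."""
        return cls(conv1_kernels=16, conv2_kernels=8, lstm_hidden=16,
                   fc_seq=32, phys_kernels=8, fc_phys=32, fc_joint=16)


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, early stopping on the monitored loss."""

    learning_rate: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 500
    early_stopping_patience: int = 50
    split_fractions: Tuple[float, float, float] = (0.70, 0.20, 0.10)
    monitor: str = "val"  # "val" or "train"
    seed: int = 0


class OffTargetNetwork(Module):
    """The fusion trunk plus one distribution head."""

    def __init__(self, config: NetworkConfig, head: str, seed: int):
        super().__init__()
        if head not in HEADS:
            raise ValueError(f"unknown head {head!r}; expected one of {HEADS}")
        self.config = config
        self.head = head
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = Conv1d(rng, 6, c.conv1_kernels, c.conv1_width)
        self.bn1 = BatchNorm1d(c.conv1_kernels)
        self.conv2 = Conv1d(rng, c.conv1_kernels, c.conv2_kernels, c.conv2_width)
        self.bn2 = BatchNorm1d(c.conv2_kernels)
        self.lstm = BiLSTM(rng, c.conv2_kernels, c.lstm_hidden)
        self.fc_seq = Dense(rng, 2 * c.lstm_hidden, c.fc_seq)
        self.phys_conv = Conv1d(rng, 4, c.phys_kernels, c.phys_width)
        self.phys_bn = BatchNorm1d(c.phys_kernels)
        self.fc_phys = Dense(rng, c.phys_kernels * 23, c.fc_phys)
        self.fc_joint = Dense(rng, c.fc_seq + c.fc_phys, c.fc_joint)
        self.heads = Dense(rng, c.fc_joint, _HEAD_OUTPUTS[head])

    def forward(self, xs: np.ndarray, xp: np.ndarray) -> Tensor:
        """Raw head outputs (B, n_heads) before activations."""
        xs = np.asarray(xs, dtype=np.float64)
        xp = np.asarray(xp, dtype=np.float64)
        if xs.ndim == 2:
            xs = xs[None]
        if xp.ndim == 2:
            xp = xp[None]
        if xs.shape[1:] != (6, 23) or xp.shape[1:] != (4, 23):
            raise ShapeError(f"expected (B,6,23) and (B,4,23), got {xs.shape} and {xp.shape}")
        ts = Tensor(xs)
        tp = Tensor(xp)
        h = self.bn1(self.conv1(ts)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = max_pool1d(h, 2, 2)                    # (B, C2, 11)
        h = h.transpose((0, 2, 1))                 # (B, 11, C2)
        e_s = self.fc_seq(self.lstm(h)).relu()     # (B, fc_seq)
        p = self.phys_bn(self.phys_conv(tp)).relu()
        B = p.data.shape[0]
        e_p = self.fc_phys(p.reshape(B, -1)).relu()
        e_total = concat([e_s, e_p], axis=1)
        joint = self.fc_joint(e_total).relu()
        return self.heads(joint)


def _activate(head: str, raw: Tensor) -> Dict[str, Tensor]:
    """Map raw head outputs to constrained distribution parameters."""
    cols = {}
    if head == "zinb":
        cols["pi_logit"] = raw[(slice(None), 0)]
        cols["mu"] = raw[(slice(None), 1)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
        cols["theta"] = raw[(slice(None), 2)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
    elif head == "zip":
        cols["pi_logit"] = raw[(slice(None), 0)]
        cols["mu"] = raw[(slice(None), 1)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
    elif head == "nb":
        cols["mu"] = raw[(slice(None), 0)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
        cols["theta"] = raw[(slice(None), 1)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
    else:  # poisson
        cols["mu"] = raw[(slice(None), 0)].clamp(_LOG_PARAM_MIN, _LOG_PARAM_MAX).exp()
    return cols


def _nb_log_pmf_t(y: np.ndarray, mu: Tensor, theta: Tensor) -> Tensor:
    """NB log pmf as an autograd expression (y constant)."""
    yt = Tensor(y)
    mt = mu + theta
    return ((yt + theta).lgamma() - theta.lgamma() - Tensor(_gammaln(y + 1.0))
            + yt * (mu.log() - mt.log()) + theta * (theta.log() - mt.log()))


def _logsumexp2(a: Tensor, b: Tensor) -> Tensor:
    m = a.maximum(b)
    return m + ((a - m).exp() + (b - m).exp()).log()


def head_loss(head: str, raw: Tensor, y: np.ndarray) -> Tensor:
    """Mean negative log likelihood of the selected head on a batch."""
    y = np.round(np.asarray(y, dtype=np.float64))
    cols = _activate(head, raw)
    if head == "zinb":
        mu, theta = cols["mu"], cols["theta"]
        nb = _nb_log_pmf_t(y, mu, theta)
        s = cols["pi_logit"]
        log_pi = -((-s).softplus())          # log pi   = log sigmoid(s)
        log_1m_pi = -(s.softplus())          # log(1-pi)
        zero = (y == 0).astype(np.float64)
        zero_term = _logsumexp2(log_pi, log_1m_pi + nb)
        pos_term = log_1m_pi + nb
        ll = Tensor(zero) * zero_term + Tensor(1.0 - zero) * pos_term
    elif head == "zip":
        lam = cols["mu"]
        s = cols["pi_logit"]
        pois = Tensor(y) * lam.log() - lam - Tensor(_gammaln(y + 1.0))
        log_pi = -((-s).softplus())
        log_1m_pi = -(s.softplus())
        zero = (y == 0).astype(np.float64)
        zero_term = _logsumexp2(log_pi, log_1m_pi + pois)
        ll = Tensor(zero) * zero_term + Tensor(1.0 - zero) * (log_1m_pi + pois)
    elif head == "nb":
        ll = _nb_log_pmf_t(y, cols["mu"], cols["theta"])
    else:
        lam = cols["mu"]
        ll = Tensor(y) * lam.log() - lam - Tensor(_gammaln(y + 1.0))
    return -(ll.mean())


def split_dataset(n_or_dataset, fractions: Sequence[float], seed: int):
    """Random permutation split into (train, val, test) index arrays.

    Sizes are floor-based with the remainder assigned to train, so 1000
    records at 0.70/0.20/0.10 give exactly 700/200/100.  Accepts either a
    record count or a sized dataset.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise DataError("fractions must be three nonnegative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError(f"fractions must sum to 1, got {sum(fractions)}")
    n = n_or_dataset if isinstance(n_or_dataset, (int, np.integer)) else len(n_or_dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reapply it: weights,
    normalization statistics, config snapshot and provenance metadata."""

    network: OffTargetNetwork
    head: str
    net_config: NetworkConfig
    train_config: TrainConfig
    norm_stats: Optional[dict] = None       # descriptor min/max, as dict
    count_scale: float = 1.0                # counts-to-activity-frequency divisor
    metadata: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    def predict_raw(self, xs: np.ndarray, xp: np.ndarray, batch_size: int = 512) -> np.ndarray:
        self.network.set_training(False)
        xs = np.asarray(xs, dtype=np.float64)
        xp = np.asarray(xp, dtype=np.float64)
        if xs.ndim == 2:
            xs, xp = xs[None], xp[None]
        outs = []
        for i in range(0, xs.shape[0], batch_size):
            outs.append(self.network.forward(xs[i:i + batch_size], xp[i:i + batch_size]).data)
        return np.concatenate(outs, axis=0)

    def predict_params(self, xs: np.ndarray, xp: np.ndarray) -> ZINBParams:
        """Predicted distribution parameters, expressed in the common
        (pi, mu, theta) parameterization.

        Reduced heads embed naturally: plain NB has pi at the numerical
        floor, Poisson-family heads use the large-dispersion limit
        theta = 1e6 (NB -> Poisson).
        """
        raw = self.predict_raw(xs, xp)
        B = raw.shape[0]
        if self.head == "zinb":
            pi = 1.0 / (1.0 + np.exp(-raw[:, 0]))
            mu = np.exp(np.clip(raw[:, 1], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            theta = np.exp(np.clip(raw[:, 2], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
        elif self.head == "zip":
            pi = 1.0 / (1.0 + np.exp(-raw[:, 0]))
            mu = np.exp(np.clip(raw[:, 1], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            theta = np.full(B, dist.PARAM_MAX)
        elif self.head == "nb":
            pi = np.full(B, dist.PI_EPS)
            mu = np.exp(np.clip(raw[:, 0], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            theta = np.exp(np.clip(raw[:, 1], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
        else:
            pi = np.full(B, dist.PI_EPS)
            mu = np.exp(np.clip(raw[:, 0], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            theta = np.full(B, dist.PARAM_MAX)
        pi, mu, theta = dist.clamp_params(pi, mu, theta)
        return ZINBParams(pi, mu, theta)

    def test_nll(self, xs: np.ndarray, xp: np.ndarray, y: np.ndarray) -> float:
        """Head-exact mean NLL per observation on a labeled set."""
        raw = self.predict_raw(xs, xp)
        y = np.round(np.asarray(y, dtype=np.float64))
        if self.head == "zinb":
            p = self.predict_params(xs, xp)
            return dist.zinb_nll(p, y) / y.size
        if self.head == "zip":
            pi = 1.0 / (1.0 + np.exp(-raw[:, 0]))
            lam = np.exp(np.clip(raw[:, 1], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            return dist.zip_nll(pi, lam, y) / y.size
        if self.head == "nb":
            mu = np.exp(np.clip(raw[:, 0], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            theta = np.exp(np.clip(raw[:, 1], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
            return dist.nb_nll(mu, theta, y) / y.size
        lam = np.exp(np.clip(raw[:, 0], _LOG_PARAM_MIN, _LOG_PARAM_MAX))
        return dist.poisson_nll(lam, y) / y.size


def train(dataset, config: TrainConfig, head: str = "zinb",
          net_config: Optional[NetworkConfig] = None,
          norm_stats: Optional[dict] = None,
          count_scale: float = 1.0,
          verbose: bool = False) -> TrainedModel:
    """Fit the selected head by mini-batch Adam with early stopping.

    ``dataset`` is either a tuple of arrays ``(Xs, Xp, y)`` with shapes
    (N,6,23), (N,4,23), (N,), or a sequence of per-site triples.  The split
    into train/val/test follows ``config.split_fractions``; early stopping
    monitors the validation loss (or the training loss when the validation
    split is empty or ``config.monitor == "train"``) and the weights with
    the best monitored loss are returned.  Fully reproducible from
    ``config.seed``.
    """
    if isinstance(dataset, tuple) and len(dataset) == 3:
        xs, xp, y = (np.asarray(a, dtype=np.float64) for a in dataset)
    else:
        xs = np.stack([np.asarray(r[0].matrix if hasattr(r[0], "matrix") else r[0])
                       for r in dataset])
        xp = np.stack([np.asarray(r[1].matrix if hasattr(r[1], "matrix") else r[1])
                       for r in dataset])
        y = np.asarray([float(r[2]) for r in dataset])
    n = y.shape[0]
    if n == 0:
        raise DataError("empty dataset")
    if not (xs.shape[0] == xp.shape[0] == n):
        raise ShapeError("Xs, Xp and y must have equal leading dimension")

    net_config = net_config or NetworkConfig.default()
    idx_train, idx_val, idx_test = split_dataset(n, config.split_fractions, config.seed)
    if idx_train.size == 0:
        raise DataError("empty training split")
    monitor_val = config.monitor == "val" and idx_val.size > 0

    net = OffTargetNetwork(net_config, head, seed=config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    def eval_loss(indices: np.ndarray) -> float:
        net.set_training(False)
        total, count = 0.0, 0
        for i in range(0, indices.size, 1024):
            sl = indices[i:i + 1024]
            raw = net.forward(xs[sl], xp[sl])
            total += float(head_loss(head, raw, y[sl]).data) * sl.size
            count += sl.size
        return total / max(count, 1)

    best_loss = np.inf
    best_state = None
    best_epoch = -1
    history = {"train_loss": [], "monitor_loss": []}
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        net.set_training(True)
        order = rng.permutation(idx_train)
        epoch_loss, seen = 0.0, 0
        for bstart in range(0, order.size, config.batch_size):
            sl = order[bstart:bstart + config.batch_size]
            opt.zero_grad()
            raw = net.forward(xs[sl], xp[sl])
            loss = head_loss(head, raw, y[sl])
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {bstart // config.batch_size}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * sl.size
            seen += sl.size
        train_loss = epoch_loss / seen
        mon = eval_loss(idx_val) if monitor_val else train_loss
        history["train_loss"].append(train_loss)
        history["monitor_loss"].append(mon)
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.4f} monitor {mon:.4f}")
        if mon < best_loss - 1e-12:
            best_loss = mon
            best_state = copy.deepcopy(net.state_arrays())
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
    if best_state is not None:
        net.load_state_arrays(best_state)
    net.set_training(False)
    history["best_epoch"] = best_epoch
    history["best_monitor_loss"] = best_loss
    metadata = {
        "seed": config.seed,
        "head": head,
        "monitor": "val" if monitor_val else "train",
        "n_train": int(idx_train.size),
        "n_val": int(idx_val.size),
        "n_test": int(idx_test.size),
    }
    return TrainedModel(network=net, head=head, net_config=net_config,
                        train_config=config, norm_stats=norm_stats,
                        count_scale=count_scale, metadata=metadata,
                        history=history)
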