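"""The 6-stage 1-D CNN mapping a 500-point variability series to TdP risk.

Architecture (all convolutions: 5 filters, kernel 2, stride 1, no padding;
all activations ReLU except the softmax output):

    stage 1: 4 conv layers, max-pool 2/stride 2, batch norm
    stage 2: 3 conv layers, max-pool 2/stride 2
    stage 3: 2 conv layers, max-pool 2/stride 2
    stage 4: 2 conv layers, max-pool 2/stride 2
    stage 5: 1 conv layer,  max-pool 4/stride 2
    stage 6: 1 conv layer,  max-pool 4/stride 2
    flatten (5 x 5 -> 25) -> dropout 20% -> dense 10 (ReLU) -> dense 3 (softmax)

For input length 500 the stagewise lengths after pooling are
[248, 122, 60, 29, 13, 5], so the flattened feature dimension is exactly
5 time-steps x 5 channels = 25.  Training minimises categorical
cross-entropy with Adam (lr 1e-5), batches of 20, 300 epochs, under
10-fold cross-validation; the retained model is the fold maximising the
mean of training and validation accuracy (ties broken by lower validation
loss).  The network is small enough that plain numpy on one CPU trains it
in minutes; forward/backward passes are implemented here directly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

#: Fixed class-index encoding, persisted with every model.
LABELS: tuple[str, ...] = ("high", "intermediate", "low")
LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class CnnConfig:
    input_length: int = 500
    stage_convs: tuple[int, ...] = (4, 3, 2, 2, 1, 1)
    n_filters: int = 5
    kernel: int = 2
    pool_sizes: tuple[int, ...] = (2, 2, 2, 2, 4, 4)
    pool_stride: int = 2
    hidden_units: int = 10
    dropout: float = 0.2
    n_classes: int = 3
    learning_rate: float = 1e-5
    batch_size: int = 20
    epochs: int = 300
    folds: int = 10
    seed: int = 0


def stage_lengths(config: CnnConfig) -> list[int]:
    """Sequence length after each stage under valid convolution/pooling.

    Each convolution shortens the sequence by kernel-1; each pool maps
    L -> floor((L - pool) / stride) + 1.  Raises if any stage output drops
    below 1, reporting the lengths reached.
    """
    lengths = []
    length = config.input_length
    for n_conv, pool in zip(config.stage_convs, config.pool_sizes):
        length -= n_conv * (config.kernel - 1)
        if length < pool:
            raise ValueError(
                f"input_length {config.input_length} too short: stagewise lengths "
                f"{lengths} then {length} before a pool of {pool}"
            )
        length = (length - pool) // config.pool_stride + 1
        lengths.append(length)
    if length < 1:
        raise ValueError(f"flatten dimension < 1; stagewise lengths {lengths}")
    return lengths


def flatten_dim(config: CnnConfig) -> int:
    return stage_lengths(config)[-1] * config.n_filters


@dataclass(frozen=True)
class TrainingSet:
    """Series matrix (rows = samples), string labels, and drug of origin."""

    x: np.ndarray  # (n, input_length)
    labels: np.ndarray  # (n,) strings from LABELS
    drugs: np.ndarray  # (n,) drug of origin per row

    def __post_init__(self) -> None:
        if len(self.x) != len(self.labels) or len(self.x) != len(self.drugs):
            raise ValueError("x, labels and drugs must align")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown risk labels {bad}")

    @property
    def y(self) -> np.ndarray:
        return np.array([LABEL_TO_INDEX[lab] for lab in self.labels])


# ---------------------------------------------------------------------------
# layers: arrays are (N, L, C); parameters updated in place by Adam


class _Conv1D:
    """Valid 1-D convolution, kernel 2, stride 1.

    ``dirac=True`` uses identity initialization (identity channel map on the
    first tap plus small noise) instead of He initialization; see Cnn1D.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dirac: bool = False,
    ):
        if dirac and c_in == c_out:
            self.w = 0.01 * rng.normal(size=(kernel, c_in, c_out))
            self.w[0] += np.eye(c_in)
        else:
            scale = np.sqrt(2.0 / (kernel * c_in))
            self.w = rng.normal(0.0, scale, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        k = self.kernel
        l_out = x.shape[1] - k + 1
        y = np.broadcast_to(self.b, (x.shape[0], l_out, self.b.size)).copy()
        for j in range(k):
            y += x[:, j : j + l_out, :] @ self.w[j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        l_out = dy.shape[1]
        self.dw = np.empty_like(self.w)
        dx = np.zeros_like(x)
        for j in range(k):
            self.dw[j] = np.tensordot(x[:, j : j + l_out, :], dy, axes=([0, 1], [0, 1]))
            dx[:, j : j + l_out, :] += dy @ self.w[j].T
        self.db = dy.sum(axis=(0, 1))
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool1D:
    def __init__(self, size: int, stride: int):
        self.size, self.stride = size, stride

    def forward(self, x, train):
        n, l_in, c = x.shape
        l_out = (l_in - self.size) // self.stride + 1
        idx = np.arange(l_out)[:, None] * self.stride + np.arange(self.size)[None, :]
        windows = x[:, idx, :]  # (n, l_out, size, c)
        self._arg = windows.argmax(axis=2)
        self._idx = idx
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, dy):
        n, l_out, c = dy.shape
        dx = np.zeros(self._in_shape)
        # absolute input position of each window maximum
        pos = np.arange(l_out)[None, :, None] * self.stride + self._arg
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, None, :]
        np.add.at(dx, (ni, pos, ci), dy)
        return dx

    def params(self):
        return []


class _BatchNorm1D:
    """Per-channel normalization over the batch and time axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[1]
        self.dgamma = (dy * self._xhat).sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)) / m
        ) / self._std

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class Cnn1D:
    """The network; build with :func:`build_cnn`."""

    def __init__(self, config: CnnConfig, rng: np.random.Generator | None = None):
        stage_lengths(config)  # validates the arithmetic
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.conv_layers: list = []
        c_in = 1
        for n_conv, pool in zip(config.stage_convs, config.pool_sizes):
            for _ in range(n_conv):
                # He init where channels are created (stage-1 entry), identity
                # (Dirac) init thereafter: at the tiny configured learning
                # rate the network trains near its initialization, and an
                # identity-initialized deep stack preserves the stage-1
                # feature information (multi-scale max summaries) instead of
                # scrambling it through a narrow random ReLU cascade
                self.conv_layers.append(
                    _Conv1D(
                        c_in, config.n_filters, config.kernel, rng,
                        dirac=c_in == config.n_filters,
                    )
                )
                self.conv_layers.append(_ReLU())
                c_in = config.n_filters
            self.conv_layers.append(_MaxPool1D(pool, config.pool_stride))
            if len([l for l in self.conv_layers if isinstance(l, _MaxPool1D)]) == 1:
                self.conv_layers.append(_BatchNorm1D(config.n_filters))
        self.dropout = _Dropout(config.dropout, rng)
        d_flat = flatten_dim(config)
        self.hidden = _Dense(d_flat, config.hidden_units, rng)
        self.hidden_relu = _ReLU()
        self.out = _Dense(config.hidden_units, config.n_classes, rng)
        # zero-initialised classification head: with the very small learning
        # rate the schedule moves each weight only O(epochs*steps*lr), so a
        # random-scale head would dominate the logits throughout training
        self.out.w[:] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch of series shaped (n, input_length)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.input_length:
            raise ValueError(
                f"series length {x.shape[1]} != configured input_length "
                f"{self.config.input_length}"
            )
        h = x[:, :, None]
        for layer in self.conv_layers:
            h = layer.forward(h, train)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.dropout.forward(h, train)
        h = self.hidden_relu.forward(self.hidden.forward(h, train), train)
        logits = self.out.forward(h, train)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, y_onehot: np.ndarray) -> None:
        n = y_onehot.shape[0]
        d = (self._probs - y_onehot) / n  # softmax + cross-entropy gradient
        d = self.out.backward(d)
        d = self.hidden.backward(self.hidden_relu.backward(d))
        d = self.dropout.backward(d)
        d = d.reshape(self._flat_shape)
        for layer in reversed(self.conv_layers):
            d = layer.backward(d)

    def all_layers(self):
        return self.conv_layers + [self.hidden, self.out]

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.all_layers()):
            for name, arr, _ in layer.params():
                out[f"layer{i}_{name}"] = arr
            if isinstance(layer, _BatchNorm1D):
                out[f"layer{i}_running_mean"] = layer.running_mean
                out[f"layer{i}_running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.all_layers()):
            for name, arr, _ in layer.params():
                arr[...] = state[f"layer{i}_{name}"]
            if isinstance(layer, _BatchNorm1D):
                layer.running_mean[...] = state[f"layer{i}_running_mean"]
                layer.running_var[...] = state[f"layer{i}_running_var"]


class _Adam:
    def __init__(self, net: Cnn1D, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self):
        self.t += 1
        i = 0
        for layer in self.net.all_layers():
            for _, arr, gname in layer.params():
                g = getattr(layer, gname)
                if i not in self.m:
                    self.m[i] = np.zeros_like(arr)
                    self.v[i] = np.zeros_like(arr)
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


@dataclass
class TrainedModel:
    """A retained fold model with its config, label map and training record."""

    config: CnnConfig
    net: Cnn1D
    labels: tuple[str, ...] = LABELS
    fold_record: list[dict] = field(default_factory=list)
    history: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        cfg = asdict(self.config)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=2)
        with open(os.path.join(path, "labels.json"), "w") as fh:
            json.dump(list(self.labels), fh)
        with open(os.path.join(path, "folds.json"), "w") as fh:
            json.dump(self.fold_record, fh, indent=2)
        np.savez(os.path.join(path, "weights.npz"), **self.net.state_arrays())

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(os.path.join(path, "config.json")) as fh:
            cfg = json.load(fh)
        for key in ("stage_convs", "pool_sizes"):
            cfg[key] = tuple(cfg[key])
        config = CnnConfig(**cfg)
        with open(os.path.join(path, "labels.json")) as fh:
            labels = tuple(json.load(fh))
        fold_file = os.path.join(path, "folds.json")
        folds = json.load(open(fold_file)) if os.path.exists(fold_file) else []
        net = Cnn1D(config)
        with np.load(os.path.join(path, "weights.npz")) as state:
            net.load_state_arrays(dict(state))
        return cls(config=config, net=net, labels=labels, fold_record=folds)


def build_cnn(config: CnnConfig) -> Cnn1D:
    """Construct the untrained network, validating the stage arithmetic."""
    return Cnn1D(config)


def assemble_training_set(
    pool, drugs, per_drug: int, seed: int
) -> TrainingSet:
    """Draw ``per_drug`` series per training drug from the variability pool.

    Rows are drawn uniformly without replacement across each drug's full
    (sample x multiplier) pool; reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    xs, labels, names = [], [], []
    for drug in drugs:
        entry = pool.get(drug.name)
        n_avail = entry.values.shape[0]
        if n_avail < per_drug:
            raise ValueError(
                f"drug {drug.name!r} has only {n_avail} series, need {per_drug}"
            )
        idx = rng.choice(n_avail, size=per_drug, replace=False)
        xs.append(entry.values[np.sort(idx)])
        labels.extend([drug.risk] * per_drug)
        names.extend([drug.name] * per_drug)
    return TrainingSet(
        x=np.concatenate(xs, axis=0),
        labels=np.array(labels),
        drugs=np.array(names),
    )


def _accuracy(net: Cnn1D, x: np.ndarray, y: np.ndarray) -> float:
    return float((net.forward(x).argmax(axis=1) == y).mean())


def _loss(net: Cnn1D, x: np.ndarray, y: np.ndarray) -> float:
    p = net.forward(x)
    return float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean())


def _train_one(
    config: CnnConfig, x: np.ndarray, y: np.ndarray, seed: int
) -> tuple[Cnn1D, list[float]]:
    rng = np.random.default_rng(seed)
    net = Cnn1D(config, rng=np.random.default_rng(seed + 1))
    opt = _Adam(net, config.learning_rate)
    n = len(x)
    onehot = np.eye(config.n_classes)[y]
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            p = net.forward(x[sel], train=True)
            eps_p = np.clip(p[np.arange(len(sel)), y[sel]], 1e-12, None)
            epoch_loss += float(-np.log(eps_p).sum())
            net.backward(onehot[sel])
            opt.step()
        losses.append(epoch_loss / n)
    return net, losses


def train(training_set: TrainingSet, config: CnnConfig) -> TrainedModel:
    """K-fold cross-validated training; retains the best fold model.

    Folds stratify by sample label; each fold trains a fresh network for the
    configured schedule and the retained model maximises the mean of
    training and validation accuracy, ties broken by lower validation loss.
    All randomness (fold split, shuffling, initialization, dropout) derives
    from ``config.seed``.
    """
    x, y = training_set.x, training_set.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    best = None
    record = []
    history: dict = {}
    for fold, (tr, va) in enumerate(skf.split(x, y)):
        net, losses = _train_one(config, x[tr], y[tr], seed=config.seed + 1000 * fold)
        acc_tr = _accuracy(net, x[tr], y[tr])
        acc_va = _accuracy(net, x[va], y[va])
        loss_va = _loss(net, x[va], y[va])
        score = 0.5 * (acc_tr + acc_va)
        record.append(
            {
                "fold": fold,
                "train_accuracy": acc_tr,
                "val_accuracy": acc_va,
                "val_loss": loss_va,
                "score": score,
            }
        )
        if best is None or (score, -loss_va) > (best[0], -best[1]):
            best = (score, loss_va, net)
            history = {"loss": losses, "fold": fold}
    return TrainedModel(config=config, net=best[2], fold_record=record, history=history)


def predict(model: TrainedModel, series: np.ndarray) -> np.ndarray:
    """3-class probability vector(s); argmax defines the hard label."""
    p = model.net.forward(np.asarray(series, dtype=float), train=False)
    return p[0] if np.asarray(series).ndim == 1 else p
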