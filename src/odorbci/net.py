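"""End-to-end 1-D residual convolutional decoder, implemented in numpy.

The network maps raw (trials, channels, samples) epochs to a per-trial
probability of odor exposure: a stem convolution followed by four residual
blocks (two convolutions each, stride-2 downsampling once per block, batch
normalization + ReLU, 1x1 skip projection where dimensions change), global
average pooling and a single sigmoid output unit — 1 + 4*2 = 9 convolution
layers. Training minimizes mean binary cross-entropy with AdamW (decoupled
weight decay), a reduce-on-plateau learning-rate schedule (factor 10,
patience 15 epochs on validation loss) and minimum-validation-loss
checkpointing. Optional augmentation adds Gaussian noise, zeroes a
contiguous temporal mask, and applies small temporal shifts.

Everything here is CPU-sized: forward/backward passes are vectorized with
im2col-style strided views; no GPU framework is required or used.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetSpec",
    "TrainSpec",
    "AugmentSpec",
    "ResNet1D",
    "build_net",
    "train_net",
    "augment",
    "predict_proba",
    "TrainingLog",
]


# ---------------------------------------------------------------- specs


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters. The reference configuration is four
    residual blocks of two convolutions each; filters double per block."""

    n_input_channels: int = 4
    n_samples: int = 256
    n_res_blocks: int = 4
    convs_per_block: int = 2
    base_filters: int = 16
    kernel_size: int = 17
    seed: int = 0

    def validate(self) -> None:
        if self.n_input_channels < 1 or self.n_samples < 1:
            raise ValueError("input dimensions must be >= 1")
        if self.n_res_blocks < 1 or self.convs_per_block != 2:
            raise ValueError("architecture requires >= 1 blocks of 2 convolutions")
        min_len = 2 ** self.n_res_blocks
        if self.n_samples < min_len:
            raise ValueError(
                f"n_samples={self.n_samples} too short for {self.n_res_blocks} "
                f"stride-2 blocks; need >= {min_len}")

    @property
    def n_conv_layers(self) -> int:
        """Stem + per-block convolutions (skip projections not counted)."""
        return 1 + self.n_res_blocks * self.convs_per_block

    @property
    def embedding_dim(self) -> int:
        return self.base_filters * 2 ** (self.n_res_blocks - 1)


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 5e-5
    weight_decay: float = 1e-2
    max_epochs: int = 70          # 50 for the sniff trace, 70 for neural data
    batch_size: int = 16
    scheduler_factor: float = 10.0
    scheduler_patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.scheduler_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.scheduler_factor <= 1:
            raise ValueError("scheduler factor must be > 1")


@dataclass(frozen=True)
class AugmentSpec:
    noise_sd: float = 0.1        # fraction of the per-trial SD
    mask_fraction: float = 0.1   # fraction of samples zeroed (contiguous)
    shift_max: float = 0.05      # seconds
    apply_prob: float = 0.5      # per transform, per trial
    sfreq: float = 256.0

    def validate(self) -> None:
        for name in ("noise_sd", "mask_fraction", "apply_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")


# ---------------------------------------------------------------- layers


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Conv1d:
    """Same-padded 1-D convolution, stride 1 or 2, via strided views."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k))  # He initialization
        self.W = _Param(rng.standard_normal((out_ch, in_ch, k)) * scale)
        self.b = _Param(np.zeros(out_ch))
        self.k, self.stride = k, stride
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, L = x.shape
        L_out = (L + self.stride - 1) // self.stride
        pad_total = max((L_out - 1) * self.stride + self.k - L, 0)
        pl, pr = pad_total // 2, pad_total - pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=-1)
        cols = cols[:, :, ::self.stride, :]          # (n, c, L_out, k)
        y = np.einsum("nclk,ock->nol", cols, self.W.value, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, x.shape, (pl, pr))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (pl, pr) = self._cache
        self.W.grad += np.einsum("nol,nclk->ock", dy, cols, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2))
        n, c, L = x_shape
        L_out = dy.shape[-1]
        dxp = np.zeros((n, c, L + pl + pr))
        starts = np.arange(L_out) * self.stride
        for j in range(self.k):
            # dy (n,o,L_out) x W[:,:,j] (o,c) -> (n,c,L_out) scattered at offset j
            contrib = np.einsum("nol,oc->ncl", dy, self.W.value[:, :, j],
                                optimize=True)
            np.add.at(dxp, (slice(None), slice(None), starts + j), contrib)
        return dxp[:, :, pl:L + pl]


class _BatchNorm1d:
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = _Param(np.ones(n_ch))
        self.beta = _Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        return term * inv[None, :, None]


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _ResBlock:
    """conv(s=2) -> BN -> ReLU -> conv -> BN, plus 1x1 stride-2 skip
    projection, added then ReLU."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.conv1 = _Conv1d(in_ch, out_ch, k, 2, rng)
        self.bn1 = _BatchNorm1d(out_ch)
        self.relu1 = _ReLU()
        self.conv2 = _Conv1d(out_ch, out_ch, k, 1, rng)
        self.bn2 = _BatchNorm1d(out_ch)
        self.skip = _Conv1d(in_ch, out_ch, 1, 2, rng)
        self.relu_out = _ReLU()

    def params(self):
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.skip):
            out += layer.params()
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        s = self.skip.forward(x, train)
        return self.relu_out.forward(h + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dy)
        ds = self.skip.backward(dy)
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + ds


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _Param(rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in))
        self.b = _Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------- network


class ResNet1D:
    """The uni-dimensional residual decoder (see module docstring)."""

    def __init__(self, spec: NetSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        k = spec.kernel_size
        f = spec.base_filters
        self.stem = _Conv1d(spec.n_input_channels, f, k, 1, rng)
        self.stem_bn = _BatchNorm1d(f)
        self.stem_relu = _ReLU()
        self.blocks = []
        in_ch = f
        for i in range(spec.n_res_blocks):
            out_ch = f * 2 ** i
            self.blocks.append(_ResBlock(in_ch, out_ch, k, rng))
            in_ch = out_ch
        self.head = _Dense(in_ch, 1, rng)
        self._emb_cache = None

    # -- parameter plumbing

    def params(self) -> list[_Param]:
        out = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self):
        return copy.deepcopy([p.value for p in self.params()] +
                             [[bn.running_mean, bn.running_var]
                              for bn in self._batchnorms()])

    def load_state_dict(self, state) -> None:
        params = self.params()
        for p, v in zip(params, state[:len(params)]):
            p.value[...] = v
        for bn, (m, v) in zip(self._batchnorms(), state[len(params):]):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def _batchnorms(self):
        out = [self.stem_bn]
        for b in self.blocks:
            out += [b.bn1, b.bn2]
        return out

    # -- forward / backward

    def embed(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Trunk output after global average pooling: (n, embedding_dim)."""
        h = self.stem.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        for b in self.blocks:
            h = b.forward(h, train)
        self._emb_cache = h.shape
        return h.mean(axis=2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-trial probability of the positive (odor) class, in (0, 1)."""
        emb = self.embed(x, train)
        z = self.head.forward(emb, train)[:, 0]
        return np.clip(_sigmoid(z), 1e-12, 1 - 1e-12)

    def backward_from_probs(self, probs: np.ndarray, y: np.ndarray) -> None:
        """Accumulate gradients of mean BCE loss; call after forward(train=True)."""
        n = len(y)
        dz = ((probs - y) / n)[:, None]           # d(mean BCE)/dz through sigmoid
        demb = self.head.backward(dz)
        n_, c, L = self._emb_cache
        dh = np.repeat(demb[:, :, None], L, axis=2) / L
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        dh = self.stem_relu.backward(dh)
        dh = self.stem_bn.backward(dh)
        self.stem.backward(dh)


def build_net(spec: NetSpec) -> ResNet1D:
    return ResNet1D(spec)


def predict_proba(net, X: np.ndarray) -> np.ndarray:
    return net.forward(np.asarray(X, dtype=float), train=False)


# ---------------------------------------------------------------- training


class _AdamW:
    def __init__(self, params: list[_Param], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                  + self.wd * p.value)  # decoupled decay


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs)))


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    lr_drops: list[int] = field(default_factory=list)


def augment(batch: np.ndarray, aspec: AugmentSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Noise addition, contiguous temporal masking and temporal shifting,
    each applied independently per trial with probability ``apply_prob``.
    Shapes (and, trivially, labels) are unchanged."""
    aspec.validate()
    out = batch.copy()
    n, _, L = out.shape
    mask_len = int(round(aspec.mask_fraction * L))
    shift_max = int(round(aspec.shift_max * aspec.sfreq))
    for i in range(n):
        if aspec.noise_sd > 0 and rng.random() < aspec.apply_prob:
            sd = out[i].std()
            out[i] += rng.standard_normal(out[i].shape) * (aspec.noise_sd * sd)
        if mask_len > 0 and rng.random() < aspec.apply_prob:
            start = rng.integers(0, L - mask_len + 1)
            out[i, :, start:start + mask_len] = 0.0
        if shift_max > 0 and rng.random() < aspec.apply_prob:
            s = int(rng.integers(-shift_max, shift_max + 1))
            if s:
                shifted = np.zeros_like(out[i])
                if s > 0:
                    shifted[:, s:] = out[i, :, :-s]
                else:
                    shifted[:, :s] = out[i, :, -s:]
                out[i] = shifted
    return out


def train_net(net, train_data, val_data, tspec: TrainSpec = TrainSpec(),
              aspec: AugmentSpec | None = None):
    """Train with AdamW + plateau scheduler; return (net at the minimum-
    validation-loss checkpoint, TrainingLog).

    ``train_data``/``val_data`` are (X, y) pairs or EpochSets (``.data``,
    ``.labels``). For the hybrid two-encoder model X is a tuple of arrays.
    """
    tspec.validate()
    X_tr, y_tr = _as_xy(train_data)
    X_va, y_va = _as_xy(val_data)
    # separate streams for batch order and augmentation: augmentation
    # on/off then sees identical batch sequences (paired comparisons)
    rng = np.random.default_rng(tspec.seed)
    aug_rng = np.random.default_rng(tspec.seed + 10007)
    opt = _AdamW(net.params(), tspec.learning_rate, tspec.weight_decay)
    log = TrainingLog()
    best_state = net.state_dict()
    plateau = 0
    n = _n_trials(X_tr)
    for epoch in range(tspec.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tspec.batch_size):
            idx = order[start:start + tspec.batch_size]
            xb = _take(X_tr, idx)
            if aspec is not None:
                xb = _apply_aug(xb, aspec, aug_rng)
            net.zero_grad()
            probs = net.forward(xb, train=True)
            loss = _bce(probs, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf training loss at epoch {epoch}, lr={opt.lr:.2e}; "
                    "aborting")
            net.backward_from_probs(probs, y_tr[idx])
            opt.step()
            losses.append(loss)
        val_probs = net.forward(X_va, train=False)
        vloss = _bce(val_probs, y_va)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(vloss)
        log.lr.append(opt.lr)
        if vloss < log.best_val_loss - 1e-12:
            log.best_val_loss = vloss
            log.best_epoch = epoch
            best_state = net.state_dict()
            plateau = 0
        else:
            plateau += 1
            if plateau >= tspec.scheduler_patience:
                opt.lr /= tspec.scheduler_factor
                log.lr_drops.append(epoch)
                plateau = 0
    net.load_state_dict(best_state)
    return net, log


def _as_xy(data):
    if hasattr(data, "labels") and hasattr(data, "data"):  # single EpochSet
        X, y = data.data, data.labels
    elif isinstance(data, tuple) and len(data) == 2 \
            and all(hasattr(d, "labels") for d in data):
        # pair of EpochSets for the hybrid model
        X = tuple(np.asarray(d.data, float) for d in data)
        y = data[0].labels
        if not np.array_equal(y, data[1].labels):
            raise ValueError("hybrid branches must share labels")
        return X, np.asarray(y, float)
    elif isinstance(data, tuple) and len(data) == 2:
        X, y = data
    else:
        raise TypeError("expected (X, y) or EpochSet(s)")
    if isinstance(X, tuple):
        return tuple(np.asarray(x, float) for x in X), np.asarray(y, float)
    return np.asarray(X, float), np.asarray(y, float)


def _n_trials(X):
    return X[0].shape[0] if isinstance(X, tuple) else X.shape[0]


def _take(X, idx):
    return tuple(x[idx] for x in X) if isinstance(X, tuple) else X[idx]


def _apply_aug(xb, aspec, rng):
    if isinstance(xb, tuple):
        return tuple(augment(x, aspec, rng) for x in xb)
    return augment(xb, aspec, rng)


class NetDecoder:
    """Estimator-style wrapper so the network slots into the nested-CV
    driver. ``fit_with_val`` uses the inner validation fold for scheduler
    and checkpoint selection (as the protocol intends); plain ``fit``
    splits off the last 25% of its training trials as a surrogate
    validation set."""

    def __init__(self, spec: NetSpec, tspec: TrainSpec = TrainSpec(),
                 aspec: AugmentSpec | None = None):
        self.spec = spec
        self.tspec = tspec
        self.aspec = aspec
        self.net: ResNet1D | None = None
        self.log: TrainingLog | None = None

    def fit_with_val(self, X, y, X_val, y_val):
        self.net = ResNet1D(self.spec)
        self.net, self.log = train_net(self.net, (X, y), (X_val, y_val),
                                       self.tspec, self.aspec)
        return self

    def fit(self, X, y):
        n = _n_trials(X)
        cut = max(1, int(round(0.75 * n)))
        rng = np.random.default_rng(self.tspec.seed)
        order = rng.permutation(n)
        tr, va = order[:cut], order[cut:]
        if len(va) == 0 or len(np.unique(np.asarray(y)[va])) < 2:
            tr = va = order  # tiny data: validate on train
        return self.fit_with_val(_take(X, tr), np.asarray(y)[tr],
                                 _take(X, va), np.asarray(y)[va])

    def predict_proba(self, X):
        p = self.net.forward(np.asarray(X, dtype=float) if not isinstance(X, tuple)
                             else tuple(np.asarray(x, float) for x in X),
                             train=False)
        return np.column_stack([1 - p, p])
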