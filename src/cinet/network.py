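"""The convolutional classifier: cuboid convolution, pooling, FCN, training.

The network maps an H x W x Z input cuboid through a stack of cuboid
convolution layers (each filter spans the full z-depth of its input, so
target and context slices are coupled inside every receptive field),
bias + ReLU, one max-pooling layer, a flatten, sigmoid hidden layers and
a softmax output read as class posterior probabilities. Training minimises
cross-entropy by mini-batch gradient descent backpropagation and stops
when the mean training cross-entropy falls below a threshold.

Everything here is plain NumPy: the forward/backward passes are written
with im2col + BLAS matmuls. A separate literal-equation implementation
of the same forward pass lives in :mod:`cinet.reference` and the two are
held to agree to 1e-5 in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConvLayerSpec",
    "PoolSpec",
    "NetworkSpec",
    "TrainConfig",
    "Prediction",
    "Network",
    "cuboid_convolve",
    "conv_layer",
    "max_pool",
    "decide",
    "train",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer: ``filters`` kernels of extent (2a+1) x (2b+1)
    spanning the full z-depth of the layer input; ``mode`` is "valid" or
    "same" (zero-padded)."""

    filters: int
    height: int
    width: int
    mode: str = "valid"

    def __post_init__(self) -> None:
        if self.mode not in ("valid", "same"):
            raise ValueError(f"mode must be 'valid' or 'same', got {self.mode!r}")
        if self.height % 2 == 0 or self.width % 2 == 0:
            raise ValueError("filter extents must be odd (2a+1, 2b+1)")
        if self.filters < 1:
            raise ValueError("need at least one filter")


@dataclass(frozen=True)
class PoolSpec:
    """Max pooling with a size x size window at the given stride."""

    size: int = 2
    stride: int = 2


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``fcn_widths`` lists the fully connected layer widths ending with the
    number of classes L; hidden FCN layers use ``hidden_activation`` and
    the final layer uses softmax.
    """

    input_shape: tuple[int, int, int]
    conv_layers: tuple[ConvLayerSpec, ...]
    pool: PoolSpec | None
    fcn_widths: tuple[int, ...]
    hidden_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.hidden_activation not in ("sigmoid", "tanh", "relu"):
            raise ValueError("hidden_activation must be sigmoid, tanh or relu")
        if len(self.fcn_widths) < 1:
            raise ValueError("fcn_widths must end with the number of classes")
        self.layer_shapes()  # validate dimension chain eagerly

    @property
    def n_classes(self) -> int:
        return self.fcn_widths[-1]

    def layer_shapes(self) -> list[tuple[int, ...]]:
        """The cuboid dimension chain from input through pooling."""
        h, w, z = self.input_shape
        shapes: list[tuple[int, ...]] = [(h, w, z)]
        for cl in self.conv_layers:
            if cl.mode == "valid":
                h, w = h - cl.height + 1, w - cl.width + 1
                if h < 1 or w < 1:
                    raise ValueError("filter larger than layer input")
            shapes.append((h, w, cl.filters))
            z = cl.filters
        if self.pool is not None:
            p = self.pool
            if (h - p.size) % p.stride or (w - p.size) % p.stride:
                raise ValueError(
                    f"pooled dims (H-{p.size})/{p.stride}+1 must be integral for {h}x{w}")
            h = (h - p.size) // p.stride + 1
            w = (w - p.size) // p.stride + 1
            shapes.append((h, w, z))
        return shapes

    @property
    def flat_dim(self) -> int:
        return int(np.prod(self.layer_shapes()[-1]))

    @classmethod
    def cinet(cls, span: int, *, filters: tuple[int, ...] = (32, 32),
              filter_size: int = 3, n_classes: int = 6,
              hidden: int = 100, grid: int = 32) -> "NetworkSpec":
        """The standard architecture used in the experiments: two valid-mode
        convolution layers, one 2x2/stride-2 max pool, and a 100-unit
        sigmoid hidden layer feeding L softmax outputs, on 32 x 32 x (1+S)
        input cuboids."""
        return cls(
            input_shape=(grid, grid, 1 + span),
            conv_layers=tuple(ConvLayerSpec(k, filter_size, filter_size, "valid")
                              for k in filters),
            pool=PoolSpec(2, 2),
            fcn_widths=(hidden, n_classes),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``train_noise_variance`` is the small variance applied to the otherwise
    noise-free exemplars; ``loss_threshold`` stops training once the mean
    cross-entropy over the full training set drops below it.
    """

    train_noise_variance: float = 0.001
    loss_threshold: float = 0.001
    max_epochs: int = 500
    learning_rate: float = 0.1
    optimizer: str = "momentum"  # "momentum" (with plateau decay) or "adam"
    momentum: float = 0.9
    lr_patience: int = 10  # epochs without improvement before halving the rate
    lr_decay: float = 0.5
    restarts: int = 4  # re-initialisations allowed when a run gets stuck
    batch_size: int = 16
    samples_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_threshold <= 0:
            raise ValueError("loss_threshold must be positive")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.optimizer not in ("adam", "momentum"):
            raise ValueError("optimizer must be 'adam' or 'momentum'")


@dataclass(frozen=True)
class Prediction:
    """Class posteriors and the maximum-posterior decision."""

    posteriors: np.ndarray
    decided_class: int


def decide(posteriors: np.ndarray | Sequence[float]) -> int:
    """Maximum-posterior decision rule; ties go to the lowest class index."""
    return int(np.argmax(np.asarray(posteriors)))


# ---------------------------------------------------------------------------
# primitive operations (single input, public per-op surface)


def cuboid_convolve(x: np.ndarray, filt: np.ndarray, mode: str = "valid") -> np.ndarray:
    """Correlate an H x W x Z cuboid with a (2a+1) x (2b+1) x Z filter.

    Returns a 2-D map: the triple sum over (u, v, z) of filter times
    receptive field. ``same`` zero-pads to preserve H x W; ``valid``
    yields (H-2a) x (W-2b).
    """
    x = np.asarray(x, dtype=np.float64)
    filt = np.asarray(filt, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if filt.ndim == 2:
        filt = filt[:, :, None]
    fh, fw, fz = filt.shape
    if fz != x.shape[2]:
        raise ValueError(f"filter z-depth {fz} != input z-depth {x.shape[2]}")
    if mode == "same":
        a, b = fh // 2, fw // 2
        x = np.pad(x, ((a, a), (b, b), (0, 0)))
    elif mode != "valid":
        raise ValueError(f"unknown mode {mode!r}")
    win = np.lib.stride_tricks.sliding_window_view(x, (fh, fw), axis=(0, 1))
    # win: (H', W', Z, fh, fw); filter indexed (u, v, z)
    return np.einsum("hwzuv,uvz->hw", win, filt)


def conv_layer(x: np.ndarray, filters: np.ndarray, biases: np.ndarray,
               mode: str = "valid") -> np.ndarray:
    """Apply K cuboid filters + bias + ReLU, stacking the K activation maps.

    ``filters`` has shape (fh, fw, Z, K); ``biases`` has shape (K,).
    """
    filters = np.asarray(filters, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)
    if filters.ndim != 4:
        raise ValueError("filters must have shape (fh, fw, Z, K)")
    if biases.shape != (filters.shape[3],):
        raise ValueError(f"need one bias per filter, got {biases.shape}")
    maps = [cuboid_convolve(x, filters[..., k], mode) + biases[k]
            for k in range(filters.shape[3])]
    return np.maximum(np.stack(maps, axis=2), 0.0)


def max_pool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Per-channel max over size x size windows at the given stride."""
    x = np.asarray(x)
    h, w = x.shape[:2]
    if (h - size) % stride or (w - size) % stride:
        raise ValueError(f"(dim - {size}) must be divisible by {stride}")
    ho = (h - size) // stride + 1
    wo = (w - size) // stride + 1
    stacked = np.stack([x[th::stride, tw::stride][:ho, :wo]
                        for th in range(size) for tw in range(size)])
    return stacked.max(axis=0)


# ---------------------------------------------------------------------------
# batched fast path


def _im2col(x: np.ndarray, fh: int, fw: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H',W',fh*fw*C) patch matrix for valid correlation."""
    n, h, w, c = x.shape
    ho, wo = h - fh + 1, w - fw + 1
    cols = np.empty((n, ho, wo, fh * fw * c), dtype=x.dtype)
    k = 0
    for u in range(fh):
        for v in range(fw):
            cols[..., k * c:(k + 1) * c] = x[:, u:u + ho, v:v + wo, :]
            k += 1
    return cols


def _col2im(dcols: np.ndarray, x_shape: tuple, fh: int, fw: int) -> np.ndarray:
    n, h, w, c = x_shape
    ho, wo = h - fh + 1, w - fw + 1
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    k = 0
    for u in range(fh):
        for v in range(fw):
            dx[:, u:u + ho, v:v + wo, :] += dcols[..., k * c:(k + 1) * c]
            k += 1
    return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACT = {
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(a.dtype)),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A trained or freshly initialised classifier.

    Weights are a flat dict: ``conv{i}_w`` (fh, fw, C, K), ``conv{i}_b``
    (K,), ``fc{i}_w`` (in, out), ``fc{i}_b`` (out,).
    """

    def __init__(self, spec: NetworkSpec, weights: dict[str, np.ndarray],
                 dtype=np.float32) -> None:
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.weights = {k: np.asarray(v, dtype=self.dtype) for k, v in weights.items()}
        self._check_shapes()

    def _check_shapes(self) -> None:
        shapes = self.spec.layer_shapes()
        z = self.spec.input_shape[2]
        for i, cl in enumerate(self.spec.conv_layers):
            want = (cl.height, cl.width, z, cl.filters)
            got = self.weights[f"conv{i}_w"].shape
            if got != want:
                raise ValueError(f"conv{i}_w shape {got}, expected {want}")
            if self.weights[f"conv{i}_b"].shape != (cl.filters,):
                raise ValueError(f"conv{i}_b must have {cl.filters} biases")
            z = cl.filters
        d = self.spec.flat_dim
        for i, width in enumerate(self.spec.fcn_widths):
            if self.weights[f"fc{i}_w"].shape != (d, width):
                raise ValueError(f"fc{i}_w shape {self.weights[f'fc{i}_w'].shape}, "
                                 f"expected {(d, width)}")
            d = width
        del shapes

    @classmethod
    def initialize(cls, spec: NetworkSpec, seed: int, dtype=np.float32) -> "Network":
        """Glorot-uniform random weights, zero biases."""
        rng = np.random.default_rng(seed)
        w: dict[str, np.ndarray] = {}
        z = spec.input_shape[2]
        for i, cl in enumerate(spec.conv_layers):
            fan_in = cl.height * cl.width * z
            fan_out = cl.height * cl.width * cl.filters
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            w[f"conv{i}_w"] = rng.uniform(-lim, lim, (cl.height, cl.width, z, cl.filters))
            w[f"conv{i}_b"] = np.zeros(cl.filters)
            z = cl.filters
        d = spec.flat_dim
        for i, width in enumerate(spec.fcn_widths):
            lim = np.sqrt(6.0 / (d + width))
            w[f"fc{i}_w"] = rng.uniform(-lim, lim, (d, width))
            w[f"fc{i}_b"] = np.zeros(width)
            d = width
        return cls(spec, w, dtype=dtype)

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (N, H, W, Z) -> posteriors (N, L); optionally return caches."""
        spec = self.spec
        cache: list = []
        act = x.astype(self.dtype, copy=False)
        for i, cl in enumerate(spec.conv_layers):
            wmat = self.weights[f"conv{i}_w"]
            fh, fw, c, k = wmat.shape
            padded = act
            if cl.mode == "same":
                a, b = fh // 2, fw // 2
                padded = np.pad(act, ((0, 0), (a, a), (b, b), (0, 0)))
            cols = _im2col(padded, fh, fw)
            n, ho, wo, _ = cols.shape
            pre = cols.reshape(-1, fh * fw * c) @ wmat.reshape(-1, k)
            pre = pre.reshape(n, ho, wo, k) + self.weights[f"conv{i}_b"]
            out = np.maximum(pre, 0.0)
            if keep_cache:
                cache.append(("conv", i, padded.shape, cols, pre > 0))
            act = out
        if spec.pool is not None:
            size, stride = spec.pool.size, spec.pool.stride
            n, h, w, c = act.shape
            ho = (h - size) // stride + 1
            wo = (w - size) // stride + 1
            stacked = np.stack([act[:, th::stride, tw::stride][:, :ho, :wo]
                                for th in range(size) for tw in range(size)])
            if keep_cache:
                arg = stacked.argmax(axis=0)  # first index wins ties
                out = np.take_along_axis(stacked, arg[None], axis=0)[0]
                cache.append(("pool", arg, act.shape))
            else:
                out = stacked.max(axis=0)
            act = out
        n = act.shape[0]
        act = act.reshape(n, -1)
        if keep_cache:
            cache.append(("flatten", self.spec.layer_shapes()[-1]))
        f_act, _ = _ACT[spec.hidden_activation]
        for i in range(len(spec.fcn_widths)):
            pre = act @ self.weights[f"fc{i}_w"] + self.weights[f"fc{i}_b"]
            if i < len(spec.fcn_widths) - 1:
                out = f_act(pre)
            else:
                out = _softmax(pre.astype(np.float64))
            if keep_cache:
                cache.append(("fc", i, act, out))
            act = out
        return (act, cache) if keep_cache else act

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Posterior probabilities for a batch of input cuboids."""
        x = np.asarray(x)
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(f"input shape {x.shape[1:]} != spec {self.spec.input_shape}")
        return self._forward(x)

    def predict(self, x) -> Prediction:
        """Classify one integrated input (array or IntegratedInput)."""
        arr = getattr(x, "cuboid", x)
        probs = self.forward_batch(np.asarray(arr)[None])[0]
        return Prediction(posteriors=probs, decided_class=decide(probs))

    def loss(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy of the true classes."""
        probs = self.forward_batch(x)
        p = probs[np.arange(len(labels)), labels]
        return float(-np.log(np.maximum(p, 1e-300)).mean())

    def accuracy(self, x: np.ndarray, labels: np.ndarray) -> float:
        probs = self.forward_batch(x)
        return float((probs.argmax(axis=1) == labels).mean())

    # -- backward ----------------------------------------------------------

    def _grads(self, x: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy loss and its gradient for a mini-batch."""
        probs, cache = self._forward(x, keep_cache=True)
        n = len(labels)
        p = probs[np.arange(n), labels]
        loss = float(-np.log(np.maximum(p, 1e-300)).mean())
        grads: dict[str, np.ndarray] = {}
        delta = probs.copy()
        delta[np.arange(n), labels] -= 1.0
        delta = (delta / n).astype(self.dtype)

        _, d_act = _ACT[self.spec.hidden_activation]
        for entry in reversed(cache):
            kind = entry[0]
            if kind == "fc":
                _, i, inp, out = entry
                if i < len(self.spec.fcn_widths) - 1:
                    delta = delta * d_act(out)
                grads[f"fc{i}_w"] = inp.T @ delta
                grads[f"fc{i}_b"] = delta.sum(axis=0)
                delta = delta @ self.weights[f"fc{i}_w"].T
            elif kind == "flatten":
                _, shape = entry
                delta = delta.reshape((-1,) + tuple(shape))
            elif kind == "pool":
                _, arg, in_shape = entry
                size, stride = self.spec.pool.size, self.spec.pool.stride
                dx = np.zeros(in_shape, dtype=self.dtype)
                nb, h, w, c = in_shape
                ho = (h - size) // stride + 1
                wo = (w - size) // stride + 1
                for idx in range(size * size):
                    th, tw = divmod(idx, size)
                    mask = arg == idx
                    dx[:, th::stride, tw::stride][:, :ho, :wo] += delta * mask
                delta = dx
            elif kind == "conv":
                _, i, padded_shape, cols, relu_mask = entry
                cl = self.spec.conv_layers[i]
                wmat = self.weights[f"conv{i}_w"]
                fh, fw, c, k = wmat.shape
                delta = delta * relu_mask
                d2 = delta.reshape(-1, k)
                grads[f"conv{i}_w"] = (cols.reshape(-1, fh * fw * c).T @ d2).reshape(wmat.shape)
                grads[f"conv{i}_b"] = d2.sum(axis=0)
                if i > 0:  # no input gradient needed at the first layer
                    dcols = (d2 @ wmat.reshape(-1, k).T).reshape(cols.shape)
                    delta = _col2im(dcols, padded_shape, fh, fw)
                    if cl.mode == "same":
                        a, b = fh // 2, fw // 2
                        delta = delta[:, a:-a or None, b:-b or None, :]
        return loss, grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist weights plus the architecture to HDF5."""
        import h5py
        import json

        with h5py.File(path, "w") as f:
            for k, v in self.weights.items():
                f.create_dataset(k, data=v)
            f.attrs["spec"] = json.dumps({
                "input_shape": self.spec.input_shape,
                "conv_layers": [(c.filters, c.height, c.width, c.mode)
                                for c in self.spec.conv_layers],
                "pool": None if self.spec.pool is None
                        else (self.spec.pool.size, self.spec.pool.stride),
                "fcn_widths": self.spec.fcn_widths,
                "hidden_activation": self.spec.hidden_activation,
            })

    @classmethod
    def load(cls, path) -> "Network":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["spec"])
            weights = {k: f[k][...] for k in f.keys()}
        spec = NetworkSpec(
            input_shape=tuple(meta["input_shape"]),
            conv_layers=tuple(ConvLayerSpec(*c) for c in meta["conv_layers"]),
            pool=None if meta["pool"] is None else PoolSpec(*meta["pool"]),
            fcn_widths=tuple(meta["fcn_widths"]),
            hidden_activation=meta["hidden_activation"],
        )
        return cls(spec, weights)


@dataclass
class TrainResult:
    network: Network
    converged: bool
    epochs: int
    final_loss: float
    train_accuracy: float
    loss_history: list[float] = field(repr=False, default_factory=list)


def train(spec: NetworkSpec, inputs: np.ndarray, labels: np.ndarray,
          config: TrainConfig) -> TrainResult:
    """Mini-batch gradient descent to the cross-entropy stopping criterion.

    Stops when the mean cross-entropy over the *full* training set falls
    below ``config.loss_threshold``. A run that settles into a poor local
    minimum (plateaued well above the threshold) is abandoned and
    restarted from a fresh initialisation, up to ``config.restarts``
    times; the final attempt runs to ``max_epochs`` and flags
    non-convergence. Deterministic for a given seed.
    """
    inputs = np.asarray(inputs)
    labels = np.asarray(labels)
    if len(inputs) == 0:
        raise ValueError("empty training set")
    if labels.min() < 0 or labels.max() >= spec.n_classes:
        raise ValueError("labels must lie in 0..L-1")
    last = None
    for attempt in range(config.restarts + 1):
        final = attempt == config.restarts
        last = _train_attempt(spec, inputs, labels, config,
                              int(np.random.SeedSequence(
                                  [int(config.seed), attempt]).generate_state(1)[0]
                                  % (2**31)),
                              allow_abandon=not final)
        if last.converged:
            break
    return last


def _train_attempt(spec: NetworkSpec, inputs: np.ndarray, labels: np.ndarray,
                   config: TrainConfig, seed: int,
                   allow_abandon: bool) -> TrainResult:
    rng = np.random.default_rng(seed)
    net = Network.initialize(spec, seed=int(rng.integers(2**31)))
    vel = {k: np.zeros_like(v) for k, v in net.weights.items()}
    sq = {k: np.zeros_like(v) for k, v in net.weights.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr = config.learning_rate
    best = np.inf
    since_best = 0
    history: list[float] = []
    converged = False
    epoch = 0
    n = len(inputs)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = net._grads(inputs[idx], labels[idx])
            batch_losses.append(loss * len(idx))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became non-finite (learning_rate={config.learning_rate})")
            if config.optimizer == "momentum":
                for k, g in grads.items():
                    vel[k] = config.momentum * vel[k] - lr * g
                    net.weights[k] += vel[k]
            else:  # Adam
                step += 1
                corr = np.sqrt(1 - b2**step) / (1 - b1**step)
                for k, g in grads.items():
                    vel[k] = b1 * vel[k] + (1 - b1) * g
                    sq[k] = b2 * sq[k] + (1 - b2) * g * g
                    net.weights[k] -= lr * corr * vel[k] / (np.sqrt(sq[k]) + eps)
        # the exact full-set loss (the stopping quantity) is only worth
        # computing once the running epoch mean gets near the stop
        epoch_mean = float(np.sum(batch_losses) / n)
        if epoch_mean < 5 * config.loss_threshold:
            full_loss = net.loss(inputs, labels)
        else:
            full_loss = epoch_mean
        history.append(full_loss)
        if not np.isfinite(full_loss) or \
                any(not np.isfinite(w).all() for w in net.weights.values()):
            raise TrainingDivergedError(
                f"training diverged (learning_rate={config.learning_rate})")
        if full_loss < config.loss_threshold:
            converged = True
            break
        # reduce-on-plateau, applied only while the run is still far from
        # the stop: it tames oscillating runs without starving the final
        # descent (which improves by small relative steps) of its rate
        if full_loss < 0.995 * best:
            best = full_loss
            since_best = 0
        elif full_loss > 10 * config.loss_threshold:
            since_best += 1
            if since_best >= config.lr_patience:
                lr *= config.lr_decay
                since_best = 0
        # a run stuck far above the stop after the rate collapsed (or after
        # many epochs), or one crawling through an over-long tail, is
        # better re-initialised than continued
        if allow_abandon and full_loss > 50 * config.loss_threshold and \
                (lr < 0.02 * config.learning_rate or epoch >= 80):
            break
        if allow_abandon and epoch >= 200 and full_loss > 5 * config.loss_threshold:
            break
    return TrainResult(network=net, converged=converged, epochs=epoch,
                       final_loss=history[-1] if history else np.inf,
                       train_accuracy=net.accuracy(inputs, labels),
                       loss_history=history)
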