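"""Residual Chebyshev graph-CNN for structure-age estimation.

The network follows a residual architecture operating on graph signals: a
first Chebyshev convolution with a large receptive field and stride-2
pooling, three pre-activation residual blocks each followed by pooling, a
final batch-norm + convolution + global average pooling, and a dual-branch
soft-bin age head (a ReLU branch emitting learnable bin ages, a Softmax
branch emitting bin probabilities; their elementwise product is linearly
combined into the age estimate).

All layers are implemented directly on NumPy arrays with hand-written
backward passes, trained with RMSprop on a mean-squared-error loss; graph
convolutions use the three-term Chebyshev recursion on the sparse rescaled
Laplacian and never materialize dense polynomial matrices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .coarsening import CoarseningHierarchy, apply_ordering

__all__ = [
    "ChebConv",
    "AgeNetworkConfig",
    "TrainingConfig",
    "InferenceConfig",
    "AgeNetwork",
    "AgePrediction",
    "ScanDataset",
    "LeakageError",
    "cheb_conv",
    "random_rotation",
    "train",
    "predict_ensemble_tta",
    "evaluate_predictions",
]


class LeakageError(ValueError):
    """Train and validation sets share a subject."""


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _lap_dot(L: sp.csr_matrix, x: np.ndarray) -> np.ndarray:
    """Apply a sparse (N, N) operator to a (B, N, F) signal stack."""
    B, N, F = x.shape
    y = L @ x.transpose(1, 0, 2).reshape(N, B * F)
    return y.reshape(N, B, F).transpose(1, 0, 2)


class ChebConv:
    """Graph convolution  Y = sum_k T_k(L~) X theta_k + bias  with
    T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2}."""

    def __init__(
        self,
        L: sp.csr_matrix,
        K: int,
        f_in: int,
        f_out: int,
        rng: np.random.Generator,
    ) -> None:
        if K < 1:
            raise ValueError("Chebyshev order K must be >= 1")
        self.L = sp.csr_matrix(L)
        self.K = K
        limit = np.sqrt(6.0 / (K * f_in + f_out))  # variance-scaling uniform
        self.params = {
            "theta": rng.uniform(-limit, limit, size=(K, f_in, f_out)),
            "bias": np.zeros(f_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.kernel_keys = ("theta",)
        self._cache: np.ndarray | None = None

    def _stack(self, x: np.ndarray) -> np.ndarray:
        """(K, B, N, F) stack of T_k(L~) X via the three-term recursion."""
        ts = [x]
        if self.K > 1:
            ts.append(_lap_dot(self.L, x))
        for _ in range(2, self.K):
            ts.append(2.0 * _lap_dot(self.L, ts[-1]) - ts[-2])
        return np.stack(ts)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.L.shape[0]:
            raise ValueError(
                f"signal has {x.shape[1]} rows, Laplacian is {self.L.shape[0]}"
            )
        tx = self._stack(x)
        self._cache = tx
        y = np.einsum("kbnf,kfo->bno", tx, self.params["theta"], optimize=True)
        return y + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        tx = self._cache
        self.grads["theta"] = np.einsum("kbnf,bno->kfo", tx, dy, optimize=True)
        self.grads["bias"] = dy.sum(axis=(0, 1))
        # dX = sum_k T_k(L~) (dY theta_k^T): Clenshaw recurrence, L~ symmetric
        theta = self.params["theta"]
        hs = [dy @ theta[k].T for k in range(self.K)]
        b1 = np.zeros_like(hs[0])
        b2 = np.zeros_like(hs[0])
        for k in range(self.K - 1, 0, -1):
            b1, b2 = hs[k] + 2.0 * _lap_dot(self.L, b1) - b2, b1
        return hs[0] + _lap_dot(self.L, b1) - b2


def cheb_conv(
    L: sp.csr_matrix | "object",
    x: np.ndarray,
    theta: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Functional Chebyshev convolution of a single (N, F_in) signal.

    ``L`` may be a sparse matrix or a ScaledLaplacian; ``theta`` has shape
    (K, F_in, F_out).
    """
    mat = getattr(L, "matrix", L)
    theta = np.asarray(theta)
    K, f_in, f_out = theta.shape
    layer = ChebConv(mat, K, f_in, f_out, np.random.default_rng(0))
    layer.params["theta"] = theta
    layer.params["bias"] = np.zeros(f_out) if bias is None else np.asarray(bias)
    return layer.forward(x[None])[0]


class BatchNorm:
    """Per-channel batch normalization over all leading axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(n_channels), "beta": np.zeros(n_channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.kernel_keys = ()
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        return (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU:
    params: dict = {}
    grads: dict = {}
    kernel_keys = ()

    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class PairPool:
    """Stride-2 pooling over consecutive row pairs of a (B, N, F) signal."""

    params: dict = {}
    grads: dict = {}
    kernel_keys = ()

    def __init__(self, mode: str = "max") -> None:
        if mode not in ("max", "mean"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.mode = mode
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, N, F = x.shape
        r = x.reshape(B, N // 2, 2, F)
        if self.mode == "max":
            idx = r.argmax(axis=2)
            self._cache = (idx, x.shape)
            return np.take_along_axis(r, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (None, x.shape)
        return r.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        B, N, F = shape
        dr = np.zeros((B, N // 2, 2, F))
        if self.mode == "max":
            np.put_along_axis(dr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        else:
            dr += dy[:, :, None, :] / 2.0
        return dr.reshape(B, N, F)


class GlobalAvgPool:
    params: dict = {}
    grads: dict = {}
    kernel_keys = ()

    def __init__(self) -> None:
        self._n = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._n = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._n, axis=1) / self._n


class Dense:
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (f_in + f_out))
        self.params = {
            "w": rng.uniform(-limit, limit, size=(f_in, f_out)),
            "b": np.zeros(f_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.kernel_keys = ("w",)
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout:
    params: dict = {}
    grads: dict = {}
    kernel_keys = ()

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Softmax:
    params: dict = {}
    grads: dict = {}
    kernel_keys = ()

    def __init__(self) -> None:
        self._y = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AgeNetworkConfig:
    """Architecture hyperparameters.

    Convolutional layers carry 64 filters except the last one (128); both
    head dense layers have 75 units (the number of age bins); dropout 0.75
    on the Softmax branch; L2 weight penalty 1e-12.  Kernel orders K control
    the spatial support of each Chebyshev filter.
    """

    conv_filters: int = 64
    last_conv_filters: int = 128
    dense_units: int = 75
    n_residual_blocks: int = 3
    K_first: int = 9
    K_block: int = 6
    dropout_softmax_branch: float = 0.75
    l2_lambda: float = 1e-12
    pool_mode: str = "max"

    def __post_init__(self) -> None:
        for name in (
            "conv_filters",
            "last_conv_filters",
            "dense_units",
            "n_residual_blocks",
            "K_first",
            "K_block",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_softmax_branch < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainingConfig:
    """Optimization regime: MSE loss minimized with RMSprop; validation MAE
    is the monitored metric, with the learning rate divided by 10 after 15
    non-improving epochs and training stopped after 30."""

    batch_size: int = 16
    max_epochs: int = 100
    initial_lr: float = 0.001
    lr_drop_factor: float = 10.0
    lr_patience_epochs: int = 15
    stop_patience_epochs: int = 30
    train_rotation_deg: float = 15.0
    val_rotation_deg: float = 5.0
    val_tta: int = 3
    seed: int = 0
    #: initialize the output-layer bias to the train-set mean age, so the
    #: network starts at the no-information prediction instead of zero
    init_output_bias_to_mean: bool = True

    def __post_init__(self) -> None:
        if self.stop_patience_epochs < self.lr_patience_epochs:
            raise ValueError("stop patience must be >= LR patience")
        if self.train_rotation_deg < 0 or self.val_rotation_deg < 0:
            raise ValueError("rotation angles must be >= 0")


@dataclass
class InferenceConfig:
    """Ensemble + test-time-augmentation inference: every (network,
    augmented copy) prediction is kept and the arithmetic mean reported."""

    ensemble_size: int = 20
    test_tta: int = 20
    rotation_deg: float = 5.0
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.ensemble_size < 1 or self.test_tta < 1:
            raise ValueError("ensemble size and TTA count must be >= 1")


@dataclass
class AgePrediction:
    scan_id: str
    structure_config: str
    raw: np.ndarray  # (ensemble, tta) estimates, years
    aggregated: float  # mean of raw
    corrected: float | None = None  # filled by bias correction

    @property
    def n_estimates(self) -> int:
        return int(self.raw.size)


@dataclass
class ScanDataset:
    """Features, ages and subject ids for a set of scans of one structure
    configuration (features in template node order, shape (n, N, F))."""

    features: np.ndarray
    ages: np.ndarray
    subject_ids: Sequence[str]
    scan_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        n = len(self.ages)
        if self.features.shape[0] != n or len(self.subject_ids) != n:
            raise ValueError("features, ages and subject_ids must align")
        if self.scan_ids is None:
            self.scan_ids = [f"scan{i:05d}" for i in range(n)]

    def __len__(self) -> int:
        return len(self.ages)


# ---------------------------------------------------------------------------
# rotation augmentation
# ---------------------------------------------------------------------------

def random_rotation(
    features: np.ndarray,
    max_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one random rotation about the origin to every coordinate triple.

    Angles are Euler Z-Y-X, each ~ Uniform(-max_deg, +max_deg) in degrees;
    the same rotation matrix is applied to all triples of the scan (columns
    come in groups of 3), so per-node norms are preserved.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.shape[-1] % 3:
        raise ValueError("feature columns must be coordinate triples")
    if max_deg == 0:
        return x.copy()
    angles = rng.uniform(-max_deg, max_deg, size=3)
    R = Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()
    out = np.empty_like(x)
    for c in range(0, x.shape[-1], 3):
        out[..., c : c + 3] = x[..., c : c + 3] @ R.T
    return out


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _ResidualBlock:
    """Pre-activation residual block: BN-ReLU-conv-BN-ReLU-conv + identity."""

    def __init__(self, L, K, channels, rng):
        self.bn1 = BatchNorm(channels)
        self.relu1 = ReLU()
        self.conv1 = ChebConv(L, K, channels, channels, rng)
        self.bn2 = BatchNorm(channels)
        self.relu2 = ReLU()
        self.conv2 = ChebConv(L, K, channels, channels, rng)
        self.layers = [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]

    def forward(self, x, training):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        return x + h

    def backward(self, dy):
        dh = dy
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dy + dh


class AgeNetwork:
    """Residual Chebyshev gCNN with the dual-branch soft-bin age head."""

    def __init__(
        self,
        hierarchy: CoarseningHierarchy,
        n_features: int,
        config: AgeNetworkConfig | None = None,
        seed: int = 0,
        structure_config: str = "structure",
    ) -> None:
        config = config or AgeNetworkConfig()
        needed = config.n_residual_blocks + 1  # pooling events
        if hierarchy.n_levels < needed:
            raise ValueError(
                f"hierarchy has {hierarchy.n_levels} levels but the "
                f"architecture pools {needed} times"
            )
        self.config = config
        self.hierarchy = hierarchy
        self.n_features = n_features
        self.seed = seed
        self.structure_config = structure_config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng((seed + 1) * 7919)
        C = config.conv_filters

        lap = [hierarchy.laplacian(s).matrix for s in range(needed + 1)]
        self.conv0 = ChebConv(lap[0], config.K_first, n_features, C, rng)
        self.pool0 = PairPool(config.pool_mode)
        self.blocks: list[_ResidualBlock] = []
        self.block_pools: list[PairPool] = []
        for b in range(config.n_residual_blocks):
            self.blocks.append(_ResidualBlock(lap[1 + b], config.K_block, C, rng))
            self.block_pools.append(PairPool(config.pool_mode))
        self.bn_final = BatchNorm(C)
        self.conv_last = ChebConv(
            lap[needed], config.K_block, C, config.last_conv_filters, rng
        )
        self.gap = GlobalAvgPool()
        self.dense_bins = Dense(config.last_conv_filters, config.dense_units, rng)
        self.relu_bins = ReLU()
        self.dense_probs = Dense(config.last_conv_filters, config.dense_units, rng)
        self.dropout_probs = Dropout(config.dropout_softmax_branch, self._dropout_rng)
        self.softmax_probs = Softmax()
        self.dense_out = Dense(config.dense_units, 1, rng)
        self._head_cache = None

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        out = [self.conv0]
        for blk in self.blocks:
            out.extend(blk.layers)
        out += [
            self.bn_final,
            self.conv_last,
            self.dense_bins,
            self.dense_probs,
            self.dense_out,
        ]
        return out

    def parameters(self):
        """Yield (layer, key, is_kernel) triples over trainable arrays."""
        for layer in self._layers():
            for key in layer.params:
                yield layer, key, key in layer.kernel_keys

    @property
    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k, _ in self.parameters())

    def get_weights(self):
        return [
            copy.deepcopy(layer.params) for layer in self._layers()
        ], [
            (copy.deepcopy(l.running_mean), copy.deepcopy(l.running_var))
            for l in self._layers()
            if isinstance(l, BatchNorm)
        ]

    def set_weights(self, snapshot) -> None:
        params, bn_stats = snapshot
        for layer, p in zip(self._layers(), params):
            layer.params = copy.deepcopy(p)
        bns = [l for l in self._layers() if isinstance(l, BatchNorm)]
        for layer, (mu, var) in zip(bns, bn_stats):
            layer.running_mean = copy.deepcopy(mu)
            layer.running_var = copy.deepcopy(var)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Predict ages (B,) from features (B, N0, F) in template order."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.hierarchy.node_counts[0] or x.shape[2] != self.n_features:
            raise ValueError(
                f"expected input (B, {self.hierarchy.node_counts[0]}, "
                f"{self.n_features}), got {x.shape}"
            )
        h = apply_ordering(x, self.hierarchy.perms[0])
        h = self.pool0.forward(self.conv0.forward(h, training), training)
        for blk, pool in zip(self.blocks, self.block_pools):
            h = pool.forward(blk.forward(h, training), training)
        h = self.bn_final.forward(h, training)
        h = self.conv_last.forward(h, training)
        g = self.gap.forward(h, training)
        bins = self.relu_bins.forward(self.dense_bins.forward(g, training), training)
        probs = self.softmax_probs.forward(
            self.dropout_probs.forward(self.dense_probs.forward(g, training), training),
            training,
        )
        self._head_cache = (bins, probs)
        out = self.dense_out.forward(bins * probs, training)
        return out[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        bins, probs = self._head_cache
        dprod = self.dense_out.backward(dpred[:, None])
        dbins = self.relu_bins.backward(dprod * probs)
        dprobs = self.softmax_probs.backward(dprod * bins)
        dg = self.dense_bins.backward(dbins)
        dg = dg + self.dense_probs.backward(self.dropout_probs.backward(dprobs))
        dh = self.gap.backward(dg)
        dh = self.conv_last.backward(dh)
        dh = self.bn_final.backward(dh)
        for blk, pool in zip(reversed(self.blocks), reversed(self.block_pools)):
            dh = blk.backward(pool.backward(dh))
        dh = self.conv0.backward(self.pool0.backward(dh))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    # -- checkpointing ------------------------------------------------------

    def hierarchy_hash(self) -> str:
        """Digest of the pooling hierarchy, so train and predict provably
        share identical orderings."""
        import hashlib

        h = hashlib.sha256()
        for perm in self.hierarchy.perms:
            h.update(np.ascontiguousarray(perm).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        """Single-file checkpoint: config, hierarchy hash and weights."""
        import pickle

        snapshot = {
            "config": self.config,
            "n_features": self.n_features,
            "seed": self.seed,
            "structure_config": self.structure_config,
            "hierarchy_hash": self.hierarchy_hash(),
            "weights": self.get_weights(),
        }
        with open(path, "wb") as fh:
            pickle.dump(snapshot, fh)

    @classmethod
    def load(cls, path, hierarchy: CoarseningHierarchy) -> "AgeNetwork":
        """Rebuild a network from a checkpoint and the matching hierarchy."""
        import pickle

        with open(path, "rb") as fh:
            snap = pickle.load(fh)
        net = cls(
            hierarchy,
            snap["n_features"],
            snap["config"],
            seed=snap["seed"],
            structure_config=snap["structure_config"],
        )
        if net.hierarchy_hash() != snap["hierarchy_hash"]:
            raise ValueError(
                "checkpoint was trained with a different pooling hierarchy"
            )
        net.set_weights(snap["weights"])
        return net


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class RMSprop:
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7) -> None:
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, network: AgeNetwork) -> None:
        for i, (layer, key, _) in enumerate(network.parameters()):
            g = layer.grads[key]
            c = self._cache.get(i)
            if c is None:
                c = np.zeros_like(g)
            c = self.rho * c + (1 - self.rho) * g * g
            self._cache[i] = c
            layer.params[key] -= self.lr * g / (np.sqrt(c) + self.eps)


class LrStopSchedule:
    """Monitor a metric; drop the LR by ``drop_factor`` after ``lr_patience``
    non-improving epochs, request a stop after ``stop_patience``."""

    def __init__(self, lr_patience: int, stop_patience: int) -> None:
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self.since_improve = 0

    def update(self, metric: float) -> tuple[bool, bool, bool]:
        """Returns (improved, drop_lr_now, stop_now)."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.since_improve = 0
            return True, False, False
        self.since_improve += 1
        stop = self.since_improve >= self.stop_patience
        drop = (
            not stop
            and self.since_improve % self.lr_patience == 0
        )
        return False, drop, stop


def _l2_penalty(network: AgeNetwork) -> float:
    lam = network.config.l2_lambda
    if lam == 0:
        return 0.0
    return lam * sum(
        float((layer.params[k] ** 2).sum())
        for layer, k, is_kernel in network.parameters()
        if is_kernel
    )


def _add_l2_grads(network: AgeNetwork) -> None:
    lam = network.config.l2_lambda
    if lam == 0:
        return
    for layer, k, is_kernel in network.parameters():
        if is_kernel:
            layer.grads[k] += 2.0 * lam * layer.params[k]


def _tta_predict(
    network: AgeNetwork,
    features: np.ndarray,
    n_tta: int,
    rotation_deg: float,
    rng: np.random.Generator,
    batch_size: int = 32,
) -> np.ndarray:
    """Mean prediction over n_tta randomly rotated copies of each scan."""
    n = features.shape[0]
    preds = np.zeros((n_tta, n))
    for t in range(n_tta):
        aug = np.stack(
            [random_rotation(features[i], rotation_deg, rng) for i in range(n)]
        )
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            preds[t, lo:hi] = network.predict(aug[lo:hi])
    return preds.mean(axis=0)


def train(
    network: AgeNetwork,
    train_set: ScanDataset,
    val_set: ScanDataset,
    config: TrainingConfig | None = None,
) -> dict:
    """Train with RMSprop on MSE + L2; monitor validation MAE with TTA.

    Returns a history dict; the network is left holding the weights of the
    best validation epoch.  Train/validation subject sets must be disjoint
    (the split is made at the subject level to prevent leakage).
    """
    config = config or TrainingConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    overlap = set(train_set.subject_ids) & set(val_set.subject_ids)
    if overlap:
        raise LeakageError(f"subjects in both train and validation: {sorted(overlap)[:5]}")

    if config.init_output_bias_to_mean:
        network.dense_out.params["b"][:] = float(np.mean(train_set.ages))
    rng = np.random.default_rng(config.seed)
    opt = RMSprop(lr=config.initial_lr)
    schedule = LrStopSchedule(config.lr_patience_epochs, config.stop_patience_epochs)
    history = {"train_loss": [], "val_mae": [], "lr": []}
    best_snapshot = network.get_weights()
    n = len(train_set)

    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = np.stack(
                [
                    random_rotation(
                        train_set.features[i], config.train_rotation_deg, rng
                    )
                    for i in idx
                ]
            )
            yb = train_set.ages[idx]
            pred = network.forward(xb, training=True)
            err = pred - yb
            loss = float(np.mean(err**2)) + _l2_penalty(network)
            network.backward(2.0 * err / len(idx))
            _add_l2_grads(network)
            opt.step(network)
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        val_pred = _tta_predict(
            network,
            val_set.features,
            config.val_tta,
            config.val_rotation_deg,
            rng,
            batch_size=max(config.batch_size, 32),
        )
        val_mae = float(np.mean(np.abs(val_pred - val_set.ages)))
        history["val_mae"].append(val_mae)
        history["lr"].append(opt.lr)
        improved, drop, stop = schedule.update(val_mae)
        if improved:
            best_snapshot = network.get_weights()
        if drop:
            opt.lr /= config.lr_drop_factor
        if stop:
            break
    network.set_weights(best_snapshot)
    return history


# ---------------------------------------------------------------------------
# inference & evaluation
# ---------------------------------------------------------------------------

def predict_ensemble_tta(
    networks: Sequence[AgeNetwork],
    features: np.ndarray,
    config: InferenceConfig | None = None,
    rng: np.random.Generator | None = None,
    scan_id: str = "scan",
) -> AgePrediction:
    """Ensemble + TTA prediction for one scan: every (network, augmented
    copy) estimate is kept; the aggregate is their arithmetic mean."""
    config = config or InferenceConfig()
    rng = rng or np.random.default_rng(0)
    if not networks:
        raise ValueError("need at least one network")
    configs = {net.structure_config for net in networks}
    if len(configs) > 1:
        raise ValueError(f"mixed structure configurations in ensemble: {configs}")
    nets = list(networks)[: config.ensemble_size]
    raw = np.zeros((len(nets), config.test_tta))
    for t in range(config.test_tta):
        aug = random_rotation(features, config.rotation_deg, rng)
        for e, net in enumerate(nets):
            raw[e, t] = float(net.predict(aug[None])[0])
    return AgePrediction(
        scan_id=scan_id,
        structure_config=nets[0].structure_config,
        raw=raw,
        aggregated=float(raw.mean()),
    )


def predict_cohort(
    networks: Sequence[AgeNetwork],
    dataset: ScanDataset,
    config: InferenceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[AgePrediction]:
    """Ensemble + TTA predictions for every scan of a dataset (batched)."""
    config = config or InferenceConfig()
    rng = rng or np.random.default_rng(0)
    nets = list(networks)[: config.ensemble_size]
    configs = {net.structure_config for net in nets}
    if len(configs) > 1:
        raise ValueError(f"mixed structure configurations in ensemble: {configs}")
    n = len(dataset)
    raw = np.zeros((n, len(nets), config.test_tta))
    for t in range(config.test_tta):
        aug = np.stack(
            [
                random_rotation(dataset.features[i], config.rotation_deg, rng)
                for i in range(n)
            ]
        )
        for e, net in enumerate(nets):
            for lo in range(0, n, 32):
                hi = min(lo + 32, n)
                raw[lo:hi, e, t] = net.predict(aug[lo:hi])
    return [
        AgePrediction(
            scan_id=str(dataset.scan_ids[i]),
            structure_config=nets[0].structure_config,
            raw=raw[i],
            aggregated=float(raw[i].mean()),
        )
        for i in range(n)
    ]


def evaluate_predictions(
    predictions: Sequence[float] | np.ndarray,
    true_ages: Sequence[float] | np.ndarray,
) -> dict:
    """Mean absolute error, median absolute error and Pearson's r (years)."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(true_ages, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and true ages must have the same length")
    if p.size < 2:
        raise ValueError("need at least two scans to evaluate")
    err = np.abs(p - t)
    return {
        "MAE": float(err.mean()),
        "median_AE": float(np.median(err)),
        "pearson_r": float(pearsonr(p, t)[0]),
    }
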