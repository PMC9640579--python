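"""Feature-guided 1-D CNN for continuous knee-angle estimation.

The network maps one sEMG analysis window ``x`` to a scaled angle estimate

    y_hat = tanh(w_p . p + w_l . l)

where ``p`` is the 14-value handcrafted feature vector of the window and
``l`` is a 14-value learned feature vector produced by a five-layer 1-D conv
stack (2, 4, 8, 16, 32 filters with kernel lengths 5, 4, 3, 2, 1; each layer
is conv -> batch-norm -> LeakyReLU with a learnable negative slope ->
non-overlapping max-pool of length 2) followed by two fully connected layers
of 192 and 14 units.  Training minimizes the mean squared error between the
scaled measured angle and ``y_hat``; every weight — including the fusion
weights, whose gradients have the closed form implemented in
:func:`fusion_gradients` — is updated with bias-corrected Adam.

The unguided baseline (``guided=False``) is the same conv stack with a
28-unit feature head and ``y_hat = tanh(w_l . l)``; its 28 outputs are the
"CNN features" of the comparison study, against the 28 "FG-CNN features"
``[p, l]`` of the guided model.

Everything runs in NumPy on the CPU; forward and backward passes are
vectorized over the batch and training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import (
    DimensionError,
    EmptyInputError,
    NumericError,
    ParameterError,
    StateError,
)

__all__ = [
    "FGCNNConfig", "FGCNN", "BaselineCNN", "FGCNNResults",
    "conv_layer", "max_pool", "leaky_relu", "mse_loss",
    "fusion_gradients", "AdamState", "adam_update",
    "train_fgcnn", "train_baseline_cnn",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FGCNNConfig:
    """Architecture and optimizer settings.

    Defaults follow the reference architecture for a 50 ms window at 5 kHz
    (``input_len = 250``); ``input_len`` is configurable because the conv
    stack and the flatten size adapt to it.
    """

    input_len: int = 250
    conv_filters: tuple = (2, 4, 8, 16, 32)
    conv_kernels: tuple = (5, 4, 3, 2, 1)
    pool_len: int = 2
    fc_sizes: tuple = (192, 14)
    leaky_init_slope: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    standardize_p: bool = True   # z-score p by training stats before fusion
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    dtype: str = "float32"       # training precision; metrics/contracts are float64

    def __post_init__(self):
        self.conv_filters = tuple(self.conv_filters)
        self.conv_kernels = tuple(self.conv_kernels)
        self.fc_sizes = tuple(self.fc_sizes)
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ParameterError("conv_filters and conv_kernels must have equal length")
        if self.pool_len != 2:
            raise ParameterError("pooling is defined on non-overlapping pairs (length 2)")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ParameterError("decay rates must lie in (0, 1)")
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.dtype not in ("float32", "float64"):
            raise ParameterError("dtype must be 'float32' or 'float64'")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def leaky_relu(x, slope):
    """f(x) = x for x > 0, a*x otherwise (learnable a)."""
    return np.where(x > 0, x, slope * x)


def _same_pad(kernel_len: int):
    left = (kernel_len - 1) // 2
    return left, kernel_len - 1 - left


def conv_layer(x, kernels, bias, slope, bn=None):
    """One conv layer: 'same'-padded cross-correlation -> (BN) -> LeakyReLU.

    Parameters
    ----------
    x : ndarray, shape (B, L, D_in)
    kernels : ndarray, shape (K, D_in, D_out)
    bias : ndarray, shape (D_out,)
    slope : float
        LeakyReLU negative slope.
    bn : tuple (gamma, beta) or None
        Per-channel batch-norm affine parameters; None disables BN (used by
        the unit-level contract tests; training always enables it).
    """
    z = _conv_forward(np.asarray(x, dtype=float)[None] if np.asarray(x).ndim == 2 else np.asarray(x, dtype=float),
                      np.asarray(kernels, dtype=float))[0]
    z = z + bias
    if bn is not None:
        gamma, beta = bn
        mu = z.mean(axis=(0, 1))
        var = z.var(axis=(0, 1))
        z = gamma * (z - mu) / np.sqrt(var + 1e-5) + beta
    return leaky_relu(z, slope)


def _conv_forward(x, W):
    """'same' cross-correlation.  x: (B, L, Din), W: (K, Din, Dout)."""
    B, L, Din = x.shape
    K = W.shape[0]
    if K > L:
        raise DimensionError(f"kernel length {K} exceeds input length {L}")
    pl, pr = _same_pad(K)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B, L, Din, K)
    z = np.tensordot(cols, W, axes=([3, 2], [0, 1]))                # (B, L, Dout)
    return z, (xp, cols, K, pl)


def max_pool(y):
    """Non-overlapping pairwise max along the length axis (floor on odd L).

    Accepts (L, D) or (B, L, D); the length axis is the second-to-last.
    """
    y = np.asarray(y, dtype=float)
    L = y.shape[-2]
    if L < 2:
        raise DimensionError("max_pool needs length >= 2")
    Lp = L // 2
    a = y[..., : 2 * Lp : 2, :]
    b = y[..., 1 : 2 * Lp : 2, :]
    return np.maximum(a, b)


# ---------------------------------------------------------------------------
# loss, fusion gradients, Adam
# ---------------------------------------------------------------------------

def mse_loss(y, y_hat):
    """Mean squared error over a batch of scaled targets."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise EmptyInputError("empty batch")
    if y.shape != y_hat.shape:
        raise DimensionError("y and y_hat lengths differ")
    return float(np.mean((y - y_hat) ** 2))


def fusion_gradients(y, p, l, y_hat):
    """Closed-form gradients of the batch MSE w.r.t. the fusion weights.

    With ``y_hat = tanh(w_p . p + w_l . l)``,

        dMSE/dw_p = -(2/N) sum_i p_i (y_i - y_hat_i) (1 - y_hat_i^2)

    and symmetrically with ``l`` for ``w_l``.
    """
    y = np.asarray(y).ravel()
    y_hat = np.asarray(y_hat).ravel()
    p = np.atleast_2d(np.asarray(p))
    l = np.atleast_2d(np.asarray(l))
    N = y.size
    if p.shape[0] != N or l.shape[0] != N or y_hat.size != N:
        raise DimensionError("batch sizes of y, p, l, y_hat disagree")
    r = (y - y_hat) * (1.0 - y_hat ** 2)  # (N,)
    g_p = -(2.0 / N) * (p.T @ r)
    g_l = -(2.0 / N) * (l.T @ r)
    return g_p, g_l


@dataclass
class AdamState:
    """Per-tensor Adam moment accumulators and step counter."""

    s: np.ndarray  # first-moment estimate
    r: np.ndarray  # second-moment estimate
    t: int = 0

    @classmethod
    def zeros_like(cls, w) -> "AdamState":
        return cls(np.zeros_like(np.asarray(w, dtype=float)),
                   np.zeros_like(np.asarray(w, dtype=float)), 0)


def adam_update(weight, gradient, state: AdamState,
                lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
    """One bias-corrected Adam step; returns the new weight, mutates state.

        s <- b1 s + (1 - b1) g        r <- b2 r + (1 - b2) g^2
        w <- w - lr * (s / (1 - b1^t)) / (sqrt(r / (1 - b2^t)) + eps)
    """
    g = np.asarray(gradient)
    if not np.all(np.isfinite(g)):
        raise NumericError("non-finite gradient")
    if state.s.shape != g.shape:
        raise DimensionError("optimizer state shape does not match gradient")
    state.t += 1
    state.s = beta1 * state.s + (1.0 - beta1) * g
    state.r = beta2 * state.r + (1.0 - beta2) * g ** 2
    s_hat = state.s / (1.0 - beta1 ** state.t)
    r_hat = state.r / (1.0 - beta2 ** state.t)
    return np.asarray(weight) - lr * s_hat / (np.sqrt(r_hat) + eps)


class _Adam:
    """Adam over a dict of named parameter arrays (shared step counter).

    Parameters are packed into one flat buffer (``views`` exposes per-name
    views into it) so the whole update is a single fused kernel pass; the
    trajectory is identical to applying :func:`adam_update` tensor by tensor.
    """

    def __init__(self, params: dict, lr, beta1, beta2, eps):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.keys = list(params)
        sizes = [int(np.asarray(params[k]).size) for k in self.keys]
        offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        self._slices = {
            k: slice(int(offsets[i]), int(offsets[i + 1]))
            for i, k in enumerate(self.keys)
        }
        total = int(offsets[-1])
        dt = np.result_type(*[np.asarray(params[k]).dtype for k in self.keys])
        self.w = np.empty(total, dt)
        self.g = np.empty(total, dt)
        self.s = np.zeros(total, dt)
        self.r = np.zeros(total, dt)
        self.t = 0
        self.views = {}
        for k in self.keys:
            arr = np.asarray(params[k], dtype=dt)
            sl = self._slices[k]
            self.w[sl] = arr.ravel()
            self.views[k] = self.w[sl].reshape(arr.shape)

    def step(self, grads: dict) -> None:
        from . import _kernels as _k

        for k, sl in self._slices.items():
            self.g[sl] = np.asarray(grads[k]).ravel()
        self.t += 1
        _k.adam_flat(self.w, self.g, self.s, self.r, self.t,
                     self.lr, self.beta1, self.beta2, self.eps)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _feature_lengths(config: FGCNNConfig):
    """Length after each conv+pool stage, and the flatten width."""
    L = config.input_len
    lengths = []
    for _ in config.conv_filters:
        L = L // 2
        if L < 1:
            raise ParameterError("input_len too short for five pooling stages")
        lengths.append(L)
    return lengths, lengths[-1] * config.conv_filters[-1]


def _init_params(config: FGCNNConfig, guided: bool, rng: np.random.Generator) -> dict:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    p: dict = {}
    d_in = 1
    for i, (K, d_out) in enumerate(zip(config.conv_kernels, config.conv_filters)):
        bound = 1.0 / np.sqrt(K * d_in)
        p[f"conv{i}_W"] = rng.uniform(-bound, bound, size=(K, d_in, d_out))
        p[f"conv{i}_b"] = rng.uniform(-bound, bound, size=d_out)
        p[f"bn{i}_gamma"] = np.ones(d_out)
        p[f"bn{i}_beta"] = np.zeros(d_out)
        p[f"slope{i}"] = np.array(config.leaky_init_slope)
        d_in = d_out
    _, flat = _feature_lengths(config)
    h1, n_feat = config.fc_sizes
    bound = 1.0 / np.sqrt(flat)
    p["fc1_W"] = rng.uniform(-bound, bound, size=(flat, h1))
    p["fc1_b"] = rng.uniform(-bound, bound, size=h1)
    p["slope_fc1"] = np.array(config.leaky_init_slope)
    bound = 1.0 / np.sqrt(h1)
    p["fc2_W"] = rng.uniform(-bound, bound, size=(h1, n_feat))
    p["fc2_b"] = rng.uniform(-bound, bound, size=n_feat)
    if guided:
        bound = 1.0 / np.sqrt(n_feat)
        p["w_p"] = rng.uniform(-bound, bound, size=n_feat)
        p["w_l"] = rng.uniform(-bound, bound, size=n_feat)
    else:
        bound = 1.0 / np.sqrt(n_feat)
        p["w_l"] = rng.uniform(-bound, bound, size=n_feat)
    return p


class _Network:
    """Forward/backward passes over the parameter dict (internal)."""

    def __init__(self, config: FGCNNConfig, guided: bool):
        self.cfg = config
        self.guided = guided
        self.n_conv = len(config.conv_filters)
        # batch-norm running statistics (not optimized)
        self.running = {
            f"bn{i}": (np.zeros(d), np.ones(d))
            for i, d in enumerate(config.conv_filters)
        }

    # -- forward ----------------------------------------------------------
    def forward(self, params, X, P_std=None, train=False):
        """X: (B, input_len); P_std: (B, 14) standardized handcrafted features."""
        cfg = self.cfg
        if X.shape[1] != cfg.input_len:
            raise DimensionError(
                f"window length {X.shape[1]} != configured input_len {cfg.input_len}"
            )
        if not np.all(np.isfinite(X)):
            raise NumericError("non-finite sEMG window")
        from . import _kernels as _k

        caches = []
        a = np.ascontiguousarray(X[:, :, None])
        for i in range(self.n_conv):
            W = params[f"conv{i}_W"]
            pl = _same_pad(W.shape[0])[0]
            z = _k.conv_same_fwd(a, W, params[f"conv{i}_b"], pl)
            rm, rv = self.running[f"bn{i}"]
            if train:
                mu, var = _k.bn_stats(z)
                m = z.shape[0] * z.shape[1]
                mom = cfg.bn_momentum
                self.running[f"bn{i}"] = (
                    (1 - mom) * rm + mom * mu,
                    (1 - mom) * rv + mom * var * m / max(m - 1, 1),
                )
            else:
                mu, var = rm, rv
            ivar = (1.0 / np.sqrt(var + cfg.bn_eps)).astype(z.dtype)
            mu = np.asarray(mu, dtype=z.dtype)
            slope = z.dtype.type(params[f"slope{i}"])
            pooled, xhat, zbn, take_first = _k.bn_leaky_pool_fwd(
                z, mu, ivar, params[f"bn{i}_gamma"], params[f"bn{i}_beta"], slope
            )
            caches.append((a, pl, xhat, ivar, zbn, take_first))
            a = pooled
        B = X.shape[0]
        flat = a.reshape(B, -1)
        h1_z = flat @ params["fc1_W"] + params["fc1_b"]
        h1 = leaky_relu(h1_z, params["slope_fc1"])
        l = h1 @ params["fc2_W"] + params["fc2_b"]
        if self.guided:
            z_out = P_std @ params["w_p"] + l @ params["w_l"]
        else:
            z_out = l @ params["w_l"]
        y_hat = np.tanh(z_out)
        cache = (caches, a.shape, flat, h1_z, h1, l, P_std, y_hat)
        return l, y_hat, cache

    # -- backward ---------------------------------------------------------
    def backward(self, params, y, cache):
        """Gradients of the batch MSE w.r.t. every parameter."""
        cfg = self.cfg
        caches, pooled_shape, flat, h1_z, h1, l, P_std, y_hat = cache
        B = y.shape[0]
        grads = {}
        # fusion layer: closed-form gradients
        if self.guided:
            g_p, g_l = fusion_gradients(y, P_std, l, y_hat)
            grads["w_p"], grads["w_l"] = g_p, g_l
        else:
            _, g_l = fusion_gradients(y, np.zeros_like(l), l, y_hat)
            grads["w_l"] = g_l
        dz_out = -(2.0 / B) * (y - y_hat) * (1.0 - y_hat ** 2)  # (B,)
        dl = dz_out[:, None] * params["w_l"][None, :]
        grads["fc2_W"] = h1.T @ dl
        grads["fc2_b"] = dl.sum(axis=0)
        dh1 = dl @ params["fc2_W"].T
        slope = params["slope_fc1"]
        grads["slope_fc1"] = np.array(np.sum(dh1 * np.where(h1_z > 0, 0.0, h1_z)))
        dh1_z = dh1 * np.where(h1_z > 0, 1.0, slope)
        grads["fc1_W"] = flat.T @ dh1_z
        grads["fc1_b"] = dh1_z.sum(axis=0)
        dflat = dh1_z @ params["fc1_W"].T
        da = np.ascontiguousarray(dflat.reshape(pooled_shape))
        from . import _kernels as _k

        for i in reversed(range(self.n_conv)):
            a_in, pl, xhat, ivar, zbn, take_first = caches[i]
            slope = xhat.dtype.type(params[f"slope{i}"])
            dz, dgamma, dbeta, dslope = _k.bn_leaky_pool_bwd(
                da, xhat, zbn, take_first, params[f"bn{i}_gamma"], slope, ivar
            )
            grads[f"slope{i}"] = np.array(dslope)
            grads[f"bn{i}_gamma"] = dgamma
            grads[f"bn{i}_beta"] = dbeta
            da, dW, db = _k.conv_same_bwd(dz, a_in, params[f"conv{i}_W"], pl, i > 0)
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

_SCHEMA = "emgknee-fgcnn-checkpoint-v1"


class FGCNN:
    """Feature-guided CNN model, statsmodels-style: build then :meth:`fit`.

    Parameters
    ----------
    windows : ndarray (N, input_len)
        sEMG analysis windows, millivolts.
    handcrafted : ndarray (N, 14)
        Handcrafted feature vector per window (raw scale).
    targets_scaled : ndarray (N,)
        Measured angles affinely scaled into [-1, 1] (training-set extrema).
    config : FGCNNConfig, optional
    """

    guided = True

    def __init__(self, windows, handcrafted, targets_scaled, config=None):
        self.config = config or FGCNNConfig(input_len=np.asarray(windows).shape[1])
        self.windows = np.ascontiguousarray(windows, dtype=float)
        self.targets = np.asarray(targets_scaled, dtype=float).ravel()
        if self.windows.shape[0] == 0:
            raise EmptyInputError("empty dataset")
        if np.max(np.abs(self.targets)) > 1.0 + 1e-12:
            raise ParameterError("targets must be scaled to [-1, 1] before training")
        if self.guided:
            self.handcrafted = np.asarray(handcrafted, dtype=float)
            if self.handcrafted.shape != (self.windows.shape[0], self.config.fc_sizes[1]):
                raise DimensionError(
                    f"handcrafted matrix must be (N, {self.config.fc_sizes[1]})"
                )
        else:
            self.handcrafted = None

    @classmethod
    def from_dataset(cls, dataset, scaler, config=None, zc_threshold=0.0, ssc_threshold=0.0):
        """Build from a :class:`~emgknee.signal_io.WindowedDataset` and a fitted scaler."""
        from .handcrafted_features import feature_matrix

        p = feature_matrix(dataset.windows, zc_threshold, ssc_threshold) if cls.guided else None
        return cls(dataset.windows, p, scaler.scale(dataset.targets_deg), config=config)

    def fit(self, seed=0, shuffle=True) -> "FGCNNResults":
        """Train with Adam for ``config.epochs`` epochs; deterministic per seed."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        params = _init_params(cfg, self.guided, rng)
        net = _Network(cfg, self.guided)
        if self.guided and cfg.standardize_p:
            p_mean = self.handcrafted.mean(axis=0)
            p_std = self.handcrafted.std(axis=0)
            p_std[p_std == 0] = 1.0
        else:
            p_mean = np.zeros(cfg.fc_sizes[1])
            p_std = np.ones(cfg.fc_sizes[1])
        dt = np.dtype(cfg.dtype)
        P = ((self.handcrafted - p_mean) / p_std).astype(dt) if self.guided else None
        X = self.windows.astype(dt, copy=False)
        y = self.targets.astype(dt, copy=False)
        N = X.shape[0]
        params = {k: v.astype(dt) for k, v in params.items()}
        opt = _Adam(params, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
        params = opt.views  # parameters now live in the optimizer's flat buffer
        loss_history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(N) if shuffle else np.arange(N)
            sq_sum = 0.0
            for start in range(0, N, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Pb = P[idx] if self.guided else None
                _, y_hat, cache = net.forward(params, X[idx], Pb, train=True)
                sq_sum += float(np.sum((y[idx] - y_hat) ** 2))
                grads = net.backward(params, y[idx], cache)
                opt.step(grads)
            loss_history.append(sq_sum / N)
        params = {k: v.copy() for k, v in params.items()}
        return FGCNNResults(self, params, net, np.array(loss_history),
                            p_mean, p_std, seed)


class BaselineCNN(FGCNN):
    """Unguided baseline: same conv stack, 28 learned features, no fusion input.

    ``handcrafted`` is accepted for interface symmetry and ignored; pass None.
    """

    guided = False

    def __init__(self, windows, handcrafted=None, targets_scaled=None, config=None):
        if config is None:
            config = FGCNNConfig(input_len=np.asarray(windows).shape[1],
                                 fc_sizes=(192, 28))
        super().__init__(windows, None, targets_scaled, config=config)


class FGCNNResults:
    """Trained parameters, loss history and feature/prediction interfaces."""

    def __init__(self, model, params, net, loss_history, p_mean, p_std, seed):
        self.model = model
        self.config = model.config
        self.params = params
        self._net = net
        self.loss_history = loss_history
        self.p_mean = p_mean
        self.p_std = p_std
        self.seed = seed

    # -- inference --------------------------------------------------------
    def _forward_eval(self, windows, handcrafted, batch=1024):
        dt = self.params["fc1_W"].dtype
        X = np.ascontiguousarray(windows, dtype=dt)
        if self.model.guided:
            if handcrafted is None:
                raise DimensionError("guided model needs the handcrafted matrix")
            P = (((np.asarray(handcrafted, dtype=float) - self.p_mean) / self.p_std)
                 .astype(dt))
        else:
            P = None
        ls, ys = [], []
        for start in range(0, X.shape[0], batch):
            sl = slice(start, start + batch)
            l, y_hat, _ = self._net.forward(
                self.params, X[sl], P[sl] if P is not None else None, train=False
            )
            ls.append(l)
            ys.append(y_hat)
        return np.concatenate(ls), np.concatenate(ys)

    def predict_scaled(self, windows, handcrafted=None):
        """Fusion-head output tanh(w_p.p + w_l.l) in (-1, 1) per window."""
        return self._forward_eval(windows, handcrafted)[1]

    def extract_features(self, windows, handcrafted=None):
        """Feature matrix for a regressor.

        Guided model: (N, 28) ``[p, l]`` whose first 14 columns are the
        handcrafted matrix bit-for-bit.  Baseline: the (N, 28) learned
        features.  Inference mode (frozen batch-norm): repeated calls with
        the same inputs are identical.
        """
        if self.params is None:
            raise StateError("model not trained")
        l, _ = self._forward_eval(windows, handcrafted)
        if self.model.guided:
            return np.hstack([np.asarray(handcrafted, dtype=float), l])
        return l

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lengths, flat = _feature_lengths(cfg)
        n_params = sum(int(np.asarray(v).size) for v in self.params.values())
        kind = "FG-CNN (guided)" if self.model.guided else "CNN baseline (unguided)"
        lines = [
            f"{kind}",
            "=" * 46,
            f"input length        {cfg.input_len}",
            f"conv filters        {cfg.conv_filters}",
            f"conv kernels        {cfg.conv_kernels}",
            f"lengths after pool  {tuple(lengths)}",
            f"flatten -> FC       {flat} -> {cfg.fc_sizes[0]} -> {cfg.fc_sizes[1]}",
            f"trainable params    {n_params}",
            f"epochs / lr / batch {cfg.epochs} / {cfg.learning_rate} / {cfg.batch_size}",
            f"seed                {self.seed}",
            f"training MSE        {self.loss_history[0]:.6f} -> {self.loss_history[-1]:.6f}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: config echo, parameters, BN stats."""
        arrays = {f"param::{k}": np.asarray(v) for k, v in self.params.items()}
        for k, (rm, rv) in self._net.running.items():
            arrays[f"running::{k}::mean"] = rm
            arrays[f"running::{k}::var"] = rv
        arrays["p_mean"] = self.p_mean
        arrays["p_std"] = self.p_std
        arrays["loss_history"] = self.loss_history
        meta = {"schema": _SCHEMA, "guided": self.model.guided,
                "seed": int(self.seed), "config": self.config.to_dict()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FGCNNResults":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("schema") != _SCHEMA:
                raise StateError(f"unknown checkpoint schema {meta.get('schema')!r}")
            cfg = FGCNNConfig(**meta["config"])
            guided = meta["guided"]
            params = {k.split("::", 1)[1]: z[k] for k in z.files if k.startswith("param::")}
            net = _Network(cfg, guided)
            for key in list(net.running):
                net.running[key] = (z[f"running::{key}::mean"], z[f"running::{key}::var"])
            dummy = cls.__new__(cls)
            model = FGCNN.__new__(FGCNN) if guided else BaselineCNN.__new__(BaselineCNN)
            model.config = cfg
            model.guided = guided
            dummy.model = model
            dummy.config = cfg
            dummy.params = params
            dummy._net = net
            dummy.loss_history = z["loss_history"]
            dummy.p_mean = z["p_mean"]
            dummy.p_std = z["p_std"]
            dummy.seed = meta["seed"]
            return dummy


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_fgcnn(windows, handcrafted, targets_scaled, config=None, seed=0):
    """Train the guided model; returns :class:`FGCNNResults`."""
    return FGCNN(windows, handcrafted, targets_scaled, config=config).fit(seed=seed)


def train_baseline_cnn(windows, targets_scaled, config=None, seed=0):
    """Train the unguided baseline; returns :class:`FGCNNResults`."""
    return BaselineCNN(windows, None, targets_scaled, config=config).fit(seed=seed)
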