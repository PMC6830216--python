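"""The 3D convolutional resolution regressor.

Architecture (fixed):
    conv(32 filters of 13x13x13, dimension-preserving zero padding, ReLU)
    -> dropout(p=0.25)
    -> flatten
    -> dense(512, ReLU)
    -> dense(1, linear)

trained with Adam on a mean-squared-error loss over Angstrom-valued labels.

The implementation is pure numpy + BLAS, written for a single CPU with
limited memory bandwidth:

* The convolution is evaluated as a batched matrix product against an
  im2col matrix built kernel-major by three axis-wise window expansions
  (contiguous writes only); the matrix is reused for the weight gradient.
  Because the convolution is the first layer no input gradient is needed.
* All large workspaces are allocated once per micro-batch size and reused.
* Weight-gradient accumulation over micro-batches goes through BLAS
  ``sgemm`` with ``beta=1`` to avoid temporary allocations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import blas as _blas

from .boxes import BOX_EDGE, BandSpec, BoxSet
from .map_io import ValidationError

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "TrainedRegressor",
    "build",
    "train",
    "predict",
    "save_regressor",
    "load_regressor",
]

_E = BOX_EDGE  # 13
_NPOS = _E**3  # 2197 output positions = kernel taps
_PAD = _E // 2  # 6, zero padding for dimension-preserving convolution


@dataclass
class NetworkConfig:
    """Fixed topology; fields exist for documentation and checkpoints."""

    conv_filters: int = 32
    conv_kernel: int = _E
    dense_units: int = 512
    output_units: int = 1
    dropout_p: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.conv_filters, self.conv_kernel, self.dense_units, self.output_units) != (
            32,
            _E,
            512,
            1,
        ):
            raise ValidationError("network topology is fixed: conv(32x13^3) -> dense(512) -> dense(1)")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError("dropout_p must be in [0, 1)")


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    validation_fraction: float = 0.1
    seed: int = 0
    micro_batch: int = 16  # workspace granularity; no effect on the math
    augment: bool = False  # random proper rotations of each cube per epoch
    lr_decay: float = 1.0  # per-epoch multiplicative learning-rate decay

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValidationError("validation_fraction must be in [0, 1)")


@dataclass
class TrainedRegressor:
    """Network weights plus the band metadata required for valid inference."""

    params: dict[str, np.ndarray]
    band: BandSpec
    config: NetworkConfig = field(default_factory=NetworkConfig)
    provenance: dict = field(default_factory=dict)
    loss_history: list[dict] = field(default_factory=list)

    @property
    def label_range(self) -> tuple[float, float]:
        return self.band.label_range


def _gemm_c(a: np.ndarray, b: np.ndarray, c: np.ndarray, beta: float = 0.0) -> None:
    """``c = a @ b + beta * c`` in place for C-contiguous float32 matrices.

    Implemented as ``c.T = b.T @ a.T`` so BLAS sees Fortran-contiguous views
    and never copies.
    """
    out = _blas.sgemm(1.0, b.T, a.T, beta=beta, c=c.T, overwrite_c=1)
    if out.base is not c and out is not c.T:  # pragma: no cover - sanity guard
        c.T[...] = out


class _Workspaces:
    """Preallocated buffers for one micro-batch size."""

    def __init__(self, m: int, dense_in: int, dense_units: int):
        np3 = _E + 2 * _PAD  # 25
        self.m = m
        self.xp = np.zeros((m, np3, np3, np3), np.float32)
        self.A = np.empty((m, _E, _E, np3, np3), np.float32)
        self.B2 = np.empty((m, _E, _E, _E, _E, np3), np.float32)
        self.col = np.empty((m, _NPOS, _NPOS), np.float32)
        self.z1 = np.empty((m, 32, _NPOS), np.float32)
        self.gmask = np.empty((m, 32, _NPOS), np.float32)
        self.z2 = np.empty((m, dense_units), np.float32)
        self.a2 = np.empty((m, dense_units), np.float32)
        self.dz1 = np.empty((m, 32, _NPOS), np.float32)
        self.dxf = np.empty((m, dense_in), np.float32)
        self.dk_tmp = np.empty((m, 32, _NPOS), np.float32)


def _im2col(x: np.ndarray, ws: _Workspaces) -> np.ndarray:
    """Kernel-major im2col: returns view ``(m, taps, positions)``.

    ``col[b, (a,b2,c), (i,j,k)] = xpad[b, i+a, j+b2, k+c]`` so that
    ``K_flat @ col`` is the 'same'-padded cross-correlation, matching the
    orientation of standard deep-learning convolution layers.
    """
    m = x.shape[0]
    e, p = _E, _PAD
    xp, A, B2 = ws.xp[:m], ws.A[:m], ws.B2[:m]
    col6 = ws.col[:m].reshape(m, e, e, e, e, e, e)
    xp[:, p : p + e, p : p + e, p : p + e] = x
    for a in range(e):
        A[:, a] = xp[:, a : a + e]
    for b2 in range(e):
        B2[:, :, b2] = A[:, :, :, b2 : b2 + e]
    for c in range(e):
        col6[:, :, :, c] = B2[:, :, :, :, :, c : c + e]
    return ws.col[:m]


def _proper_rotations() -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """The 24 orientation-preserving symmetries of the cube as
    (axis permutation, per-axis sign) pairs with det = +1."""
    from itertools import permutations, product

    out = []
    for perm in permutations((0, 1, 2)):
        perm_parity = 1 if perm in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else -1
        for signs in product((1, -1), repeat=3):
            if perm_parity * signs[0] * signs[1] * signs[2] == 1:
                out.append((perm, signs))
    return out


_ROTATIONS = _proper_rotations()


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly rotate each cube by one of the 24 proper cube rotations.

    Labels are isotropic-filter cutoffs, hence rotation-invariant.
    """
    out = np.empty_like(x)
    choices = rng.integers(0, len(_ROTATIONS), size=len(x))
    for i, c in enumerate(choices):
        perm, signs = _ROTATIONS[c]
        cube = np.transpose(x[i], perm)
        out[i] = cube[:: signs[0], :: signs[1], :: signs[2]]
    return out


def _init_params(config: NetworkConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    dense_in = 32 * _NPOS
    params = {
        "Kc": (rng.standard_normal((32, _NPOS)) * np.sqrt(2.0 / _NPOS)).astype(np.float32),
        "bc": np.zeros(32, np.float32),
        "W1": (rng.standard_normal((dense_in, 512)) * np.sqrt(2.0 / dense_in)).astype(np.float32),
        "b1": np.zeros(512, np.float32),
        "W2": (rng.standard_normal((512, 1)) * np.sqrt(1.0 / 512)).astype(np.float32),
        "b2": np.zeros(1, np.float32),
    }
    return params


def build(config: NetworkConfig | None = None, band: BandSpec | None = None) -> TrainedRegressor:
    """Create an untrained regressor with deterministic (seeded) weights."""
    from .boxes import wide_band

    config = config or NetworkConfig()
    band = band or wide_band()
    return TrainedRegressor(params=_init_params(config), band=band, config=config)


def conv_forward(params: dict, x: np.ndarray, ws: _Workspaces) -> np.ndarray:
    """Convolution layer output before activation, shape ``(m, 32, 2197)``."""
    m = x.shape[0]
    col = _im2col(x, ws)
    z1 = ws.z1[:m]
    np.matmul(params["Kc"][None], col, out=z1)
    z1 += params["bc"][None, :, None]
    return z1


def _forward(
    params: dict,
    x: np.ndarray,
    ws: _Workspaces,
    train_mode: bool = False,
    dropout_p: float = 0.25,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward pass on a micro-batch ``x (m, 13, 13, 13)``; returns ``(m,)``."""
    m = x.shape[0]
    z1 = conv_forward(params, x, ws)
    # ReLU + (optionally) inverted dropout; gmask keeps d(activation)/d(z1).
    gmask = ws.gmask[:m]
    gmask[...] = z1 > 0
    if train_mode and dropout_p > 0.0:
        keep = (rng.random(z1.shape) >= dropout_p).astype(np.float32)
        keep /= 1.0 - dropout_p
        gmask *= keep
    np.multiply(z1, gmask, out=z1)  # z1 now holds the dropped activation
    xf = z1.reshape(m, -1)

    z2, a2 = ws.z2[:m], ws.a2[:m]
    _gemm_c(xf, params["W1"], z2)
    z2 += params["b1"]
    np.maximum(z2, 0.0, out=a2)
    y = a2 @ params["W2"] + params["b2"]
    return y[:, 0]


def _backward(
    params: dict,
    grads: dict,
    ws: _Workspaces,
    dy: np.ndarray,
    accumulate: bool,
) -> None:
    """Backpropagate ``dy (m,)``; adds into ``grads`` when ``accumulate``.

    Uses the activations left in the workspaces by the preceding
    :func:`_forward` call.
    """
    m = dy.shape[0]
    beta = 1.0 if accumulate else 0.0
    a2, z2 = ws.a2[:m], ws.z2[:m]
    xf = ws.z1[:m].reshape(m, -1)
    col = ws.col[:m]

    dyc = np.ascontiguousarray(dy[:, None], dtype=np.float32)  # (m, 1)
    if accumulate:
        grads["b2"] += dyc.sum(0)
    else:
        grads["b2"][...] = dyc.sum(0)
    _gemm_c(np.ascontiguousarray(a2.T), dyc, grads["W2"], beta=beta)

    da2 = dyc @ params["W2"].T  # (m, 512), small
    dz2 = np.ascontiguousarray(da2 * (z2 > 0), dtype=np.float32)
    if accumulate:
        grads["b1"] += dz2.sum(0)
    else:
        grads["b1"][...] = dz2.sum(0)
    # dW1 (+)= xf^T @ dz2, in place via dW1^T = dz2^T @ (xf^T)^T; all operands
    # are Fortran-contiguous views so BLAS never copies.
    out = _blas.sgemm(
        1.0, dz2.T, xf.T, beta=beta, c=grads["W1"].T, trans_b=1, overwrite_c=1
    )
    if out.base is not grads["W1"]:  # pragma: no cover - BLAS fell back to a copy
        grads["W1"].T[...] = out

    # dxf = dz2 @ W1^T, in place via dxf^T = (W1^T)^T @ dz2^T
    dxf = ws.dxf[:m]
    out = _blas.sgemm(1.0, params["W1"].T, dz2.T, c=dxf.T, trans_a=1, overwrite_c=1)
    if out.base is not dxf:  # pragma: no cover
        dxf.T[...] = out

    dz1 = ws.dz1[:m]
    np.multiply(dxf.reshape(m, 32, _NPOS), ws.gmask[:m], out=dz1)
    if accumulate:
        grads["bc"] += dz1.sum(axis=(0, 2))
    else:
        grads["bc"][...] = dz1.sum(axis=(0, 2))
    np.matmul(dz1, col.transpose(0, 2, 1), out=ws.dk_tmp[:m])
    if accumulate:
        grads["Kc"] += ws.dk_tmp[:m].sum(0)
    else:
        grads["Kc"][...] = ws.dk_tmp[:m].sum(0)


try:  # fused single-pass update: large parameter tensors are bandwidth-bound
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _adam_fused(w, g, m, v, lr_t, b1, b2, eps):  # pragma: no cover - jitted
        for i in range(w.size):
            mi = b1 * m[i] + (1.0 - b1) * g[i]
            vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            m[i] = mi
            v[i] = vi
            w[i] -= lr_t * mi / (np.sqrt(vi) + eps)

except Exception:  # pragma: no cover - numba unavailable
    _adam_fused = None


class _Adam:
    """Adam with a single shared scratch buffer (memory-traffic frugal)."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        biggest = max(v.size for v in params.values())
        self._scratch = np.empty(biggest, np.float32)

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for key, w in params.items():
            g, m, v = grads[key], self.m[key], self.v[key]
            if _adam_fused is not None and w.size > 1 << 16:
                _adam_fused(
                    w.reshape(-1), g.reshape(-1), m.reshape(-1), v.reshape(-1),
                    np.float32(lr_t), np.float32(self.b1), np.float32(self.b2),
                    np.float32(self.eps),
                )
                continue
            s = self._scratch[: w.size].reshape(w.shape)
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=s)
            m += s
            v *= self.b2
            np.square(g, out=s)
            s *= 1.0 - self.b2
            v += s
            np.sqrt(v, out=s)
            s += self.eps
            np.divide(m, s, out=s)
            s *= lr_t
            w -= s


def train(
    reg: TrainedRegressor,
    box_set: BoxSet,
    tc: TrainingConfig | None = None,
) -> TrainedRegressor:
    """Minimise MSE with Adam; returns ``reg`` with updated weights in place.

    Labels must lie within the regressor's band; a validation split (held
    out by seed) is evaluated per epoch when the corpus is large enough.
    """
    tc = tc or TrainingConfig()
    n = len(box_set)
    if n == 0:
        raise ValidationError("empty training corpus")
    d_min, d_max = reg.label_range
    bad = (box_set.labels < d_min - 1e-6) | (box_set.labels > d_max + 1e-6)
    if bad.any():
        offender = float(box_set.labels[bad][0])
        raise ValidationError(
            f"label {offender} A outside the regressor band [{d_min}, {d_max}] A"
        )

    rng = np.random.default_rng(tc.seed)
    drop_rng = np.random.default_rng(tc.seed + 1)
    order = rng.permutation(n)
    n_val = int(round(n * tc.validation_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]

    cubes = box_set.cubes
    labels = box_set.labels.astype(np.float32)
    params = reg.params
    if float(params["b2"][0]) == 0.0:
        params["b2"][0] = float(labels[train_idx].mean())  # start at the label mean

    micro = max(1, min(tc.micro_batch, tc.batch_size))
    ws = _Workspaces(micro, 32 * _NPOS, 512)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    opt = _Adam(params, tc.learning_rate)

    history: list[dict] = []
    for epoch in range(tc.epochs):
        opt.lr = tc.learning_rate * tc.lr_decay**epoch
        perm = rng.permutation(len(train_idx))
        idx = train_idx[perm]
        sq_sum, seen = 0.0, 0
        for b0 in range(0, len(idx), tc.batch_size):
            batch = idx[b0 : b0 + tc.batch_size]
            first = True
            for m0 in range(0, len(batch), micro):
                sel = batch[m0 : m0 + micro]
                x = cubes[sel]
                if tc.augment:
                    x = _augment_batch(x, drop_rng)
                t = labels[sel]
                y = _forward(
                    params, x, ws, train_mode=True, dropout_p=reg.config.dropout_p, rng=drop_rng
                )
                resid = y - t
                sq_sum += float(np.sum(resid**2))
                seen += len(sel)
                dy = (2.0 / len(batch)) * resid
                _backward(params, grads, ws, dy, accumulate=not first)
                first = False
            opt.step(params, grads)
        entry = {"epoch": epoch, "train_mse": sq_sum / max(seen, 1)}
        if len(val_idx):
            val_pred = _predict_array(params, cubes[val_idx], ws)
            entry["val_mse"] = float(np.mean((val_pred - labels[val_idx]) ** 2))
        history.append(entry)

    reg.loss_history = history
    reg.provenance.setdefault("training", {})
    reg.provenance["training"] = {
        "n_boxes": int(n),
        "config": {
            "learning_rate": tc.learning_rate,
            "batch_size": tc.batch_size,
            "epochs": tc.epochs,
            "validation_fraction": tc.validation_fraction,
            "seed": tc.seed,
        },
        "corpus_labels": sorted(set(float(v) for v in np.unique(labels))),
    }
    return reg


def _predict_array(params: dict, cubes: np.ndarray, ws: _Workspaces) -> np.ndarray:
    out = np.empty(len(cubes), np.float32)
    m = ws.m
    for i0 in range(0, len(cubes), m):
        x = cubes[i0 : i0 + m]
        out[i0 : i0 + len(x)] = _forward(params, x, ws, train_mode=False)
    return out


def predict(
    reg: TrainedRegressor,
    cubes: np.ndarray,
    batch: int = 16,
    norm_tol: float = 1e-3,
) -> np.ndarray:
    """Predict one Angstrom value per unit-norm 13^3 cube, clipped to the band.

    Raises when a cube violates the unit-norm training contract by more
    than ``norm_tol``.
    """
    cubes = np.asarray(cubes, dtype=np.float32)
    if cubes.ndim == 3:
        cubes = cubes[None]
    if cubes.shape[1:] != (_E, _E, _E):
        raise ValidationError(f"cubes must be (n, {_E}, {_E}, {_E}), got {cubes.shape}")
    if len(cubes) == 0:
        return np.zeros(0, np.float32)
    norms = np.linalg.norm(cubes.reshape(len(cubes), -1), axis=1)
    worst = float(np.abs(norms - 1.0).max())
    if worst > norm_tol:
        raise ValidationError(
            f"input cube norm deviates from 1 by {worst:.2e} (> {norm_tol}); "
            "boxes must be L2-normalised exactly as in training"
        )
    ws = _Workspaces(min(batch, len(cubes)), 32 * _NPOS, 512)
    raw = _predict_array(reg.params, cubes, ws)
    d_min, d_max = reg.label_range
    return np.clip(raw, d_min, d_max)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_regressor(path: str | Path, reg: TrainedRegressor) -> None:
    meta = {
        "band": reg.band.to_dict(),
        "config": {
            "conv_filters": reg.config.conv_filters,
            "conv_kernel": reg.config.conv_kernel,
            "dense_units": reg.config.dense_units,
            "output_units": reg.config.output_units,
            "dropout_p": reg.config.dropout_p,
            "seed": reg.config.seed,
        },
        "provenance": reg.provenance,
        "loss_history": reg.loss_history,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **reg.params)


def load_regressor(path: str | Path) -> TrainedRegressor:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends .npz
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        params = {k: data[k] for k in ("Kc", "bc", "W1", "b1", "W2", "b2")}
    cfg = NetworkConfig(**meta["config"])
    reg = TrainedRegressor(
        params=params,
        band=BandSpec.from_dict(meta["band"]),
        config=cfg,
        provenance=meta.get("provenance", {}),
        loss_history=meta.get("loss_history", []),
    )
    return reg


def write_loss_history_csv(path: str | Path, reg: TrainedRegressor) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        fields = sorted({k for row in reg.loss_history for k in row})
        writer = csv.DictWriter(fh, fieldnames=fields or ["epoch", "train_mse"])
        writer.writeheader()
        for row in reg.loss_history:
            writer.writerow(row)
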