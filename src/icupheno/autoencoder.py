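"""Masking-aware bidirectional-GRU sequence autoencoder, in plain numpy.

The model compresses one admission's irregular multivariate time series into a
single fixed-size feature vector (the bottleneck) and reconstructs the series
from it.  Architecture:

* **GRU block** — two GRU layers, one reading the sequence forward and one
  backward; their per-step outputs are summed and layer-normalized.  Dropout
  acts on the non-recurrent (input) connections of each GRU layer.  The gate
  activations are sigmoid; the candidate ("non-recurrent") activation is ELU.
* **Encoder** — GRU block over the full input (dynamic + static + temporal
  columns), masked mean over the valid time steps, then a linear dense layer
  down to the bottleneck (46 dimensions by default; odd sizes round up so the
  feature space stays even-dimensional).
* **Decoder** — the bottleneck is repeated along time, the input's temporal
  features are re-appended (the decoder cannot know *when* to place values
  otherwise, since time is not on a regular grid), a second GRU block with its
  own weights runs over that, and a linear dense layer applied at each time
  step emits the reconstruction of the dynamic + static columns.  Temporal
  columns are inputs only, never reconstruction targets.

Training uses Adam with Huber loss computed only over mask-valid rows,
gradient-norm clipping, Gaussian input noise on the dynamic columns only
(never on the targets or temporal columns), mini-batches padded to the longest
admission in the batch, and early stopping on validation loss with
best-weight restoration.  Gradients are hand-derived backpropagation; a
numerical-gradient test pins them down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import AdmissionMatrix, Normalizer, assemble_batch, pad_batch

logger = logging.getLogger("icupheno")


@dataclass(frozen=True)
class ModelHyperparams:
    gru_size: int = 158
    bottleneck_size: int = 46
    nonrecurrent_dropout: float = 0.267
    nonrecurrent_activation: str = "elu"
    noise_sigma: float = 0.0573

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonrecurrent_dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.gru_size < 1 or self.bottleneck_size < 1:
            raise ValueError("layer sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.00075
    huber_delta: float = 1.0
    grad_clip_norm: float = 1.0
    batch_size: int = 4
    early_stop_patience_epochs: int = 8
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "huber_delta", "grad_clip_norm",
                     "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class FeatureMatrix:
    """One bottleneck embedding per admission."""

    admission_ids: list[str]
    embeddings: np.ndarray  # (N, bottleneck_size)

    def __post_init__(self) -> None:
        if self.embeddings.shape[0] != len(self.admission_ids):
            raise ValueError("one embedding row per admission id is required")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite entries")


@dataclass
class ReconstructionReport:
    series_mse: dict[tuple[str, str], float]
    median_mse: float
    mape_percent: float
    per_admission_error: dict[str, float]
    n_excluded_series: int = 0
    n_excluded_mape_targets: int = 0


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad_from_output(y: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation output
    if kind == "elu":
        return np.where(y > 0, 1.0, y + 1.0)
    if kind == "tanh":
        return 1.0 - y * y
    raise ValueError(f"unknown activation {kind!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.normal(size=(max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diagonal(r))
    return q[:n, :m] if n >= m else q.T[:n, :m]


def _gru_forward(params: dict, prefix: str, x: np.ndarray, mask: np.ndarray,
                 reverse: bool, activation: str):
    """Run one GRU layer over (B, T, D) input; returns (B, T, H) and a cache.

    Masked steps carry the hidden state through unchanged, so appended padding
    rows cannot influence any valid output in either direction.
    """
    w, u, b = params[prefix + ".W"], params[prefix + ".U"], params[prefix + ".b"]
    bsz, t_len, _ = x.shape
    h_size = u.shape[0]
    xp = x @ w + b  # (B, T, 3H)
    order = range(t_len - 1, -1, -1) if reverse else range(t_len)

    h = np.zeros((bsz, h_size))
    out = np.zeros((bsz, t_len, h_size))
    cache_steps = []
    for t in order:
        m = mask[:, t : t + 1].astype(float)
        hp = h @ u  # (B, 3H)
        z = _sigmoid(xp[:, t, :h_size] + hp[:, :h_size])
        r = _sigmoid(xp[:, t, h_size : 2 * h_size] + hp[:, h_size : 2 * h_size])
        rh = r * h
        c = _act(xp[:, t, 2 * h_size :] + rh @ u[:, 2 * h_size :], activation)
        h_new = z * h + (1.0 - z) * c
        h_next = m * h_new + (1.0 - m) * h
        out[:, t] = h_next
        cache_steps.append((t, h, z, r, rh, c, m))
        h = h_next
    return out, (cache_steps, x, w, u, activation)


def _gru_backward(cache, d_out: np.ndarray):
    """Backprop one GRU layer; returns (dX, grads dict with W/U/b keys)."""
    cache_steps, x, w, u, activation = cache
    bsz, t_len, d_in = x.shape
    h_size = u.shape[0]
    d_xp = np.zeros((bsz, t_len, 3 * h_size))
    d_u = np.zeros_like(u)
    dh = np.zeros((bsz, h_size))
    u_zr_t = u[:, : 2 * h_size].T
    u_h_t = u[:, 2 * h_size :].T

    for t, h_prev, z, r, rh, c, m in reversed(cache_steps):
        dh_total = d_out[:, t] + dh
        dh_new = m * dh_total
        dh_pass = (1.0 - m) * dh_total

        dz = dh_new * (h_prev - c)
        dpre_z = dz * z * (1.0 - z)
        dc = dh_new * (1.0 - z)
        dpre_c = dc * _act_grad_from_output(c, activation)
        d_rh = dpre_c @ u_h_t
        dr = d_rh * h_prev
        dpre_r = dr * r * (1.0 - r)

        dpre_zr = np.concatenate([dpre_z, dpre_r], axis=1)
        dh = (
            dh_new * z
            + d_rh * r
            + dpre_zr @ u_zr_t
            + dh_pass
        )
        d_u[:, : 2 * h_size] += h_prev.T @ dpre_zr
        d_u[:, 2 * h_size :] += rh.T @ dpre_c
        d_xp[:, t, : 2 * h_size] = dpre_zr
        d_xp[:, t, 2 * h_size :] = dpre_c

    d_xp2 = d_xp.reshape(-1, 3 * h_size)
    d_w = x.reshape(-1, d_in).T @ d_xp2
    d_b = d_xp2.sum(axis=0)
    d_x = d_xp @ w.T
    return d_x, {"W": d_w, "U": d_u, "b": d_b}


def _layernorm_forward(params: dict, prefix: str, x: np.ndarray, eps: float = 1e-5):
    g, b = params[prefix + ".g"], params[prefix + ".b"]
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(cache, dy: np.ndarray):
    xhat, inv, g = cache
    h = xhat.shape[-1]
    dxhat = dy * g
    dx = (
        inv
        / h
        * (
            h * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, {"g": dg, "b": db}


def _gru_block_forward(params: dict, prefix: str, x: np.ndarray, mask: np.ndarray,
                       activation: str, dropout: float,
                       rng: np.random.Generator | None):
    """Bidirectional GRU pair, summed, layer-normalized.

    Dropout (if training) acts on the input connections of each direction,
    with an independent mask per direction, shared across time steps.
    """
    caches = {}
    inputs = {}
    for direction in ("f", "b"):
        xi = x
        if rng is not None and dropout > 0.0:
            keep = rng.random((x.shape[0], 1, x.shape[2])) >= dropout
            drop_mask = keep.astype(float) / (1.0 - dropout)
            xi = x * drop_mask
            caches[direction + ".drop"] = drop_mask
        inputs[direction] = xi
    out_f, cache_f = _gru_forward(params, f"{prefix}.gru_f", inputs["f"], mask,
                                  reverse=False, activation=activation)
    out_b, cache_b = _gru_forward(params, f"{prefix}.gru_b", inputs["b"], mask,
                                  reverse=True, activation=activation)
    summed = out_f + out_b
    normed, cache_ln = _layernorm_forward(params, f"{prefix}.ln", summed)
    caches.update({"f": cache_f, "b": cache_b, "ln": cache_ln})
    return normed, caches


def _gru_block_backward(caches, d_out: np.ndarray, prefix: str):
    d_sum, ln_grads = _layernorm_backward(caches["ln"], d_out)
    grads = {f"{prefix}.ln.{k}": v for k, v in ln_grads.items()}
    dx = None
    for direction, cache_key in (("f", "f"), ("b", "b")):
        d_xi, g = _gru_backward(caches[cache_key], d_sum)
        drop = caches.get(direction + ".drop")
        if drop is not None:
            d_xi = d_xi * drop
        dx = d_xi if dx is None else dx + d_xi
        for k, v in g.items():
            grads[f"{prefix}.gru_{direction}.{k}"] = v
    return dx, grads


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class GRUAutoencoder:
    """Joint encoder/decoder over padded admission matrices."""

    def __init__(self, hp: ModelHyperparams, n_dynamic: int, n_static: int,
                 n_temporal: int, seed: int = 0) -> None:
        if min(n_dynamic, n_temporal) < 1 or n_static < 0:
            raise ValueError("input block dimensions must be positive")
        bottleneck = hp.bottleneck_size
        if bottleneck % 2 == 1:
            logger.warning(
                "odd bottleneck size %d rounded up to %d", bottleneck, bottleneck + 1
            )
            bottleneck += 1
        self.hp = hp
        self.bottleneck_size = bottleneck
        self.n_dynamic = n_dynamic
        self.n_static = n_static
        self.n_temporal = n_temporal
        self.n_input = n_dynamic + n_static + n_temporal
        self.n_rec = n_dynamic + n_static
        self.seed = seed
        self.params = self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        h = self.hp.gru_size
        k = self.bottleneck_size
        params: dict[str, np.ndarray] = {}

        def gru(prefix: str, d_in: int) -> None:
            params[prefix + ".W"] = _glorot(rng, d_in, 3 * h)
            params[prefix + ".U"] = np.concatenate(
                [_orthogonal(rng, h, h) for _ in range(3)], axis=1
            )
            params[prefix + ".b"] = np.zeros(3 * h)

        def ln(prefix: str) -> None:
            params[prefix + ".g"] = np.ones(h)
            params[prefix + ".b"] = np.zeros(h)

        gru("enc.gru_f", self.n_input)
        gru("enc.gru_b", self.n_input)
        ln("enc.ln")
        params["enc.dense.W"] = _glorot(rng, h, k)
        params["enc.dense.b"] = np.zeros(k)
        gru("dec.gru_f", k + self.n_temporal)
        gru("dec.gru_b", k + self.n_temporal)
        ln("dec.ln")
        params["dec.dense.W"] = _glorot(rng, h, self.n_rec)
        params["dec.dense.b"] = np.zeros(self.n_rec)
        return params

    # -- forward ------------------------------------------------------------

    def _split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x[:, :, : self.n_rec], x[:, :, self.n_rec :]

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Full pass; returns (reconstruction Y, bottleneck Z, cache)."""
        act = self.hp.nonrecurrent_activation
        dropout = self.hp.nonrecurrent_dropout if train else 0.0
        drop_rng = rng if train else None
        x_rec, x_temp = self._split(x)

        x_in = x
        if train and rng is not None and self.hp.noise_sigma > 0.0:
            noise = rng.normal(0.0, self.hp.noise_sigma,
                               size=(x.shape[0], x.shape[1], self.n_dynamic))
            x_in = x.copy()
            x_in[:, :, : self.n_dynamic] += noise

        enc_out, enc_cache = _gru_block_forward(
            self.params, "enc", x_in, mask, act, dropout, drop_rng
        )
        mf = mask.astype(float)[:, :, None]
        counts = mf.sum(axis=1)  # (B, 1)
        pooled = (enc_out * mf).sum(axis=1) / counts  # masked mean over time
        z = pooled @ self.params["enc.dense.W"] + self.params["enc.dense.b"]

        t_len = x.shape[1]
        z_rep = np.repeat(z[:, None, :], t_len, axis=1)
        dec_in = np.concatenate([z_rep, x_temp], axis=2)
        dec_out, dec_cache = _gru_block_forward(
            self.params, "dec", dec_in, mask, act, dropout, drop_rng
        )
        y = dec_out @ self.params["dec.dense.W"] + self.params["dec.dense.b"]

        cache = {
            "x_rec": x_rec, "mask": mask, "mf": mf, "counts": counts,
            "enc": enc_cache, "pooled": pooled, "z": z,
            "dec": dec_cache, "dec_out": dec_out,
        }
        return y, z, cache

    # -- loss and gradients -------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, mask: np.ndarray, delta: float,
                       train: bool = True,
                       rng: np.random.Generator | None = None):
        y, _, cache = self.forward(x, mask, train=train, rng=rng)
        target = cache["x_rec"]
        err = y - target
        mf = cache["mf"]
        n_valid = float(mf.sum() * self.n_rec)
        abs_err = np.abs(err)
        quad = np.minimum(abs_err, delta)
        elem = 0.5 * quad**2 + delta * (abs_err - quad)
        loss = float((elem * mf).sum() / n_valid)

        d_y = np.clip(err, -delta, delta) * mf / n_valid
        grads = self._backward(d_y, cache)
        return loss, grads

    def evaluate_loss(self, x: np.ndarray, mask: np.ndarray, delta: float) -> float:
        y, _, cache = self.forward(x, mask, train=False)
        err = y - cache["x_rec"]
        mf = cache["mf"]
        abs_err = np.abs(err)
        quad = np.minimum(abs_err, delta)
        elem = 0.5 * quad**2 + delta * (abs_err - quad)
        return float((elem * mf).sum() / (mf.sum() * self.n_rec))

    def _backward(self, d_y: np.ndarray, cache) -> dict[str, np.ndarray]:
        dec_out = cache["dec_out"]
        grads: dict[str, np.ndarray] = {}
        w_out = self.params["dec.dense.W"]
        grads["dec.dense.W"] = dec_out.reshape(-1, dec_out.shape[-1]).T @ d_y.reshape(
            -1, d_y.shape[-1]
        )
        grads["dec.dense.b"] = d_y.sum(axis=(0, 1))
        d_dec_out = d_y @ w_out.T

        d_dec_in, dec_grads = _gru_block_backward(cache["dec"], d_dec_out, "dec")
        grads.update(dec_grads)

        k = self.bottleneck_size
        d_z = d_dec_in[:, :, :k].sum(axis=1)  # repeated bottleneck
        w_enc = self.params["enc.dense.W"]
        grads["enc.dense.W"] = cache["pooled"].T @ d_z
        grads["enc.dense.b"] = d_z.sum(axis=0)
        d_pooled = d_z @ w_enc.T

        d_enc_out = cache["mf"] * d_pooled[:, None, :] / cache["counts"][:, None, :]
        _, enc_grads = _gru_block_backward(cache["enc"], d_enc_out, "enc")
        grads.update(enc_grads)
        return grads

    # -- inference ----------------------------------------------------------

    def encode_batch(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        _, z, _ = self.forward(x, mask, train=False)
        return z

    def reconstruct_batch(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        y, _, _ = self.forward(x, mask, train=False)
        return y

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def build_model(hp: ModelHyperparams, n_dynamic: int, n_static: int,
                n_temporal: int, seed: int = 0) -> GRUAutoencoder:
    """Seeded construction of the autoencoder for a given column schema."""
    return GRUAutoencoder(hp, n_dynamic, n_static, n_temporal, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class EarlyStopper:
    """Stop after ``patience`` epochs without validation improvement."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.epochs_since = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record an epoch's validation loss; returns True when training stops."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.epochs_since = 0
        else:
            self.epochs_since += 1
        return self.epochs_since >= self.patience


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def _clip_by_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def train(model: GRUAutoencoder, train_matrices: list[AdmissionMatrix],
          val_matrices: list[AdmissionMatrix], tc: TrainConfig,
          verbose: bool = False) -> tuple[GRUAutoencoder, dict]:
    """Train in place; returns the model (best-validation weights) and history."""
    if not train_matrices or not val_matrices:
        raise ValueError("both training and validation splits must be non-empty")

    rng = np.random.default_rng(tc.seed)
    optimizer = _Adam(model.params, tc.learning_rate)
    stopper = EarlyStopper(tc.early_stop_patience_epochs)
    best_params = model.copy_params()
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    val_batches = assemble_batch(val_matrices, tc.batch_size)

    for epoch in range(tc.max_epochs):
        batches = assemble_batch(train_matrices, tc.batch_size, rng=rng)
        epoch_loss = 0.0
        n_batches = 0
        for x, mask, _ in batches:
            loss, grads = model.loss_and_grads(
                x, mask, tc.huber_delta, train=True, rng=rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"last finite epoch losses: {history['train_loss'][-3:]}"
                )
            _clip_by_global_norm(grads, tc.grad_clip_norm)
            optimizer.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1

        val_loss = float(
            np.mean([model.evaluate_loss(x, m, tc.huber_delta)
                     for x, m, _ in val_batches])
        )
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_loss"].append(val_loss)
        if verbose:
            logger.info("epoch %d: train %.5f val %.5f", epoch,
                        history["train_loss"][-1], val_loss)

        if val_loss <= stopper.best:
            best_params = model.copy_params()
        if stopper.update(epoch, val_loss):
            break

    model.set_params(best_params)
    history["best_epoch"] = stopper.best_epoch
    history["best_val_loss"] = stopper.best
    return model, history


# ---------------------------------------------------------------------------
# inference and metrics
# ---------------------------------------------------------------------------


def encode(model: GRUAutoencoder, matrices: list[AdmissionMatrix],
           batch_size: int = 16) -> FeatureMatrix:
    """Deterministic bottleneck embeddings, one row per admission."""
    ids = [m.admission_id for m in matrices]
    chunks = []
    for start in range(0, len(matrices), batch_size):
        x, mask = pad_batch(matrices[start : start + batch_size])
        chunks.append(model.encode_batch(x, mask))
    return FeatureMatrix(admission_ids=ids, embeddings=np.concatenate(chunks, axis=0))


def reconstruct(model: GRUAutoencoder, matrix: AdmissionMatrix) -> np.ndarray:
    """Reconstruction of one admission's dynamic + static columns (valid rows)."""
    if matrix.values.shape[1] != model.n_input:
        raise ValueError(
            f"matrix has {matrix.values.shape[1]} columns, model expects {model.n_input}"
        )
    x, mask = pad_batch([matrix])
    y = model.reconstruct_batch(x, mask)[0]
    return y[matrix.mask.astype(bool)]


def reconstruction_metrics(
    matrices: list[AdmissionMatrix],
    reconstructions: list[np.ndarray],
    normalizer: Normalizer | None = None,
    mape_floor: float = 0.1,
) -> ReconstructionReport:
    """Per-series MSE in normalized space; MAPE on the original scale.

    The MSE is computed per (admission, attribute) time series over valid rows
    and summarized by its median across all series.  MAPE inverse-transforms
    dynamic targets and reconstructions to the original measurement scale and
    excludes targets with absolute value below ``mape_floor``, since relative
    error is ill-defined near zero.
    """
    if len(matrices) != len(reconstructions):
        raise ValueError("need one reconstruction per admission matrix")
    series_mse: dict[tuple[str, str], float] = {}
    per_admission: dict[str, float] = {}
    ape_parts: list[np.ndarray] = []
    n_excluded = 0
    n_excluded_targets = 0

    for mat, rec in zip(matrices, reconstructions):
        valid = mat.mask.astype(bool)
        truth = mat.values[valid, : mat.schema.n_reconstructed]
        rec_valid = rec[: valid.sum()] if rec.shape[0] == valid.sum() else rec[valid]
        if rec_valid.shape != truth.shape:
            raise ValueError("reconstruction shape does not match valid rows")
        sq = (rec_valid - truth) ** 2
        per_admission[mat.admission_id] = float(sq.mean())
        for j, attr in enumerate(mat.schema.dynamic):
            if truth.shape[0] == 0:
                n_excluded += 1
                continue
            series_mse[(mat.admission_id, attr)] = float(sq[:, j].mean())
            if normalizer is not None:
                orig = normalizer.inverse_transform(attr, truth[:, j])
                pred = normalizer.inverse_transform(attr, rec_valid[:, j])
                keep = np.abs(orig) >= mape_floor
                n_excluded_targets += int((~keep).sum())
                if keep.any():
                    ape_parts.append(np.abs((pred[keep] - orig[keep]) / orig[keep]))

    all_mse = np.asarray(list(series_mse.values()))
    median_mse = float(np.median(all_mse)) if all_mse.size else float("nan")
    if ape_parts:
        mape = float(np.concatenate(ape_parts).mean() * 100.0)
    else:
        mape = float("nan")
    return ReconstructionReport(
        series_mse=series_mse,
        median_mse=median_mse,
        mape_percent=mape,
        per_admission_error=per_admission,
        n_excluded_series=n_excluded,
        n_excluded_mape_targets=n_excluded_targets,
    )
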