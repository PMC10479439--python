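"""Twin-tower neural distance model for name strings.

Two weight-tied towers map an encoded name pair to vectors whose cosine
distance is the model's output, trained with the contrastive loss

    L(d, y) = (1 - y) * d**2 + y * max(0, m - d)**2

where ``y = 0`` labels matching pairs (pulled toward distance 0) and
``y = 1`` distant pairs (pushed beyond the margin ``m``).

Each tower is: per-character embedding (dim 30) → two position-wise dense
layers (width 130, ReLU) → bidirectional LSTM (65 units per direction) →
concatenated final hidden states.  The implementation is pure NumPy with
hand-written backpropagation and Adam.  Because the embedding and the
position-wise dense stack see only the 28 distinct input symbols, their
composition is evaluated once per step as a 28-row table and sequences
index into it; gradients are scattered back through the same table.  This
makes the recurrent layer the only per-timestep matrix work.

The model's reported distance is clipped into [0, 1] (cosine distance can
reach 2); the training loss is computed on the unclipped value so matching
pairs beyond 1 still receive a gradient.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .fuzzy import RankedCandidates
from .pairgen import PairDataset
from .textprep import ALPHABET_SIZE, MAX_LEN, encode, normalize

__all__ = [
    "ModelConfig",
    "DistanceModel",
    "TrainReport",
    "TrainingError",
    "cosine_distance",
    "contrastive_loss",
    "build_model",
    "train",
    "distance",
    "model_top_k",
]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The recurrent width (65 per direction) matches the fixed sequence
    length of the encoding; margin 1.0 is the canonical contrastive-loss
    default consistent with the [0, 1] reported distance; threshold 0.5 is
    the midpoint of the label range.
    """

    max_len: int = MAX_LEN
    alphabet_size: int = ALPHABET_SIZE
    char_embed_dim: int = 30
    dense_layers: int = 2
    dense_width: int = 130
    recurrent_units: int = 65
    margin: float = 1.0
    match_threshold: float = 0.5
    max_epochs: int = 500
    patience: int = 10
    min_delta: float = 3e-3
    learning_rate: float = 2e-3
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 4
    batch_size: int = 256
    grad_clip: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        dims = (
            self.max_len,
            self.alphabet_size,
            self.char_embed_dim,
            self.dense_layers,
            self.dense_width,
            self.recurrent_units,
            self.max_epochs,
            self.patience,
            self.batch_size,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all model dimensions must be positive")
        if not 0 < self.match_threshold < 1:
            raise ValueError("match_threshold must be in (0, 1)")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class TrainReport:
    """Per-epoch history and the best (restored) epoch."""

    epochs_run: int
    best_epoch: int
    history: list[dict[str, float]]
    best_val_acc: float
    best_val_loss: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cos(u, v)`` in [0, 2]; raises on zero vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - float(u @ v) / (nu * nv))


def contrastive_loss(d: float, y: int, m: float = 1.0) -> float:
    """Contrastive loss for one pair: (1-y)·d² + y·max(0, m-d)²."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return float((1 - y) * d * d + y * max(0.0, m - d) ** 2)


# ---------------------------------------------------------------------------
# parameters and forward/backward machinery


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    H, D, W = cfg.recurrent_units, cfg.char_embed_dim, cfg.dense_width
    p: dict[str, np.ndarray] = {}
    p["E"] = (0.1 * rng.standard_normal((cfg.alphabet_size, D))).astype(np.float32)
    prev = D
    for li in range(cfg.dense_layers):
        p[f"W{li}"] = _glorot(rng, (prev, W))
        p[f"b{li}"] = np.zeros(W, dtype=np.float32)
        prev = W
    for dname in ("f", "b"):
        p[f"Wx_{dname}"] = _glorot(rng, (prev, 4 * H))
        p[f"Wh_{dname}"] = _glorot(rng, (H, 4 * H))
        bias = np.zeros(4 * H, dtype=np.float32)
        bias[H : 2 * H] = 1.0  # forget-gate bias
        p[f"b_{dname}"] = bias
    return p


def _symbol_table(p: dict, cfg: ModelConfig) -> tuple[np.ndarray, list]:
    """Compose embedding + dense stack over the 28-symbol alphabet."""
    act = p["E"]
    caches = []
    for li in range(cfg.dense_layers):
        pre = act @ p[f"W{li}"] + p[f"b{li}"]
        post = np.maximum(pre, 0.0)
        caches.append((act, pre))
        act = post
    return act, caches


def _symbol_table_backward(
    dS: np.ndarray, caches: list, p: dict, cfg: ModelConfig, grads: dict
) -> None:
    d = dS
    for li in reversed(range(cfg.dense_layers)):
        act_in, pre = caches[li]
        d = d * (pre > 0)
        grads[f"W{li}"] += act_in.T @ d
        grads[f"b{li}"] += d.sum(axis=0)
        d = d @ p[f"W{li}"].T
    grads["E"] += d


class _LstmCache:
    __slots__ = ("codes", "mask", "gates", "cells", "hs", "P")

    def __init__(self, codes, mask, gates, cells, hs, P):
        self.codes = codes
        self.mask = mask
        self.gates = gates
        self.cells = cells
        self.hs = hs
        self.P = P


def _lstm_forward(
    codes: np.ndarray,
    lengths: np.ndarray,
    S: np.ndarray,
    p: dict,
    dname: str,
    H: int,
    keep_cache: bool,
) -> tuple[np.ndarray, _LstmCache | None]:
    """Masked LSTM over integer sequences; input features come from table S.

    ``P = S @ Wx + b`` is the per-symbol input projection, so the input
    term of every timestep is a row lookup, gathered up front for the whole
    batch.  Gate columns are laid out [i | f | o | g] so the three sigmoid
    gates share one exp call.  Padded positions carry state through
    unchanged, which makes truncation at the batch maximum length exact.
    """
    B, T = codes.shape
    P = S @ p[f"Wx_{dname}"] + p[f"b_{dname}"]  # (alphabet, 4H)
    Z = P[codes.T]  # (T, B, 4H) input projections, time-major
    Wh = p[f"Wh_{dname}"]
    h = np.zeros((B, H), dtype=np.float32)
    c = np.zeros((B, H), dtype=np.float32)
    gates = np.empty((T, B, 4 * H), dtype=np.float32) if keep_cache else None
    cells = np.empty((T, B, 2 * H), dtype=np.float32) if keep_cache else None
    hs = np.empty((T, B, H), dtype=np.float32) if keep_cache else None
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float32)
    min_len = int(lengths.min())
    scratch = np.empty((B, 4 * H), dtype=np.float32)
    for t in range(T):
        pre = Z[t] + h @ Wh
        if keep_cache:
            sg = gates[t, :, : 3 * H]
            g = gates[t, :, 3 * H :]
        else:
            sg = scratch[:, : 3 * H]
            g = scratch[:, 3 * H :]
        np.negative(pre[:, : 3 * H], out=sg)
        np.exp(sg, out=sg)
        sg += 1.0
        np.reciprocal(sg, out=sg)
        np.tanh(pre[:, 3 * H :], out=g)
        i, f, o = sg[:, :H], sg[:, H : 2 * H], sg[:, 2 * H :]
        c_new = f * c
        c_new += i * g
        tc = np.tanh(c_new)
        if keep_cache:
            hs[t] = h
            cells[t, :, :H] = c
            cells[t, :, H:] = tc
        if t < min_len:  # whole batch valid: no mask arithmetic needed
            h = o * tc
            c = c_new
        else:
            m = mask[:, t : t + 1]
            h = m * (o * tc) + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
    cache = _LstmCache(codes, mask, gates, cells, hs, P) if keep_cache else None
    return h, cache


def _lstm_backward(
    dh_final: np.ndarray,
    cache: _LstmCache,
    S: np.ndarray,
    p: dict,
    dname: str,
    H: int,
    grads: dict,
) -> np.ndarray:
    """BPTT through the masked LSTM; returns dS contribution."""
    codes, mask = cache.codes, cache.mask
    B, T = codes.shape
    Wh = p[f"Wh_{dname}"]
    WhT = np.ascontiguousarray(Wh.T)
    dWh = np.zeros_like(Wh)
    dZ = np.empty((T, B, 4 * H), dtype=np.float32)
    dh = dh_final.astype(np.float32)
    dc = np.zeros((B, H), dtype=np.float32)
    min_len = int(mask.sum(axis=1).min())
    for t in range(T - 1, -1, -1):
        sg = cache.gates[t, :, : 3 * H]
        i, f, o = sg[:, :H], sg[:, H : 2 * H], sg[:, 2 * H :]
        g = cache.gates[t, :, 3 * H :]
        c_prev = cache.cells[t, :, :H]
        tc = cache.cells[t, :, H:]
        all_valid = t < min_len
        if all_valid:
            dh_new = dh
            dc_new = dc + dh_new * o * (1.0 - tc * tc)
        else:
            m = mask[:, t : t + 1]
            dh_new = dh * m
            dc_new = dc * m + dh_new * o * (1.0 - tc * tc)
        dpre = dZ[t]
        dpre[:, :H] = dc_new * g
        dpre[:, H : 2 * H] = dc_new * c_prev
        dpre[:, 2 * H : 3 * H] = dh_new * tc
        dpre[:, : 3 * H] *= sg * (1.0 - sg)
        dpre[:, 3 * H :] = dc_new * i * (1.0 - g * g)
        dWh += cache.hs[t].T @ dpre
        if all_valid:
            dh = dpre @ WhT
            dc = dc_new * f
        else:
            dh = dpre @ WhT + dh * (1.0 - m)
            dc = dc_new * f + dc * (1.0 - m)
    # scatter dZ back to per-symbol projections with one one-hot gemm
    A = S.shape[0]
    flat_codes = codes.T.ravel()
    onehot = np.zeros((A, T * B), dtype=np.float32)
    onehot[flat_codes, np.arange(T * B)] = 1.0
    dP = onehot @ dZ.reshape(T * B, 4 * H)
    grads[f"Wx_{dname}"] += S.T @ dP
    grads[f"b_{dname}"] += dP.sum(axis=0)
    grads[f"Wh_{dname}"] += dWh
    return dP @ p[f"Wx_{dname}"].T


def _reverse_prefixes(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence's valid prefix, keeping trailing padding."""
    B, T = codes.shape
    idx = np.arange(T)[None, :]
    src = lengths[:, None] - 1 - idx
    valid = src >= 0
    src = np.where(valid, src, idx)
    return np.take_along_axis(codes, src, axis=1)


@dataclass
class DistanceModel:
    """Weight-tied twin-tower distance model (both towers share ``params``)."""

    config: ModelConfig
    params: dict[str, np.ndarray] = field(repr=False)
    trained: bool = False

    # -- forward ------------------------------------------------------------

    def embed_batch(
        self, codes: np.ndarray, lengths: np.ndarray, keep_cache: bool = False
    ):
        """Tower vectors for a batch of encoded names.

        Returns ``(vectors, cache)``; vectors have width 2 × recurrent
        units (final hidden state of each direction).
        """
        cfg = self.config
        H = cfg.recurrent_units
        T = max(int(lengths.max()), 1)
        codes = np.ascontiguousarray(codes[:, :T])
        S, dense_caches = _symbol_table(self.params, cfg)
        rev = _reverse_prefixes(codes, lengths)
        hf, cf = _lstm_forward(codes, lengths, S, self.params, "f", H, keep_cache)
        hb, cb = _lstm_forward(rev, lengths, S, self.params, "b", H, keep_cache)
        out = np.concatenate([hf, hb], axis=1)
        cache = (S, dense_caches, cf, cb) if keep_cache else None
        return out, cache

    def _encode_names(self, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        codes = np.zeros((len(names), cfg.max_len), dtype=np.int64)
        lengths = np.zeros(len(names), dtype=np.int64)
        for i, name in enumerate(names):
            enc = encode(name, cfg.max_len)
            codes[i] = enc.as_array()
            lengths[i] = enc.length
        return codes, lengths

    def distances_raw(
        self,
        codes_a: np.ndarray,
        len_a: np.ndarray,
        codes_b: np.ndarray,
        len_b: np.ndarray,
    ) -> np.ndarray:
        """Unclipped cosine distances (in [0, 2]) for aligned code batches."""
        n = codes_a.shape[0]
        codes = np.concatenate([codes_a, codes_b], axis=0)
        lengths = np.concatenate([len_a, len_b], axis=0)
        u, _ = self.embed_batch(codes, lengths)
        return _pair_distances(u[:n], u[n:])

    # -- public string API ---------------------------------------------------

    def distance(self, a: str, b: str) -> float:
        """Clipped distance in [0, 1] between two raw name strings.

        Identical names map to exactly 0 (shared towers force identical
        embeddings).  Symmetric in its arguments.
        """
        na, nb = normalize(a), normalize(b)
        if na == nb:
            return 0.0
        codes, lengths = self._encode_names([na, nb])
        d = self.distances_raw(codes[:1], lengths[:1], codes[1:], lengths[1:])
        return float(np.clip(d[0], 0.0, 1.0))

    def distances_to_pool(self, query: str, pool: list[str]) -> np.ndarray:
        """Clipped distances from one query to every pool member."""
        nq = normalize(query)
        codes, lengths = self._encode_names([nq] + [normalize(c) for c in pool])
        u, _ = self.embed_batch(codes, lengths)
        d = _pair_distances(np.repeat(u[:1], len(pool), axis=0), u[1:])
        d = np.clip(d, 0.0, 1.0)
        for i, c in enumerate(pool):
            if normalize(c) == nq:
                d[i] = 0.0
        return d

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights to ``path`` (npz) with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.params, __trained__=np.array([self.trained]))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DistanceModel":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():  # saved as foo.npz with sidecar foo.npz.json
            raise FileNotFoundError(f"missing config sidecar {sidecar}")
        cfg = ModelConfig(**json.loads(sidecar.read_text()))
        with np.load(path) as data:
            trained = bool(data["__trained__"][0])
            params = {k: data[k] for k in data.files if k != "__trained__"}
        return cls(config=cfg, params=params, trained=trained)


def _pair_distances(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    eps = np.float32(1e-12)
    nu = np.sqrt((u * u).sum(axis=1)) + eps
    nv = np.sqrt((v * v).sum(axis=1)) + eps
    cos = (u * v).sum(axis=1) / (nu * nv)
    return 1.0 - cos


def build_model(config: ModelConfig | None = None) -> DistanceModel:
    """Initialize an untrained model from ``config`` (seeded)."""
    cfg = config or ModelConfig()
    cfg.validate()
    return DistanceModel(config=cfg, params=_init_params(cfg))


# ---------------------------------------------------------------------------
# training


def _prepare_split(model: DistanceModel, pairs) -> tuple[np.ndarray, ...]:
    names_a = [p.a for p in pairs]
    names_b = [p.b for p in pairs]
    codes_a, len_a = model._encode_names(names_a)
    codes_b, len_b = model._encode_names(names_b)
    y = np.array([p.label for p in pairs], dtype=np.float32)
    return codes_a, len_a, codes_b, len_b, y


def _batches(
    n: int, batch_size: int, rng: np.random.Generator, sort_key: np.ndarray
) -> list[np.ndarray]:
    """Shuffled batches, length-bucketed so batch max lengths stay small."""
    order = rng.permutation(n)
    bucket = 16 * batch_size
    chunks = []
    for start in range(0, n, bucket):
        chunk = order[start : start + bucket]
        chunk = chunk[np.argsort(sort_key[chunk], kind="stable")]
        chunks.extend(
            chunk[i : i + batch_size] for i in range(0, len(chunk), batch_size)
        )
    idx = rng.permutation(len(chunks))
    return [chunks[i] for i in idx]


def _forward_backward(
    model: DistanceModel,
    codes_a,
    len_a,
    codes_b,
    len_b,
    y,
    margin: float,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    cfg = model.config
    H = cfg.recurrent_units
    p = model.params
    n = codes_a.shape[0]
    codes = np.concatenate([codes_a, codes_b], axis=0)
    lengths = np.concatenate([len_a, len_b], axis=0)
    u_all, cache = model.embed_batch(codes, lengths, keep_cache=True)
    S, dense_caches, cf, cb = cache
    u, v = u_all[:n], u_all[n:]

    eps = np.float32(1e-12)
    nu = np.sqrt((u * u).sum(axis=1)) + eps
    nv = np.sqrt((v * v).sum(axis=1)) + eps
    dot = (u * v).sum(axis=1)
    cos = dot / (nu * nv)
    d = 1.0 - cos  # unclipped, in [0, 2]

    viol = np.maximum(0.0, margin - d)
    loss = float(np.mean((1.0 - y) * d * d + y * viol * viol))
    dL_dd = (2.0 * (1.0 - y) * d - 2.0 * y * viol) / n
    dcos = -dL_dd

    du = dcos[:, None] * (v / (nu * nv)[:, None] - (cos / (nu * nu))[:, None] * u)
    dv = dcos[:, None] * (u / (nu * nv)[:, None] - (cos / (nv * nv))[:, None] * v)
    d_all = np.concatenate([du, dv], axis=0).astype(np.float32)

    grads = {k: np.zeros_like(w) for k, w in p.items()}
    dS = _lstm_backward(d_all[:, :H], cf, S, p, "f", H, grads)
    dS += _lstm_backward(d_all[:, H:], cb, S, p, "b", H, grads)
    _symbol_table_backward(dS, dense_caches, p, cfg, grads)
    return loss, grads, d


def _adam_step(p, grads, state, lr, clip, t):
    gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    scale = np.float32(clip / gnorm) if gnorm > clip else np.float32(1.0)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for k, g in grads.items():
        g = g * scale
        m = state.setdefault(f"m_{k}", np.zeros_like(g))
        v = state.setdefault(f"v_{k}", np.zeros_like(g))
        m += (1 - b1) * (g - m)
        v += (1 - b2) * (g * g - v)
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        p[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


def _evaluate(model, arrays, margin, threshold, batch_size) -> tuple[float, float]:
    codes_a, len_a, codes_b, len_b, y = arrays
    n = codes_a.shape[0]
    losses = np.empty(n, dtype=np.float64)
    correct = 0
    sort = np.argsort(np.maximum(len_a, len_b), kind="stable")
    for start in range(0, n, batch_size):
        idx = sort[start : start + batch_size]
        d = model.distances_raw(codes_a[idx], len_a[idx], codes_b[idx], len_b[idx])
        yy = y[idx]
        viol = np.maximum(0.0, margin - d)
        losses[start : start + len(idx)] = (1 - yy) * d * d + yy * viol * viol
        pred = np.clip(d, 0.0, 1.0) > threshold
        correct += int((pred == (yy == 1)).sum())
    return float(losses.mean()), correct / n


def train(
    model: DistanceModel,
    data: PairDataset,
    config: ModelConfig | None = None,
) -> TrainReport:
    """Fit the model on ``data.train``, early-stopping on validation loss.

    Stops when validation loss fails to improve by at least ``min_delta``
    for ``patience`` consecutive epochs, and restores the weights of the
    epoch with the lowest validation loss seen.  On an intermediate
    plateau (``lr_decay_patience`` epochs without meaningful improvement)
    the learning rate is halved, which settles the tail of training so
    the stopping criterion can bite.  Deterministic under the config seed
    when run serially on one device.
    """
    cfg = config or model.config
    cfg.validate()
    if not data.train or not data.validation:
        raise ValueError("train and validation splits must be nonempty")
    labels = {p.label for p in data.train}
    if labels != {0, 1}:
        raise ValueError("training data must contain both labels")

    rng = np.random.default_rng(cfg.seed + 1)
    tr = _prepare_split(model, data.train)
    va = _prepare_split(model, data.validation)
    codes_a, len_a, codes_b, len_b, y = tr
    sort_key = np.maximum(len_a, len_b)

    state: dict[str, np.ndarray] = {}
    history: list[dict[str, float]] = []
    best_val_loss = np.inf
    reference_loss = np.inf
    best_val_acc = 0.0
    best_epoch = 0
    best_params: dict[str, np.ndarray] | None = None
    step = 0
    since_best = 0
    current_lr = cfg.learning_rate

    for epoch in range(1, cfg.max_epochs + 1):
        epoch_losses: list[float] = []
        correct = 0
        for idx in _batches(len(y), cfg.batch_size, rng, sort_key):
            step += 1
            loss, grads, d = _forward_backward(
                model,
                codes_a[idx],
                len_a[idx],
                codes_b[idx],
                len_b[idx],
                y[idx],
                cfg.margin,
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            _adam_step(
                model.params, grads, state, current_lr, cfg.grad_clip, step
            )
            epoch_losses.append(loss * len(idx))
            pred = np.clip(d, 0.0, 1.0) > cfg.match_threshold
            correct += int((pred == (y[idx] == 1)).sum())
        train_loss = float(np.sum(epoch_losses) / len(y))
        train_acc = correct / len(y)
        val_loss, val_acc = _evaluate(
            model, va, cfg.margin, cfg.match_threshold, cfg.batch_size
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_epoch = epoch
            best_params = {k: w.copy() for k, w in model.params.items()}
        # patience resets only on a meaningful (>= min_delta) improvement
        if val_loss < reference_loss - cfg.min_delta:
            reference_loss = val_loss
            since_best = 0
        else:
            since_best += 1
        best_val_acc = max(best_val_acc, val_acc)
        if since_best >= cfg.patience:
            break
        if since_best > 0 and since_best % cfg.lr_decay_patience == 0:
            current_lr = max(current_lr * cfg.lr_decay_factor, 1e-5)

    if best_params is not None:
        model.params = best_params
    model.trained = True
    return TrainReport(
        epochs_run=len(history),
        best_epoch=best_epoch,
        history=history,
        best_val_acc=best_val_acc,
        best_val_loss=best_val_loss,
    )


# ---------------------------------------------------------------------------
# module-level convenience API


def distance(model: DistanceModel, a: str, b: str) -> float:
    """Clipped model distance between two raw strings (see method docs)."""
    return model.distance(a, b)


def model_top_k(
    model: DistanceModel, query: str, pool: list[str], k: int = 20
) -> RankedCandidates:
    """Best-``k`` pool members by model distance, ascending, ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq = list(dict.fromkeys(pool))
    if not uniq:
        return RankedCandidates(
            query=normalize(query), method="SM", entries=(), trained=model.trained
        )
    d = model.distances_to_pool(query, uniq)
    scored = sorted(zip(uniq, d.tolist()), key=lambda cs: (cs[1], cs[0]))
    return RankedCandidates(
        query=normalize(query),
        method="SM",
        entries=tuple(scored[:k]),
        trained=model.trained,
    )
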