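"""Per-disease autoencoder and one-dimensional "pseudogene" extraction.

A symmetric dense autoencoder (NumPy implementation) compresses a sample's
standardized expression profile over the selected genes down to a single
bottleneck value.  Encoder and decoder hidden layers use ReLU with inverted
dropout during training; the bottleneck and the output layer are linear.
Training minimizes mean-squared reconstruction error with the Adam optimizer
and early stopping on held-out MSE (best-epoch weights restored).

The bottleneck score of a trained encoder is sign-ambiguous (negating the
bottleneck weights and the first decoder layer leaves the reconstruction
unchanged), so every trained encoder is canonically oriented at training time
such that mean(score | training cases) >= mean(score | training controls).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AeConfig:
    """Architecture and training hyperparameters.

    ``hidden_widths`` are the encoder hidden-layer sizes (the decoder mirrors
    them); the bottleneck is fixed at one node.  Defaults: 128-64-10 encoder,
    dropout 0.2, Adam with learning rate 5e-4, batch size 16, at most 500
    epochs with patience 30 on held-out MSE (any strict improvement resets
    the counter; reconstruction of a weak latent factor improves slowly, so
    a large minimum-improvement threshold would stop training prematurely).
    """

    hidden_widths: tuple[int, ...] = (128, 64, 10)
    dropout: float = 0.2
    learning_rate: float = 5e-4
    batch_size: int = 16
    max_epochs: int = 500
    patience: int = 30
    min_delta: float = 0.0
    n_restarts: int = 4
    seed: int = 0

    def validate(self) -> None:
        ws = tuple(self.hidden_widths)
        if not ws or any(int(w) != w or w <= 1 for w in ws):
            raise ValueError(f"AeConfig.hidden_widths must be integers > 1, got {ws}")
        if any(a <= b for a, b in zip(ws, ws[1:])):
            raise ValueError(f"AeConfig.hidden_widths must be strictly decreasing, got {ws}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"AeConfig.dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError(f"AeConfig.learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"AeConfig.batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            raise ValueError(f"AeConfig.max_epochs must be >= 1, got {self.max_epochs}")
        if self.patience < 1:
            raise ValueError(f"AeConfig.patience must be >= 1, got {self.patience}")
        if self.n_restarts < 1:
            raise ValueError(f"AeConfig.n_restarts must be >= 1, got {self.n_restarts}")


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grid for exhaustive search.

    ``depths`` counts dense maps of the whole autoencoder including the
    output layer: depth d uses (d - 2) / 2 encoder hidden layers.  With the
    width options (w1, w2, w3) a depth-6 model uses (w1, w2), depth-8 uses
    (w1, w2, w3) and depth-10 appends a fourth layer of width w3 // 2.
    """

    learning_rates: tuple[float, ...] = (0.0001, 0.0005, 0.001, 0.002)
    depths: tuple[int, ...] = (6, 8, 10)
    w1_options: tuple[int, ...] = (64, 96, 128)
    w2_options: tuple[int, ...] = (32, 48, 64)
    w3_options: tuple[int, ...] = (10, 12, 16)
    dropouts: tuple[float, ...] = (0.1, 0.2, 0.3)

    def __post_init__(self):
        for name in ("learning_rates", "depths", "w1_options", "w2_options", "w3_options", "dropouts"):
            if not getattr(self, name):
                raise ValueError(f"HyperGrid.{name} must be non-empty")

    def __len__(self) -> int:
        return (
            len(self.learning_rates)
            * len(self.depths)
            * len(self.w1_options)
            * len(self.w2_options)
            * len(self.w3_options)
            * len(self.dropouts)
        )

    def combinations(self, base: AeConfig | None = None) -> list[AeConfig]:
        """All configurations in deterministic enumeration order."""
        base = base or AeConfig()
        out = []
        for lr, depth, w1, w2, w3, dr in itertools.product(
            self.learning_rates, self.depths, self.w1_options, self.w2_options,
            self.w3_options, self.dropouts,
        ):
            k = (depth - 2) // 2
            widths = {2: (w1, w2), 3: (w1, w2, w3), 4: (w1, w2, w3, max(2, w3 // 2))}[k]
            out.append(replace(base, hidden_widths=widths, dropout=dr, learning_rate=lr))
        return out


# ---------------------------------------------------------------------------
# split and standardization


def split_train_holdout(meta: pd.DataFrame, seed: int, train_frac: float = 0.6) -> pd.Series:
    """Stratified train/holdout partition of a cohort's samples (default 3:2).

    Returns a Series mapping sample_id to ``"train"`` or ``"holdout"``,
    deterministic for a given seed, with the case:control ratio preserved in
    both parts to within one sample.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for group, ids in meta.groupby("group")["sample_id"]:
        ids = list(ids)
        if len(ids) < 2:
            raise ValueError(f"split_train_holdout: group {group!r} has {len(ids)} sample(s); need >= 2")
        order = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        for rank, j in enumerate(order):
            assignment[ids[j]] = "train" if rank < n_train else "holdout"
    out = pd.Series(assignment, name="split")
    return out.loc[[s for s in meta["sample_id"]]]


@dataclass
class Standardizer:
    """Per-gene z-scoring with mean/sd taken from the training split only."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [g for g in self.mean.index if g not in matrix.index]
        if missing:
            raise ValueError(f"standardizer: matrix is missing gene(s) {missing[:5]}")
        sub = matrix.loc[self.mean.index]
        return sub.sub(self.mean, axis=0).div(self.sd, axis=0)


def fit_standardizer(matrix: pd.DataFrame, split: pd.Series) -> Standardizer:
    """Per-gene mean and sd over the training columns; zero variance -> sd 1."""
    train_cols = [s for s in split.index if split.loc[s] == "train"]
    if not train_cols:
        raise ValueError("fit_standardizer: training split is empty")
    sub = matrix[train_cols]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    n_zero = int((sd == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} gene(s) with zero training variance; standardized with sd = 1",
            stacklevel=2,
        )
        sd = sd.where(sd > 0, 1.0)
    return Standardizer(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# network


class AutoencoderNet:
    """Dense symmetric autoencoder with a one-node linear bottleneck."""

    def __init__(self, n_genes: int, config: AeConfig):
        config.validate()
        if n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        self.config = config
        hidden = list(config.hidden_widths)
        self.widths = [n_genes] + hidden + [1] + hidden[::-1] + [n_genes]
        self.bottleneck_index = len(hidden)  # layer whose output is the bottleneck
        rng = np.random.default_rng(config.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(self.widths[:-1], self.widths[1:]):
            # He initialization, suited to the ReLU hidden stack
            self.weights.append(rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameter_count(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights, self.biases)))

    def _is_relu(self, layer: int) -> bool:
        # ReLU on every hidden layer; the bottleneck and the final output are linear
        return layer not in (self.bottleneck_index, self.n_layers - 1)

    def _has_dropout(self, layer: int) -> bool:
        return self._is_relu(layer) and self.config.dropout > 0

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Forward pass; returns (output, caches for backprop)."""
        a = x
        caches = []
        for layer in range(self.n_layers):
            z = a @ self.weights[layer] + self.biases[layer]
            relu = self._is_relu(layer)
            h = np.maximum(z, 0.0) if relu else z
            mask = None
            if train and self._has_dropout(layer):
                keep = 1.0 - self.config.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            caches.append((a, z, mask))
            a = h
        return a, caches

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-free) bottleneck activations, shape (k, 1)."""
        a = x
        for layer in range(self.bottleneck_index + 1):
            z = a @ self.weights[layer] + self.biases[layer]
            a = np.maximum(z, 0.0) if self._is_relu(layer) else z
        return a

    def backward(self, x: np.ndarray, out: np.ndarray, caches) -> tuple[list, list]:
        """Gradients of mean squared reconstruction error w.r.t. weights/biases."""
        grad = 2.0 * (out - x) / out.size
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        for layer in range(self.n_layers - 1, -1, -1):
            a_in, z, mask = caches[layer]
            if mask is not None:
                grad = grad * mask
            if self._is_relu(layer):
                grad = grad * (z > 0)
            grads_w[layer] = a_in.T @ grad
            grads_b[layer] = grad.sum(axis=0)
            if layer > 0:
                grad = grad @ self.weights[layer].T
        return grads_w, grads_b

    def copy_weights(self) -> tuple[list, list]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_weights(self, snapshot: tuple[list, list]) -> None:
        ws, bs = snapshot
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]


def build_autoencoder(n_genes: int, config: AeConfig) -> AutoencoderNet:
    """Construct an untrained autoencoder for ``n_genes`` input features."""
    return AutoencoderNet(n_genes, config)


class _Adam:
    def __init__(self, shapes_w, shapes_b, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m_w = [np.zeros(s) for s in shapes_w]
        self.v_w = [np.zeros(s) for s in shapes_w]
        self.m_b = [np.zeros(s) for s in shapes_b]
        self.v_b = [np.zeros(s) for s in shapes_b]

    def step(self, net: AutoencoderNet, grads_w, grads_b) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for i in range(net.n_layers):
            for params, grads, m, v in (
                (net.weights, grads_w, self.m_w, self.v_w),
                (net.biases, grads_b, self.m_b, self.v_b),
            ):
                m[i] = self.b1 * m[i] + (1 - self.b1) * grads[i]
                v[i] = self.b2 * v[i] + (1 - self.b2) * grads[i] ** 2
                params[i] -= self.lr * (m[i] / c1) / (np.sqrt(v[i] / c2) + self.eps)


def _mse(net: AutoencoderNet, x: np.ndarray) -> float:
    out, _ = net.forward(x, train=False)
    return float(np.mean((out - x) ** 2))


@dataclass
class TrainedEncoder:
    """A trained encoder with everything needed for deterministic inference."""

    net: AutoencoderNet
    genes: list[str]
    standardizer: Standardizer
    orientation: int  # +1 or -1; fixed so mean(train cases) >= mean(train controls)
    history: pd.DataFrame = field(repr=False, default=None)
    config: AeConfig | None = None
    best_epoch: int | None = None

    def encode(self, matrix: pd.DataFrame) -> pd.Series:
        """Oriented pseudogene score per sample (column) of ``matrix``."""
        missing = [g for g in self.genes if g not in matrix.index]
        if missing:
            raise ValueError(f"encoder input is missing gene(s) {missing[:10]}")
        z = self.standardizer.transform(matrix.loc[self.genes])
        scores = self.net.encode(z.to_numpy(float).T)[:, 0] * self.orientation
        return pd.Series(scores, index=matrix.columns, name="pseudogene")

    def save(self, weights_path, sidecar_path) -> None:
        """Serialize: weights to an .npz file, everything else (gene list,
        standardizer, orientation, config) to a YAML sidecar."""
        import yaml
        from dataclasses import asdict

        arrays = {f"w{i}": w for i, w in enumerate(self.net.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.biases)})
        np.savez(weights_path, **arrays)
        sidecar = {
            "genes": list(self.genes),
            "standardizer": {
                "mean": {g: float(v) for g, v in self.standardizer.mean.items()},
                "sd": {g: float(v) for g, v in self.standardizer.sd.items()},
            },
            "orientation": int(self.orientation),
            "config": asdict(self.config),
            "best_epoch": self.best_epoch,
        }
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump(sidecar, fh)

    @classmethod
    def load(cls, weights_path, sidecar_path) -> "TrainedEncoder":
        import yaml

        with open(sidecar_path) as fh:
            sidecar = yaml.safe_load(fh)
        cfg_d = sidecar["config"]
        cfg_d["hidden_widths"] = tuple(cfg_d["hidden_widths"])
        config = AeConfig(**cfg_d)
        genes = sidecar["genes"]
        net = AutoencoderNet(len(genes), config)
        with np.load(weights_path) as data:
            net.weights = [data[f"w{i}"] for i in range(net.n_layers)]
            net.biases = [data[f"b{i}"] for i in range(net.n_layers)]
        std = Standardizer(
            mean=pd.Series(sidecar["standardizer"]["mean"]).loc[genes],
            sd=pd.Series(sidecar["standardizer"]["sd"]).loc[genes],
        )
        return cls(
            net=net,
            genes=genes,
            standardizer=std,
            orientation=sidecar["orientation"],
            config=config,
            best_epoch=sidecar["best_epoch"],
        )


def train_autoencoder(
    net: AutoencoderNet,
    matrix: pd.DataFrame,
    split: pd.Series,
    config: AeConfig,
) -> tuple[AutoencoderNet, pd.DataFrame, int]:
    """Train on the standardized matrix's training columns.

    ``matrix`` is genes x samples, already standardized.  Returns the network
    with best-epoch weights restored, the per-epoch history (train and
    holdout MSE) and the best epoch number.  Early stopping waits
    ``config.patience`` epochs for an improvement of at least
    ``config.min_delta`` in holdout MSE.
    """
    config.validate()
    train_cols = [s for s in split.index if split.loc[s] == "train" and s in matrix.columns]
    hold_cols = [s for s in split.index if split.loc[s] == "holdout" and s in matrix.columns]
    if not train_cols or not hold_cols:
        raise ValueError("train_autoencoder: both train and holdout splits must be non-empty")
    x_train = matrix[train_cols].to_numpy(float).T
    x_hold = matrix[hold_cols].to_numpy(float).T

    rng = np.random.default_rng(config.seed)
    opt = _Adam([w.shape for w in net.weights], [b.shape for b in net.biases], config.learning_rate)
    best_val = math.inf
    best_snapshot = net.copy_weights()
    best_epoch = 0
    wait = 0
    records = []
    n = x_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            out, caches = net.forward(xb, train=True, rng=rng)
            if not np.isfinite(out).all():
                raise FloatingPointError(
                    f"non-finite reconstruction at epoch {epoch}; "
                    f"learning rate {config.learning_rate} may be too large"
                )
            grads_w, grads_b = net.backward(xb, out, caches)
            opt.step(net, grads_w, grads_b)
        train_mse = _mse(net, x_train)
        val_mse = _mse(net, x_hold)
        records.append((epoch, train_mse, val_mse))
        if val_mse < best_val - config.min_delta:
            wait = 0
        else:
            wait += 1
        if val_mse < best_val:
            best_val = val_mse
            best_snapshot = net.copy_weights()
            best_epoch = epoch
        if wait >= config.patience:
            break
    net.set_weights(best_snapshot)
    history = pd.DataFrame(records, columns=["epoch", "train_mse", "val_mse"])
    return net, history, best_epoch


def fit_encoder(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    split: pd.Series,
    config: AeConfig,
) -> TrainedEncoder:
    """Standardize, build, train and orient an encoder for one cohort.

    A one-node bottleneck trained with dropout occasionally gets stuck in a
    dead-ReLU optimum that reconstructs nothing beyond the per-gene mean; the
    stuck runs are plainly visible as a higher held-out MSE.  Training is
    therefore restarted ``config.n_restarts`` times from seeds derived
    deterministically from ``config.seed`` and the restart with the lowest
    held-out MSE is kept.
    """
    standardizer = fit_standardizer(matrix, split)
    z = standardizer.transform(matrix)
    net = history = best_epoch = None
    best_val = math.inf
    for restart in range(config.n_restarts):
        cfg_r = replace(config, seed=config.seed + 10007 * restart)
        net_r = build_autoencoder(matrix.shape[0], cfg_r)
        net_r, hist_r, best_epoch_r = train_autoencoder(net_r, z, split, cfg_r)
        val = float(hist_r["val_mse"].min())
        if val < best_val:
            net, history, best_epoch, best_val = net_r, hist_r, best_epoch_r, val
    enc = TrainedEncoder(
        net=net,
        genes=list(matrix.index),
        standardizer=standardizer,
        orientation=1,
        history=history,
        config=config,
        best_epoch=best_epoch,
    )
    groups = meta.set_index("sample_id")["group"]
    train_ids = [s for s in split.index if split.loc[s] == "train"]
    scores = enc.encode(matrix[train_ids])
    mean_case = scores[[s for s in train_ids if groups.loc[s] == "case"]].mean()
    mean_ctrl = scores[[s for s in train_ids if groups.loc[s] == "control"]].mean()
    if mean_case < mean_ctrl:
        enc.orientation = -1
    return enc


def encode_and_orient(encoder: TrainedEncoder, matrix: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.Series:
    """Oriented pseudogene scores for the samples of ``matrix``."""
    return encoder.encode(matrix)


def grid_search(
    matrix: pd.DataFrame,
    split: pd.Series,
    grid: HyperGrid,
    base: AeConfig | None = None,
) -> tuple[AeConfig, pd.DataFrame]:
    """Exhaustively train one model per grid combination (shared seed) and
    return the configuration minimizing holdout MSE, plus the full record.

    Ties keep the first combination in enumeration order.  ``matrix`` must
    already be standardized.
    """
    configs = grid.combinations(base)
    records = []
    best_cfg, best_mse = None, math.inf
    for i, cfg in enumerate(configs):
        net = build_autoencoder(matrix.shape[0], cfg)
        _, history, best_epoch = train_autoencoder(net, matrix, split, cfg)
        val = float(history["val_mse"].min())
        records.append(
            (i, cfg.learning_rate, cfg.hidden_widths, cfg.dropout, val, best_epoch)
        )
        if val < best_mse:
            best_cfg, best_mse = cfg, val
    table = pd.DataFrame(
        records, columns=["index", "learning_rate", "hidden_widths", "dropout", "val_mse", "best_epoch"]
    )
    return best_cfg, table
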