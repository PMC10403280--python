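"""Outer-product convolutional interaction predictor with transfer evaluation.

Each chain of a variant pair is embedded as a D-vector by a pluggable
sequence embedder; the pair is represented as the D x D outer product
V_a (x) V_b and regressed to a normalized enrichment score by a 3-layer 2D
CNN (kernel 5x5, maxpool, ReLU, instance norm per layer) with a two-layer
fully connected head and sigmoid output, trained with squared-error loss
and Adam. Because the embedder places physicochemically similar residues
near each other, a model trained on a restricted amino-acid alphabet can
score pairs containing amino acids never seen in training — the transfer
setting evaluated per novel-amino-acid bin.

The network and optimizer are implemented directly in numpy (im2col
convolutions, manual backpropagation) so the full pipeline runs
deterministically on one CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats
from sklearn.metrics import average_precision_score, roc_auc_score

from coevoscreen.library_design import LibraryDesign
from coevoscreen.pair_enrichment import EnrichedPairSet, pool_counts
from coevoscreen.screen_simulator import PairCountTable

from coevoscreen.residues import ATCHLEY_FACTORS


class Embedder:
    """Contract for sequence embedders: deterministic D-vector per chain."""

    name: str = "base"
    dim: int = 0
    deterministic: bool = True

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def embed_batch(self, sequences: Sequence[str]) -> np.ndarray:
        cache: dict[str, np.ndarray] = {}
        out = np.empty((len(sequences), self.dim))
        for i, s in enumerate(sequences):
            if s not in cache:
                cache[s] = self.embed(s)
            out[i] = cache[s]
        return out


class PhysicochemicalEmbedder(Embedder):
    """Built-in deterministic embedder: physicochemical factors with fixed
    position-specific projections, mean-pooled over the chain.

    Residue r at chain position p contributes P_p @ [phi(r), 1] where
    phi(r) is the five-factor score vector and P_p a fixed seeded D x 6
    matrix; the chain embedding is the mean contribution. Amino acids
    unseen in training land near physicochemically similar ones, giving
    the shared-embedding-space property a pre-trained language model
    provides (and which alphabet transfer relies on). For an external
    language model use :class:`CallableEmbedder` instead.
    """

    def __init__(self, dim: int = 32, seed: int = 7, max_length: int = 64) -> None:
        self.name = f"physchem-d{dim}"
        self.dim = dim
        self.deterministic = True
        self.seed = seed
        rng = np.random.default_rng(seed)
        # one fixed projection per chain position, drawn once
        self._proj = rng.normal(0.0, 1.0, size=(max_length, dim, 6)) / np.sqrt(6)
        self._phi = {
            aa: np.array(list(v) + [1.0]) for aa, v in ATCHLEY_FACTORS.items()
        }

    def embed(self, sequence: str) -> np.ndarray:
        if len(sequence) > self._proj.shape[0]:
            raise ValueError(
                f"sequence length {len(sequence)} exceeds embedder capacity "
                f"{self._proj.shape[0]}"
            )
        acc = np.zeros(self.dim)
        for p, aa in enumerate(sequence):
            if aa not in self._phi:
                raise ValueError(f"invalid residue {aa!r} at position {p + 1}")
            acc += self._proj[p] @ self._phi[aa]
        return acc / len(sequence)


class CallableEmbedder(Embedder):
    """Adapter wrapping an external embedding function (e.g. a pre-trained
    protein language model producing 1280-d mean last-layer embeddings)."""

    def __init__(self, fn: Callable[[str], np.ndarray], dim: int, name: str = "external",
                 deterministic: bool = True) -> None:
        self._fn = fn
        self.dim = dim
        self.name = name
        self.deterministic = deterministic

    def embed(self, sequence: str) -> np.ndarray:
        v = np.asarray(self._fn(sequence), dtype=float)
        if v.shape != (self.dim,):
            raise ValueError(f"embedder returned shape {v.shape}, expected ({self.dim},)")
        return v


def pair_representation(v_a: np.ndarray, v_b: np.ndarray) -> np.ndarray:
    """Outer product V_a (x) V_b as a D x D matrix."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape or v_a.ndim != 1:
        raise ValueError(f"length mismatch: {v_a.shape} vs {v_b.shape}")
    return np.outer(v_a, v_b)


def normalize_label(count: int | np.ndarray, maxcount: float) -> float | np.ndarray:
    """Min-max normalized log enrichment label for positive pairs.

    X_s = (ln(count + 100) - ln 2) / (ln(maxcount) - ln 2) with
    maxcount = max over positives of (count + 100), so the top positive
    maps to exactly 1. 100 base counts are added to every positive to keep
    it distinguishable from naive pairs, which score 0 directly.
    """
    if maxcount <= 2:
        raise ValueError(f"maxcount must exceed 2, got {maxcount}")
    c = np.asarray(count, dtype=float)
    if np.any(c < 1):
        raise ValueError("positive counts must be >= 1")
    x = (np.log(c + 100.0) - np.log(2.0)) / (np.log(maxcount) - np.log(2.0))
    return float(x) if np.isscalar(count) else x


@dataclass
class PairDataset:
    """Labeled pair examples: columns seq_a seq_b count label cls split."""

    df: pd.DataFrame
    seed: int
    meta: dict = field(default_factory=dict)

    def subset(self, split: str) -> pd.DataFrame:
        return self.df[self.df["split"] == split].reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def assemble_dataset(
    naive_table: PairCountTable,
    enriched_set: EnrichedPairSet,
    enriched_tables: Sequence[PairCountTable],
    seed: int = 0,
    val_fraction: float = 0.2,
    max_positives: int | None = None,
) -> PairDataset:
    """Assemble matched positive/negative examples from screen outputs.

    Positives are the statistically enriched pairs, labeled by min-max
    normalized log counts; negatives are a size-matched random sample of
    naive pairs absent from the enriched rounds, labeled 0. The combined
    set is split 80/20 into train/validation deterministically per seed.
    ``max_positives`` caps the positive class by a seeded subsample, for
    runs scaled to a single CPU.
    """
    positives = enriched_set.df[["seq_a", "seq_b", "k"]].rename(columns={"k": "count"})
    if positives.empty:
        raise ValueError("enriched set is empty")
    if max_positives is not None and len(positives) > max_positives:
        sub_rng = np.random.default_rng(seed + 11)
        keep = np.sort(sub_rng.choice(len(positives), size=max_positives, replace=False))
        positives = positives.iloc[keep].reset_index(drop=True)
    enriched_pairs = set()
    for t in enriched_tables:
        enriched_pairs.update(zip(t.df["seq_a"], t.df["seq_b"]))
    naive = naive_table.df[["seq_a", "seq_b", "count"]]
    mask = [
        (a, b) not in enriched_pairs for a, b in zip(naive["seq_a"], naive["seq_b"])
    ]
    candidates = naive[mask].reset_index(drop=True)
    n_pos = len(positives)
    if len(candidates) < n_pos:
        raise ValueError(
            f"insufficient eligible negatives: {len(candidates)} naive-only pairs "
            f"for {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(len(candidates), size=n_pos, replace=False))
    negatives = candidates.iloc[take].reset_index(drop=True)

    maxcount = float(positives["count"].max() + 100)
    positives = positives.assign(
        label=normalize_label(positives["count"].to_numpy(), maxcount), cls="positive"
    )
    negatives = negatives.assign(label=0.0, cls="negative")
    df = pd.concat([positives, negatives], ignore_index=True)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    n_val = int(round(val_fraction * len(df)))
    split = np.array(["train"] * len(df), dtype=object)
    split[:n_val] = "val"
    df["split"] = split
    return PairDataset(df, seed, meta={"maxcount": maxcount})


def novel_aa_bin(
    pair: tuple[str, str],
    training_alphabets: tuple[str | set, str | set],
) -> str:
    """Count residues outside the training alphabets; >= 4 collapses to "4+".

    ``training_alphabets`` holds the per-chain amino-acid sets of the
    training library (chain A, chain B).
    """
    set_a, set_b = (set(training_alphabets[0]), set(training_alphabets[1]))
    n = sum(aa not in set_a for aa in pair[0]) + sum(aa not in set_b for aa in pair[1])
    return "4+" if n >= 4 else str(n)


# ---------------------------------------------------------------------------
# numpy CNN
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture and optimization settings, recorded verbatim in bundles.

    Defaults follow the published recipe (5x5 kernels, channels
    [64, 128, 256], two-layer head, Adam at 1e-4 for 100 epochs with the
    best validation checkpoint); smaller channel/epoch settings are used
    for CPU-scale experiments.
    """

    kernel: tuple[int, int] = (5, 5)
    channels: tuple[int, ...] = (64, 128, 256)
    pool: int = 2
    hidden: tuple[int, ...] = (256, 1)
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    checkpoint: str = "val_loss"
    standardize_input: bool = True

    def __post_init__(self) -> None:
        if min(self.kernel) < 1 or min(self.channels) < 1 or self.pool < 1:
            raise ValueError("kernel, channels and pool must be positive")
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, epochs and batch_size must be positive")
        if self.hidden[-1] != 1:
            raise ValueError("final head width must be 1 (scalar binding score)")

    def to_dict(self) -> dict:
        return {
            "kernel": list(self.kernel), "channels": list(self.channels),
            "pool": self.pool, "hidden": list(self.hidden), "lr": self.lr,
            "epochs": self.epochs, "batch_size": self.batch_size,
            "seed": self.seed, "checkpoint": self.checkpoint,
        }


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding stride-1 cross-correlation via im2col.

    x: (N, Cin, H, W); w: (Cout, Cin, K, K). Returns (out, cols)."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, Cin, H, W, K, K) -> cols (N*H*W, Cin*K*K)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, cin * kh * kw)
    out = cols @ w.reshape(cout, -1).T + b
    return out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray):
    """Gradients for same-padding stride-1 conv: (dx, dw, db)."""
    n, cout, h, wd = dout.shape
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    # dx = cross-correlation of dout with spatially flipped, channel-swapped w
    w_hat = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    dx, _ = _conv_forward(dout, w_hat, np.zeros(w_hat.shape[0], dtype=w.dtype))
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, p: int):
    n, c, h, w = x.shape
    ho, wo = h // p, w // p
    xr = x[:, :, : ho * p, : wo * p].reshape(n, c, ho, p, wo, p)
    out = xr.max(axis=(3, 5))
    return out, xr


def _maxpool_backward(dout: np.ndarray, xr: np.ndarray, x_shape, p: int):
    n, c, h, w = x_shape
    ho, wo = h // p, w // p
    mx = xr.max(axis=(3, 5), keepdims=True)
    mask = (xr == mx).astype(xr.dtype)
    mask /= mask.sum(axis=(3, 5), keepdims=True)
    dxr = mask * dout[:, :, :, None, :, None]
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : ho * p, : wo * p] = dxr.reshape(n, c, ho * p, wo * p)
    return dx


_IN_EPS = 1e-5


def _instnorm_forward(x: np.ndarray):
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    std = np.sqrt(var + _IN_EPS)
    xhat = (x - mu) / std
    return xhat, std


def _instnorm_backward(dout: np.ndarray, xhat: np.ndarray, std: np.ndarray):
    m1 = dout.mean(axis=(2, 3), keepdims=True)
    m2 = (dout * xhat).mean(axis=(2, 3), keepdims=True)
    return (dout - m1 - xhat * m2) / std


class CNNRegressor:
    """3-layer 2D CNN + 2-layer head over outer-product pair matrices.

    Per layer: InstanceNorm(ReLU(Maxpool(Conv(x)))); head:
    sigmoid(FC(ReLU(FC(flatten)))). Squared-error loss, Adam optimizer.
    """

    def __init__(self, input_dim: int, config: ModelConfig) -> None:
        self.config = config
        spatial = input_dim
        for _ in config.channels:
            spatial //= config.pool
            if spatial < 1:
                raise ValueError(
                    f"input {input_dim} too small for {len(config.channels)} "
                    f"pooling stages (receptive field exhausted)"
                )
        self.input_dim = input_dim
        self.flat_dim = spatial * spatial * config.channels[-1]
        rng = np.random.default_rng(config.seed)
        kh, kw = config.kernel
        self.params: dict[str, np.ndarray] = {}
        cin = 1
        for li, cout in enumerate(config.channels):
            fan_in = cin * kh * kw
            self.params[f"w{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kh, kw)
            ).astype(np.float32)
            self.params[f"b{li}"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        dims = [self.flat_dim] + list(config.hidden)
        for li, (din, dh) in enumerate(zip(dims, dims[1:])):
            self.params[f"fw{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / din), size=(dh, din)
            ).astype(np.float32)
            self.params[f"fb{li}"] = np.zeros(dh, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        cache: list = []
        h = x
        for li in range(len(self.config.channels)):
            w, b = self.params[f"w{li}"], self.params[f"b{li}"]
            conv, cols = _conv_forward(h, w, b)
            pooled, xr = _maxpool_forward(conv, self.config.pool)
            relu = np.maximum(pooled, 0.0)
            xhat, std = _instnorm_forward(relu)
            if keep_cache:
                cache.append((cols, conv.shape, xr, pooled, xhat, std))
            h = xhat
        n = h.shape[0]
        flat = h.reshape(n, -1)
        acts = [flat]
        z = flat
        n_fc = len(self.config.hidden)
        for li in range(n_fc):
            z = z @ self.params[f"fw{li}"].T + self.params[f"fb{li}"]
            if li < n_fc - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        pred = 1.0 / (1.0 + np.exp(-z[:, 0]))
        if keep_cache:
            return pred, (cache, acts)
        return pred

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        pred, (cache, acts) = self.forward(x, keep_cache=True)
        n = len(y)
        loss = float(np.mean((pred - y) ** 2))
        grads = {}
        dz = (2.0 / n) * (pred - y) * pred * (1.0 - pred)
        dz = dz[:, None]
        n_fc = len(self.config.hidden)
        # acts[li] is the (post-ReLU) input to FC layer li; acts[0] is the
        # flat conv output, which has no ReLU in front of the first FC.
        for li in range(n_fc - 1, -1, -1):
            grads[f"fw{li}"] = dz.T @ acts[li]
            grads[f"fb{li}"] = dz.sum(axis=0)
            dz = dz @ self.params[f"fw{li}"]
            if li > 0:  # backprop through the ReLU feeding this FC layer
                dz = dz * (acts[li] > 0)
        dh = dz.reshape((x.shape[0],) + self._last_shape())
        for li in range(len(self.config.channels) - 1, -1, -1):
            cols, conv_shape, xr, pooled, xhat, std = cache[li]
            dh = _instnorm_backward(dh, xhat, std)
            dh = dh * (pooled > 0)
            dh = _maxpool_backward(dh, xr, conv_shape, self.config.pool)
            dh, dw, db = _conv_backward(dh, cols, self.params[f"w{li}"])
            grads[f"w{li}"] = dw
            grads[f"b{li}"] = db
        return loss, grads, pred

    def _last_shape(self):
        spatial = self.input_dim
        for _ in self.config.channels:
            spatial //= self.config.pool
        return (self.config.channels[-1], spatial, spatial)

    def adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.config.lr
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class InteractionModelBundle:
    """Trained model with its config, weights, history and provenance.

    ``feat_mean``/``feat_std`` hold the global input standardization
    (single mean and scale from the training split) applied before the
    first convolution; mean-pooled chain embeddings make the raw outer
    products arrive orders of magnitude away from unit scale otherwise.
    """

    config: ModelConfig
    embedder_name: str
    embedder_dim: int
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    best_epoch: int
    seed: int
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return x
        return (x - self.feat_mean) / self.feat_std

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.yaml").write_text(
            yaml.safe_dump(
                {
                    "model": self.config.to_dict(),
                    "embedder": {"name": self.embedder_name, "dim": self.embedder_dim},
                    "best_epoch": self.best_epoch,
                    "seed": self.seed,
                },
                sort_keys=True,
            )
        )
        self.history.to_csv(directory / "history.tsv", sep="\t", index=False)
        extras = {}
        if self.feat_mean is not None:
            extras = {"feat_mean": self.feat_mean, "feat_std": self.feat_std}
        np.savez(directory / "weights.npz", **self.params, **extras)

    def make_model(self, input_dim: int) -> CNNRegressor:
        model = CNNRegressor(input_dim, self.config)
        model.params = {k: v.copy() for k, v in self.params.items()}
        return model


def _featurize(
    pairs: Sequence[tuple[str, str]],
    embedder: Embedder,
    design: LibraryDesign,
) -> np.ndarray:
    """Outer-product features (N, 1, D, D) for variable-region pairs.

    Full chains (scaffold with the variant substituted at library
    positions) are embedded; embeddings are cached per unique chain.
    """
    chains_a = [design.apply_variant("A", a) for a, _ in pairs]
    chains_b = [design.apply_variant("B", b) for _, b in pairs]
    va = embedder.embed_batch(chains_a).astype(np.float32)
    vb = embedder.embed_batch(chains_b).astype(np.float32)
    return np.einsum("ni,nj->nij", va, vb)[:, None, :, :]


def train_model(
    dataset: PairDataset,
    embedder: Embedder,
    config: ModelConfig,
    design: LibraryDesign,
) -> InteractionModelBundle:
    """Train the CNN on a labeled dataset; return the best-validation bundle.

    Reproducible for fixed config seed: initialization, batch order and the
    recorded loss history are all driven by one generator.
    """
    train = dataset.subset("train")
    val = dataset.subset("val")
    if train.empty or val.empty:
        raise ValueError("dataset must contain both train and val splits")
    x_train = _featurize(list(zip(train["seq_a"], train["seq_b"])), embedder, design)
    y_train = train["label"].to_numpy(dtype=np.float32)
    x_val = _featurize(list(zip(val["seq_a"], val["seq_b"])), embedder, design)
    y_val = val["label"].to_numpy(dtype=np.float32)

    # global input standardization over the training split: one mean and
    # one scale, so the input reaches the first convolution at unit scale
    # without distorting the outer product's internal geometry
    if config.standardize_input:
        feat_mean = np.float32(x_train.mean()).reshape(1, 1, 1, 1)
        feat_std = np.float32(x_train.std() + 1e-8).reshape(1, 1, 1, 1)
        x_train = (x_train - feat_mean) / feat_std
        x_val = (x_val - feat_mean) / feat_std
    else:
        feat_mean = feat_std = None

    model = CNNRegressor(embedder.dim, config)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = -1
    n = len(y_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            loss, grads, _ = model.loss_and_grads(x_train[idx], y_train[idx])
            model.adam_step(grads)
            losses.append(loss * len(idx))
        train_loss = float(np.sum(losses) / n)
        val_pred = predict_matrix(model, x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        record = {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        criterion = val_loss
        if config.checkpoint == "val_auc":
            y_bin = (y_val > 0).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                record["val_auc"] = float(roc_auc_score(y_bin, val_pred))
                criterion = -record["val_auc"]
        history.append(record)
        if criterion < best_val:
            best_val = criterion
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
    return InteractionModelBundle(
        config=copy.deepcopy(config),
        embedder_name=embedder.name,
        embedder_dim=embedder.dim,
        params=best_params,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        seed=config.seed,
        feat_mean=feat_mean,
        feat_std=feat_std,
    )


def predict_matrix(model: CNNRegressor, x: np.ndarray, batch: int = 256) -> np.ndarray:
    out = np.empty(len(x))
    for lo in range(0, len(x), batch):
        out[lo: lo + batch] = model.forward(x[lo: lo + batch])
    return out


def predict_pairs(
    bundle: InteractionModelBundle,
    pairs: Sequence[tuple[str, str]],
    embedder: Embedder,
    design: LibraryDesign,
) -> np.ndarray:
    """Score variant pairs with a trained bundle."""
    model = bundle.make_model(embedder.dim)
    return predict_matrix(model, bundle.standardize(_featurize(pairs, embedder, design)))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

BIN_ORDER = ["0", "1", "2", "3", "4+"]


@dataclass
class EvalReport:
    """Classification metrics, per-bin breakdown and round-wise trends."""

    auc: float | None
    ap: float | None
    per_bin: pd.DataFrame
    round_means: pd.DataFrame | None = None
    round_spearman: tuple[float, float] | None = None
    top_hits: pd.DataFrame | None = None
    note: str = ""


def _safe_metrics(y: np.ndarray, scores: np.ndarray):
    if len(np.unique(y)) < 2:
        return None, None
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def evaluate(
    bundle: InteractionModelBundle,
    test_df: pd.DataFrame,
    embedder: Embedder,
    design: LibraryDesign,
    training_alphabets: tuple[str, str] | None = None,
    per_round_tables: Sequence[PairCountTable] | None = None,
    per_round_scalar: Mapping[str, float] | None = None,
    truth_for_topk: Mapping[tuple[str, str], int] | None = None,
    top_k: int = 11,
) -> EvalReport:
    """Evaluate a trained bundle on a labeled test set.

    ``test_df`` needs columns seq_a, seq_b and cls (positive/negative).
    With ``training_alphabets``, metrics are additionally stratified by
    novel-amino-acid bin. With per-round tables, mean predicted score per
    round is reported, plus its Spearman rank correlation against an
    external per-round scalar (e.g. a retention readout) when supplied.
    Single-class test labels give an undefined-metric result with a note.
    """
    pairs = list(zip(test_df["seq_a"], test_df["seq_b"]))
    scores = predict_pairs(bundle, pairs, embedder, design)
    y = (test_df["cls"] == "positive").to_numpy(dtype=int)
    auc, ap = _safe_metrics(y, scores)
    note = "" if auc is not None else "single-class test labels: AUC/AP undefined"

    bin_rows = []
    if training_alphabets is not None:
        bins = np.array([novel_aa_bin(p, training_alphabets) for p in pairs])
        for b in BIN_ORDER:
            mask = bins == b
            if not mask.any():
                continue
            bauc, bap = _safe_metrics(y[mask], scores[mask])
            bin_rows.append(
                {"bin": b, "n": int(mask.sum()), "auc": bauc, "ap": bap,
                 "mean_score": float(scores[mask].mean())}
            )
    per_bin = pd.DataFrame(bin_rows)

    round_means = None
    round_spearman = None
    if per_round_tables:
        model = bundle.make_model(embedder.dim)
        rows = []
        for t in per_round_tables:
            rpairs = list(zip(t.df["seq_a"], t.df["seq_b"]))
            rscores = predict_matrix(
                model, bundle.standardize(_featurize(rpairs, embedder, design))
            )
            w = t.df["count"].to_numpy(dtype=float)
            rows.append(
                {"round": t.round_label,
                 "mean_score": float(np.average(rscores, weights=w)),
                 "n_pairs": len(rpairs)}
            )
        round_means = pd.DataFrame(rows)
        if per_round_scalar is not None:
            merged = round_means[round_means["round"].isin(per_round_scalar)]
            if len(merged) >= 3:
                rho, pval = _sstats.spearmanr(
                    merged["mean_score"],
                    [per_round_scalar[r] for r in merged["round"]],
                )
                round_spearman = (float(rho), float(pval))

    top_hits = None
    if truth_for_topk is not None:
        order = np.argsort(-scores, kind="stable")[:top_k]
        top_hits = pd.DataFrame(
            {
                "seq_a": [pairs[i][0] for i in order],
                "seq_b": [pairs[i][1] for i in order],
                "score": scores[order],
                "hit": [int(truth_for_topk.get(pairs[i], 0)) for i in order],
            }
        )
    return EvalReport(auc, ap, per_bin, round_means, round_spearman, top_hits, note)
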