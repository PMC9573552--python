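"""Permutation-invariant spot-to-lenslet matching network.

Spot-to-lenslet association is cast as a per-point classification problem
over an unordered set of k centroid coordinates.  The architecture is a
symmetric-function (point-set) network: a shared-weight pointwise MLP lifts
each 2-D point to a 512-dimensional feature, elementwise max pooling over
the points produces a single order-independent 1x512 global feature, and a
shared pointwise head maps each point's [local || global] feature to k
class scores (one score per effective lenslet).  ReLU and batch
normalization follow every stage but the last; training minimizes the
softmax cross-entropy against one-hot lenslet labels with Adam.

Because every per-point operation is shared and the pooling is symmetric,
the mapping {point -> score vector} is exactly invariant to the order in
which the points are presented.

The network is small enough that it is implemented directly on NumPy
(float32 forward/backward passes, explicit Adam); training a scaled sensor
takes minutes on one CPU core.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .centroid import CentroidSet, CorrelatorTemplate, extract_centroids, gaussian_template
from .forward_model import LensletGeometry, render_frame, spot_positions
from .zernike import sample_coefficients

__all__ = [
    "SamplerConfig",
    "TrainingConfig",
    "PointDataset",
    "MatchNetwork",
    "SpotAssignment",
    "normalize_points",
    "make_dataset",
    "softmax_loss",
    "train",
    "assign",
]

logger = logging.getLogger(__name__)

_EPS = 1e-5  # batch-norm variance floor


# ---------------------------------------------------------------------------
# Configuration and data containers


@dataclass(frozen=True)
class SamplerConfig:
    """Random-wavefront sampler settings for dataset generation."""

    n_modes: int = 15
    rms_range: tuple[float, float] = (0.1, 2.0)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings (defaults follow the reference protocol:
    Adam, learning rate 1e-3, 50 epochs, batch 8, first-moment coefficient
    0.9, step decay 0.7 every 10 epochs)."""

    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 8
    beta1: float = 0.9  # Adam first-moment coefficient ("momentum")
    beta2: float = 0.999
    decay_factor: float = 0.7
    decay_every: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class PointDataset:
    """Normalized point sets with per-point lenslet labels.

    ``points``: (N, k, 2) float32 in [-1, 1] frame-normalized coordinates
    (large displacements may exceed the nominal range slightly);
    ``labels``: (N, k) int lenslet ids.
    """

    points: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class SpotAssignment:
    """Bijective centroid -> lenslet mapping with per-pair confidence."""

    mapping: np.ndarray  # (k,) lenslet id for centroid i
    confidence: np.ndarray  # (k,)
    warnings: list[str] = field(default_factory=list)

    def inverse(self) -> np.ndarray:
        """lenslet id -> centroid index."""
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.mapping.size)
        return inv


def normalize_points(points_px: np.ndarray, geometry: LensletGeometry) -> np.ndarray:
    """Map global pixel coordinates to [-1, 1] per axis (frame extent)."""
    h, w = geometry.frame_shape
    p = np.asarray(points_px, dtype=np.float64)
    out = np.empty_like(p)
    out[..., 0] = 2.0 * p[..., 0] / (w - 1) - 1.0
    out[..., 1] = 2.0 * p[..., 1] / (h - 1) - 1.0
    return out


# ---------------------------------------------------------------------------
# Network


def _bn_forward(x, gamma, beta, running, train):
    """Batch norm over all leading axes (per trailing feature)."""
    if train:
        axes = tuple(range(x.ndim - 1))
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = 0.9 * running["mean"] + 0.1 * mean
        running["var"] = 0.9 * running["var"] + 0.1 * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mean) * inv
    return gamma * xhat + beta, (xhat, inv)


def _bn_backward(dout, cache, gamma):
    xhat, inv = cache
    axes = tuple(range(dout.ndim - 1))
    n = float(np.prod([dout.shape[a] for a in axes]))
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma
    dx = inv / n * (n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
    return dx, dgamma, dbeta


class MatchNetwork:
    """Shared-weight point-set classifier (see module docstring).

    Parameters
    ----------
    k_classes : number of effective lenslets (= number of points).
    encoder : per-point feature widths, default (64, 512).
    head_width : hidden width of the per-point classification head.
    seed : initialization seed.
    """

    def __init__(
        self,
        k_classes: int,
        encoder: tuple[int, int] = (64, 512),
        head_width: int = 256,
        seed: int = 0,
    ):
        self.k_classes = int(k_classes)
        self.encoder = tuple(encoder)
        self.head_width = int(head_width)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d1, d2 = self.encoder
        dims = [(2, d1), (d1, d2), (2 * d2, head_width), (head_width, k_classes)]
        self.params: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(dims, start=1):
            scale = np.sqrt(2.0 / fan_in) if i < 4 else np.sqrt(1.0 / fan_in)
            self.params[f"W{i}"] = (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(fan_out, dtype=np.float32)
        for i, d in zip((1, 2, 3), (d1, d2, head_width)):
            self.params[f"g{i}"] = np.ones(d, dtype=np.float32)
            self.params[f"be{i}"] = np.zeros(d, dtype=np.float32)
        self.running = {
            i: {"mean": np.zeros(d, dtype=np.float32), "var": np.ones(d, dtype=np.float32)}
            for i, d in zip((1, 2, 3), (d1, d2, head_width))
        }

    # -- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        """X: (B, n, 2) -> logits (B, n, k) plus cache for backprop.

        Internally all pointwise stages run on a flattened (B*n, features)
        matrix (shared weights = one GEMM); only the max pooling needs the
        (B, n) structure.
        """
        p = self.params
        B, n, _ = X.shape
        Xf = X.reshape(B * n, 2).astype(np.float32, copy=False)
        z1 = Xf @ p["W1"] + p["b1"]
        a1, bn1 = _bn_forward(z1, p["g1"], p["be1"], self.running[1], train)
        h1 = np.maximum(a1, 0.0)
        z2 = h1 @ p["W2"] + p["b2"]
        a2, bn2 = _bn_forward(z2, p["g2"], p["be2"], self.running[2], train)
        h2 = np.maximum(a2, 0.0)
        d2 = h2.shape[-1]
        h2b = h2.reshape(B, n, d2)
        gmax = h2b.max(axis=1)  # (B, d2) global feature
        argm = h2b.argmax(axis=1)
        c = np.concatenate([h2, np.repeat(gmax, n, axis=0)], axis=-1)
        z3 = c @ p["W3"] + p["b3"]
        a3, bn3 = _bn_forward(z3, p["g3"], p["be3"], self.running[3], train)
        h3 = np.maximum(a3, 0.0)
        logits = (h3 @ p["W4"] + p["b4"]).reshape(B, n, self.k_classes)
        cache = (Xf, a1, h1, a2, argm, c, a3, h3, bn1, bn2, bn3, (B, n))
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache):
        p = self.params
        Xf, a1, h1, a2, argm, c, a3, h3, bn1, bn2, bn3, (B, n) = cache
        d2 = self.encoder[1]
        dlog = dlogits.reshape(B * n, self.k_classes)
        g: dict[str, np.ndarray] = {}
        g["W4"] = h3.T @ dlog
        g["b4"] = dlog.sum(axis=0)
        dh3 = dlog @ p["W4"].T
        da3 = dh3 * (a3 > 0)
        dz3, g["g3"], g["be3"] = _bn_backward(da3, bn3, p["g3"])
        g["W3"] = c.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dc = dz3 @ p["W3"].T
        dh2 = dc[:, :d2].copy()
        dgmax = dc[:, d2:].reshape(B, n, d2).sum(axis=1)  # (B, d2)
        # route the pooled gradient back to each feature's argmax point
        flat_rows = argm + (np.arange(B) * n)[:, None]  # (B, d2) row indices
        f_idx = np.broadcast_to(np.arange(d2), (B, d2))
        np.add.at(dh2, (flat_rows, f_idx), dgmax)
        h2pos = np.maximum(a2, 0.0) > 0
        da2 = dh2 * h2pos
        dz2, g["g2"], g["be2"] = _bn_backward(da2, bn2, p["g2"])
        g["W2"] = h1.T @ dz2
        g["b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ p["W2"].T
        da1 = dh1 * (a1 > 0)
        dz1, g["g1"], g["be1"] = _bn_backward(da1, bn1, p["g1"])
        g["W1"] = Xf.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        return g

    # -- public API -------------------------------------------------------

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Per-point class probabilities.

        ``points``: (n, 2) or (B, n, 2) normalized coordinates; returns the
        matching (n, k) or (B, n, k) array of probability vectors (each row
        non-negative, summing to 1).
        """
        pts = np.asarray(points, dtype=np.float32)
        single = pts.ndim == 2
        if single:
            pts = pts[None]
        if pts.ndim != 3 or pts.shape[-1] != 2:
            raise ValueError(f"expected (B, n, 2) points, got {pts.shape}")
        logits, _ = self._forward(pts, train=False)
        probs = _softmax(logits)
        return probs[0] if single else probs

    def global_feature(self, points: np.ndarray) -> np.ndarray:
        """The max-pooled 1x512 global feature (order-invariant)."""
        pts = np.asarray(points, dtype=np.float32)[None]
        p = self.params
        z1 = pts @ p["W1"] + p["b1"]
        a1, _ = _bn_forward(z1, p["g1"], p["be1"], self.running[1], False)
        h1 = np.maximum(a1, 0.0)
        z2 = h1 @ p["W2"] + p["b2"]
        a2, _ = _bn_forward(z2, p["g2"], p["be2"], self.running[2], False)
        h2 = np.maximum(a2, 0.0)
        return h2.max(axis=1)[0]

    # -- persistence ------------------------------------------------------

    def save(self, path, geometry: LensletGeometry | None = None) -> None:
        meta = {
            "k_classes": self.k_classes,
            "encoder": list(self.encoder),
            "head_width": self.head_width,
            "seed": self.seed,
            "geometry_hash": geometry_hash(geometry) if geometry else None,
        }
        arrays = dict(self.params)
        for i, r in self.running.items():
            arrays[f"rm{i}"] = r["mean"]
            arrays[f"rv{i}"] = r["var"]
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, geometry: LensletGeometry | None = None) -> "MatchNetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            net = cls(
                k_classes=meta["k_classes"],
                encoder=tuple(meta["encoder"]),
                head_width=meta["head_width"],
                seed=meta["seed"],
            )
            for k in net.params:
                net.params[k] = data[k]
            for i in net.running:
                net.running[i] = {"mean": data[f"rm{i}"], "var": data[f"rv{i}"]}
        if geometry is not None and meta.get("geometry_hash") not in (
            None,
            geometry_hash(geometry),
        ):
            warnings.warn("checkpoint was trained for a different sensor geometry")
        return net


def geometry_hash(geometry: LensletGeometry) -> str:
    return hashlib.sha256(repr(geometry.config).encode()).hexdigest()[:16]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Loss


def softmax_loss(pred: np.ndarray, labels_onehot: np.ndarray, reduction: str = "mean") -> float:
    """Cross-entropy  -sum_i y_i log(yhat_i)  between per-point probability
    vectors and one-hot labels; ``reduction`` is "mean" (per point) or
    "sum"."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(labels_onehot, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("shape mismatch between predictions and labels")
    if not np.allclose(y.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("labels must be normalized (one-hot) per point")
    ll = -(y * np.log(np.clip(pred, 1e-12, None))).sum(axis=-1)
    if reduction == "mean":
        return float(ll.mean())
    if reduction == "sum":
        return float(ll.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# Dataset generation


def make_dataset(
    n_wavefronts: int,
    geometry: LensletGeometry,
    sampler: SamplerConfig | None = None,
    split: float = 0.9,
    rng_seed: int = 0,
    method: str = "extract",
    sigma_px: float = 1.0,
    template: CorrelatorTemplate | None = None,
    match_tolerance_px: float = 2.0,
) -> tuple[PointDataset, PointDataset]:
    """Simulate ``n_wavefronts`` random wavefronts and build labelled,
    order-shuffled point sets, split into train/test.

    ``method``:

    * ``"extract"`` — render the frame and run the full whole-frame
      matched-filter extraction; each centroid is labelled with the lenslet
      of the nearest true spot (one-to-one by optimal matching).  Samples
      whose matching is ambiguous (distance above ``match_tolerance_px``)
      are dropped with a warning.
    * ``"analytic"`` — use the forward model's true spot positions directly
      (noiseless extraction shortcut for large runs).
    """
    if n_wavefronts < 2:
        raise ValueError("need at least 2 wavefronts to split")
    if method not in ("extract", "analytic"):
        raise ValueError(f"unknown method {method!r}")
    sampler = sampler or SamplerConfig()
    rng = np.random.default_rng(rng_seed)
    if method == "extract" and template is None:
        template = gaussian_template(sigma_px)
    k = geometry.k_effective
    pts_all, lab_all = [], []
    dropped = 0
    for _ in range(n_wavefronts):
        coeffs = sample_coefficients(
            rng, n_modes=sampler.n_modes, rms_range=sampler.rms_range
        )
        if method == "analytic":
            pos = spot_positions(coeffs, geometry)
            labels = np.arange(k)
        else:
            frame, gt = render_frame(coeffs, geometry, sigma_px=sigma_px)
            try:
                cset = extract_centroids(frame, template, k=k)
            except RuntimeError as exc:
                dropped += 1
                logger.debug("extraction failed, sample dropped: %s", exc)
                continue
            d = cdist(cset.points, gt.true_centers)
            rows, cols = linear_sum_assignment(d)
            if d[rows, cols].max() > match_tolerance_px:
                dropped += 1
                logger.debug(
                    "ambiguous centroid/lenslet matching (max dist %.2f px), "
                    "sample dropped", d[rows, cols].max(),
                )
                continue
            pos = cset.points
            labels = np.empty(k, dtype=int)
            labels[rows] = gt.lenslet_ids[cols]
        perm = rng.permutation(k)
        pts_all.append(normalize_points(pos[perm], geometry).astype(np.float32))
        lab_all.append(labels[perm])
    if dropped:
        logger.warning("dropped %d of %d samples", dropped, n_wavefronts)
    points = np.stack(pts_all)
    labels = np.stack(lab_all)
    order = rng.permutation(len(points))
    points, labels = points[order], labels[order]
    n_train = int(round(split * len(points)))
    return (
        PointDataset(points[:n_train], labels[:n_train]),
        PointDataset(points[n_train:], labels[n_train:]),
    )


# ---------------------------------------------------------------------------
# Training


def train(
    net: MatchNetwork,
    dataset: PointDataset,
    cfg: TrainingConfig | None = None,
) -> dict:
    """Train the network in place with Adam; returns the loss history.

    Fully seeded (``cfg.seed`` drives batching); aborts with diagnostics if
    the loss goes non-finite.
    """
    cfg = cfg or TrainingConfig()
    cfg.validate()
    if len(dataset) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    t = 0
    history: dict = {"epoch_loss": [], "lr": []}
    n = len(dataset)
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * cfg.decay_factor ** (epoch // cfg.decay_every)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            X = dataset.points[idx]
            y = dataset.labels[idx]
            logits, cache = net._forward(X, train=True)
            probs = _softmax(logits)
            b, npts, _ = probs.shape
            bi = np.arange(b)[:, None]
            pi = np.arange(npts)[None, :]
            loss = float(-np.log(np.clip(probs[bi, pi, y], 1e-12, None)).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {t}: loss={loss}"
                )
            losses.append(loss)
            dlogits = probs.copy()
            dlogits[bi, pi, y] -= 1.0
            dlogits /= b * npts
            grads = net._backward(dlogits.astype(np.float32), cache)
            t += 1
            for key, p in net.params.items():
                gk = grads[key].astype(np.float32)
                m[key] = cfg.beta1 * m[key] + (1 - cfg.beta1) * gk
                v[key] = cfg.beta2 * v[key] + (1 - cfg.beta2) * gk * gk
                mhat = m[key] / (1 - cfg.beta1**t)
                vhat = v[key] / (1 - cfg.beta2**t)
                p -= (lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32)
        history["epoch_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
        logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, history["epoch_loss"][-1])
    return history


def accuracy(net: MatchNetwork, dataset: PointDataset, batch: int = 64) -> float:
    """Per-point classification accuracy on a dataset."""
    correct = 0
    total = 0
    for start in range(0, len(dataset), batch):
        X = dataset.points[start : start + batch]
        y = dataset.labels[start : start + batch]
        pred = net.forward(X).argmax(axis=-1)
        correct += int((pred == y).sum())
        total += y.size
    return correct / total


# ---------------------------------------------------------------------------
# Assignment


def assign(
    net: MatchNetwork,
    centroids: CentroidSet,
    geometry: LensletGeometry,
    method: str = "greedy",
    min_separation_px: float = 2.0,
) -> SpotAssignment:
    """One-to-one centroid -> lenslet assignment from network probabilities.

    ``method="greedy"`` (default) assigns highest-confidence pairs first
    with exclusion; ``method="optimal"`` solves the linear assignment
    problem maximizing the total log-probability.

    Degenerate configurations are flagged (not resolved) with warnings:
    centroids closer than ``min_separation_px`` (merged/overlapping spots)
    and centroid pairs whose top-2 class sets coincide (swap-ambiguous).
    """
    pts = centroids.points
    if len(centroids) != geometry.k_effective:
        raise ValueError(
            f"expected {geometry.k_effective} centroids, got {len(centroids)}"
        )
    probs = net.forward(normalize_points(pts, geometry))
    mapping, confidence = _bijective_assignment(probs, method)
    warns = assignment_warnings(probs, pts, min_separation_px)
    for w in warns:
        warnings.warn(w)
    return SpotAssignment(mapping=mapping, confidence=confidence, warnings=warns)


def _bijective_assignment(probs: np.ndarray, method: str = "greedy"):
    k = probs.shape[0]
    if probs.shape != (k, k):
        raise ValueError("probability matrix must be square (k points, k classes)")
    mapping = np.full(k, -1, dtype=int)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-np.log(np.clip(probs, 1e-12, None)))
        mapping[rows] = cols
    elif method == "greedy":
        order = np.argsort(probs, axis=None)[::-1]
        used_pt = np.zeros(k, dtype=bool)
        used_cl = np.zeros(k, dtype=bool)
        assigned = 0
        for flat in order:
            i, c = divmod(int(flat), k)
            if used_pt[i] or used_cl[c]:
                continue
            mapping[i] = c
            used_pt[i] = used_cl[c] = True
            assigned += 1
            if assigned == k:
                break
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    confidence = probs[np.arange(k), mapping]
    return mapping, confidence


def assignment_warnings(
    probs: np.ndarray, points_px: np.ndarray, min_separation_px: float = 2.0
) -> list[str]:
    """Detect the two irreducible degeneracies: merged/overlapping spots and
    swap-ambiguous pairs (identical top-2 label sets)."""
    warns: list[str] = []
    k = probs.shape[0]
    d = cdist(points_px, points_px)
    np.fill_diagonal(d, np.inf)
    ii, jj = np.where(np.triu(d < min_separation_px))
    for i, j in zip(ii, jj):
        warns.append(
            f"centroids {i} and {j} are {d[i, j]:.2f} px apart: "
            "overlapping or merged spots, local aberration unreliable"
        )
    top2 = np.argsort(probs, axis=1)[:, -2:]
    top2sets = [frozenset(map(int, row)) for row in top2]
    for i in range(k):
        for j in range(i + 1, k):
            if top2sets[i] == top2sets[j]:
                warns.append(
                    f"centroids {i} and {j} share top-2 lenslet candidates "
                    f"{sorted(top2sets[i])}: possible spot swap, assignment ambiguous"
                )
    return warns
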