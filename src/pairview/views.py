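"""The augmentor and aggregator.

A drug pair with modality availability sets A and B is expanded into
|A| x |B| modality-pair views.  Each view embedding is one transformation of
[z_ma | z_mb | c]; a shared head scores every view, and the aggregator keeps
the top-k view predictions (noisy-label masking), combining them through a
learnable affine term plus a shortcut mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .data import MODALITIES, ModalityId, modality_order

EPS_CLAMP = 1e-7  # classification outputs are clamped into (eps, 1-eps)

ViewKey = tuple[ModalityId, ModalityId]

ALL_VIEW_KEYS: tuple[ViewKey, ...] = tuple(
    (ma, mb) for ma in MODALITIES for mb in MODALITIES
)
VIEW_KEY_INDEX = {k: i for i, k in enumerate(ALL_VIEW_KEYS)}


def enumerate_views(avail_a, avail_b) -> list[ViewKey]:
    """Full Cartesian product of the two availability sets, in canonical
    modality order; (ma, mb) pairs drug A's modality with drug B's."""
    if not avail_a:
        raise ValueError("drug A has no available modality")
    if not avail_b:
        raise ValueError("drug B has no available modality")
    a = sorted(avail_a, key=modality_order)
    b = sorted(avail_b, key=modality_order)
    return [(ma, mb) for ma in a for mb in b]


@dataclass
class ViewBundle:
    """Per-triplet view inventory: embeddings and per-view predictions."""

    triplet_id: int
    views: dict[ViewKey, tuple[np.ndarray, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.views:
            self._check()

    def _check(self):
        if not self.views:
            raise ValueError("a view bundle must hold at least one view")
        for key, (_, p) in self.views.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"view {key}: prediction {p} outside (0, 1)")

    @property
    def keys(self) -> list[ViewKey]:
        return sorted(self.views, key=lambda k: VIEW_KEY_INDEX[k])

    def prediction_vector(self) -> np.ndarray:
        return np.array([self.views[k][1] for k in self.keys])


@dataclass
class AggregatedPrediction:
    triplet_id: int
    value: float
    retained_keys: tuple[ViewKey, ...]


class Augmentor:
    """One-layer view transformation: Dropout(ReLU(W [z_ma | z_mb | c])),
    R^(3 d_hid) -> R^(2 d_hid).  For interaction-type tasks the context enters
    later through the bilinear head, so the input is [z_ma | z_mb] and the
    activation is Tanh (R^(2 d_hid) -> R^(2 d_hid))."""

    def __init__(self, dhid: int, rng: np.random.Generator, dropout: float = 0.0,
                 with_context: bool = True):
        n_in = (3 if with_context else 2) * dhid
        self.linear = nn.Linear(n_in, 2 * dhid, rng)
        self.dropout = dropout
        self.with_context = with_context

    def parameters(self):
        return self.linear.parameters()

    def __call__(self, x: nn.Tensor, rng=None, train: bool = False) -> nn.Tensor:
        h = self.linear(x)
        h = h.relu() if self.with_context else h.tanh()
        return nn.dropout(h, self.dropout, rng, train)


def build_view_embedding(z_ma: nn.Tensor, z_mb: nn.Tensor, c: nn.Tensor,
                         augmentor: Augmentor, rng=None, train: bool = False) -> nn.Tensor:
    """View embedding for one (modality-a, modality-b, context) triple."""
    for name, v in (("z_ma", z_ma), ("z_mb", z_mb), ("c", c)):
        if v.shape[-1] != z_ma.shape[-1]:
            raise ValueError(f"{name}: length {v.shape[-1]} != d_hid {z_ma.shape[-1]}")
    return augmentor(nn.concat([z_ma, z_mb, c], axis=-1), rng=rng, train=train)


class SynergyHead:
    """Shared two-layer per-view classifier/regressor:
    w2 . Dropout(ReLU(w1 . z)); sigmoid for classification tasks."""

    def __init__(self, dhid: int, rng: np.random.Generator, dropout: float = 0.0,
                 classify: bool = True):
        self.l1 = nn.Linear(2 * dhid, dhid, rng)
        self.l2 = nn.Linear(dhid, 1, rng)
        self.dropout = dropout
        self.classify = classify

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()

    def __call__(self, z: nn.Tensor, rng=None, train: bool = False) -> nn.Tensor:
        h = nn.dropout(self.l1(z).relu(), self.dropout, rng, train)
        s = self.l2(h).reshape(-1) if z.ndim > 1 else self.l2(h).reshape(())
        return s.sigmoid() if self.classify else s


def predict_view_synergy(z: nn.Tensor, head: SynergyHead, rng=None,
                         train: bool = False) -> nn.Tensor:
    return head(z, rng=rng, train=train)


class DDIHead:
    """Bilinear interaction head: the type embedding is refined as
    c_hat = Dropout(Tanh(c + wc [z | c])) and scored against
    Dropout(Tanh(wz z)); sigmoid of the bilinear product is the probability."""

    def __init__(self, dhid: int, rng: np.random.Generator, dropout: float = 0.0):
        self.dhid = dhid
        self.wc = nn.Linear(3 * dhid, dhid, rng, bias=False)
        self.wz = nn.Linear(2 * dhid, dhid, rng, bias=False)
        self.dropout = dropout

    def parameters(self):
        return self.wc.parameters() + self.wz.parameters()

    def __call__(self, z: nn.Tensor, c: nn.Tensor, rng=None,
                 train: bool = False) -> nn.Tensor:
        if z.shape[-1] != 2 * self.dhid:
            raise ValueError(f"pair embedding length {z.shape[-1]} != {2 * self.dhid}")
        if c.shape[-1] != self.dhid:
            raise ValueError(f"type embedding length {c.shape[-1]} != {self.dhid}")
        if z.ndim > 1 and c.ndim == 1:
            c = c.reshape(1, -1) + nn.constant(np.zeros((z.shape[0], self.dhid)))
        chat = nn.dropout((c + self.wc(nn.concat([z, c], axis=-1))).tanh(),
                          self.dropout, rng, train)
        zhat = nn.dropout(self.wz(z).tanh(), self.dropout, rng, train)
        score = (zhat * chat).sum(axis=-1)
        return score.sigmoid()


def predict_view_ddi(z: nn.Tensor, c: nn.Tensor, head: DDIHead, rng=None,
                     train: bool = False) -> nn.Tensor:
    return head(z, c, rng=rng, train=train)


def top_k_mask(predictions: np.ndarray, k: int) -> np.ndarray:
    """Zero every entry outside the top-min(k, n) set; ties broken in favor of
    the earlier (canonical) position."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= predictions.size:
        return predictions.copy()
    order = np.argsort(-predictions, kind="stable")  # stable: earlier index wins ties
    keep = order[:k]
    out = np.zeros_like(predictions)
    out[keep] = predictions[keep]
    return out


def top_k_indices(values: np.ndarray, k: int, valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Indices of the top-min(k, #valid) entries (stable tie-break)."""
    v = np.asarray(values, dtype=float).copy()
    if valid is not None:
        v[~valid] = -np.inf
        n_valid = int(valid.sum())
    else:
        n_valid = v.size
    order = np.argsort(-v, kind="stable")
    return order[: min(k, n_valid)]


class Aggregator:
    """Top-k noisy-label aggregation: y* = w_nll . masked + shortcut, where
    `masked` zeroes all but the k most confident view predictions.  The
    shortcut is the mean of the retained top-k (optionally sum-over-all / k)."""

    def __init__(self, n_keys: int, rng: np.random.Generator,
                 shortcut_mode: str = "topk_mean"):
        self.w_nll = nn.parameter(rng.normal(0.0, 0.01, size=(n_keys,)))
        self.shortcut_mode = shortcut_mode

    def parameters(self):
        return [self.w_nll]

    def __call__(self, dense_preds: nn.Tensor, valid: np.ndarray, k: int,
                 classify: bool = True) -> nn.Tensor:
        """dense_preds: (n_batch, n_keys) with invalid entries zero;
        valid: boolean mask of the same shape."""
        n_batch, n_keys = dense_preds.shape
        mask = np.zeros((n_batch, n_keys))
        k_eff = np.empty(n_batch)
        for i in range(n_batch):
            keep = top_k_indices(dense_preds.data[i], k, valid[i])
            mask[i, keep] = 1.0
            k_eff[i] = len(keep)
        masked = dense_preds * nn.constant(mask)
        affine = masked @ self.w_nll
        if self.shortcut_mode == "topk_mean":
            shortcut = masked.sum(axis=1) / nn.constant(k_eff)
        else:  # sum of all views over the nominal k
            shortcut = dense_preds.sum(axis=1) * (1.0 / k)
        y = affine + shortcut
        if classify:
            y = y.clamp(EPS_CLAMP, 1.0 - EPS_CLAMP)
        return y


def aggregate(predictions, k: int, w_nll, shortcut_mode: str = "topk_mean",
              classify: bool = True, triplet_id: int = 0) -> AggregatedPrediction:
    """Aggregate one triplet's canonical-ordered view predictions.

    y* = w_nll . top_k_mask(p) + (sum of retained top-k) / k_eff, clamped into
    (0, 1) for classification; unclamped for regression.
    """
    p = np.asarray(predictions, dtype=float)
    w = np.asarray(w_nll, dtype=float)
    if w.shape != p.shape:
        raise ValueError(f"w_nll shape {w.shape} != predictions shape {p.shape}")
    masked = top_k_mask(p, k)
    retained = np.flatnonzero(masked)
    k_eff = min(k, p.size)
    if shortcut_mode == "topk_mean":
        shortcut = masked.sum() / k_eff
    else:
        shortcut = p.sum() / k
    value = float(w @ masked + shortcut)
    if classify:
        value = float(np.clip(value, EPS_CLAMP, 1.0 - EPS_CLAMP))
    return AggregatedPrediction(triplet_id, value, tuple(int(i) for i in retained))
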