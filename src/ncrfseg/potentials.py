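"""Unary and pairwise CRF potentials computed from deep features.

The method's central idea lives here: instead of hand-designed pairwise
terms, every edge's K x K cost matrix is produced by learnable functions
of the deep features.  Pixel features are first augmented with a
sinusoidal positional encoding, re-embedded by a shared pixel-wise MLP
``f``, and for each edge the (symmetric) elementwise squared difference
of the two endpoint embeddings is mapped by a second network ``g`` to K^2
logits whose exponential is the cost matrix M -- strictly positive by
construction.

Classic CRF baselines (spatial, intensity, posterior kernels with a Potts
label-compatibility) are provided on the same 8-neighbour graph so the
learned potentials can be compared against fixed ones.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import OFFSETS, EdgePotentials, NeighborGraph, edge_slices
from .nn import MLP

#: Euclidean pixel distance of each canonical edge direction.
OFFSET_DISTANCE = {off: float(np.hypot(*off)) for off in OFFSETS}

#: Clamp applied to g's output before exponentiation, guarding exp overflow.
LOGIT_CLAMP = 30.0


# ---------------------------------------------------------------------
# positional encoding
# ---------------------------------------------------------------------

def positional_encoding(height: int, width: int, channels: int,
                        growing_frequency: bool = False) -> np.ndarray:
    """Sinusoidal position table of shape (H, W, C), entries in [-1, 1].

    Channels come in groups of four: ``(sin wj, cos wj, sin wi, cos wi)``
    for group index ``k = c // 4`` with frequency ``w = 10000**(-4k/C)``.
    ``growing_frequency=True`` flips the exponent's sign to
    ``10000**(+4k/C)``; the decaying convention is the default because the
    growing one aliases severely on image-sized grids.
    """
    if channels % 4:
        raise ValueError("channel count must be divisible by 4 for "
                         "positional encoding")
    ks = np.arange(channels // 4)
    expo = 4.0 * ks / channels
    omega = 10000.0 ** (expo if growing_frequency else -expo)
    jj = np.arange(width)[:, None] * omega[None, :]   # (W, C/4)
    ii = np.arange(height)[:, None] * omega[None, :]  # (H, C/4)
    pe = np.empty((height, width, channels))
    pe[:, :, 0::4] = np.sin(jj)[None, :, :]
    pe[:, :, 1::4] = np.cos(jj)[None, :, :]
    pe[:, :, 2::4] = np.sin(ii)[:, None, :]
    pe[:, :, 3::4] = np.cos(ii)[:, None, :]
    return pe


def add_positional_encoding(features: np.ndarray, pe: np.ndarray) -> np.ndarray:
    """Elementwise sum o' = o + PE."""
    features = np.asarray(features)
    pe = np.asarray(pe)
    if features.shape != pe.shape:
        raise ValueError(f"feature shape {features.shape} does not match "
                         f"positional encoding shape {pe.shape}")
    return features + pe


# ---------------------------------------------------------------------
# unary potentials
# ---------------------------------------------------------------------

def compute_unary(features: np.ndarray, weight: np.ndarray,
                  bias: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel affine map of features to K-label costs: (H,W,C) -> (H,W,K)."""
    features = np.asarray(features, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if features.shape[-1] != weight.shape[0]:
        raise ValueError(f"feature width {features.shape[-1]} does not match "
                         f"weight shape {weight.shape}")
    out = features @ weight
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)
    return out


# ---------------------------------------------------------------------
# learned pairwise potentials
# ---------------------------------------------------------------------

_DIFFERENCES = {
    "squared": lambda a, b: (a - b) * (a - b),
    "absolute": lambda a, b: ad.relu(a - b) + ad.relu(b - a),
}


def encode_features(features: np.ndarray, mlp: MLP | None) -> np.ndarray:
    """Apply the shared pixel-wise embedding f; ``mlp=None`` is the identity."""
    features = np.asarray(features, dtype=float)
    if mlp is None:
        return features.copy()
    if features.shape[-1] != mlp.layers[0].in_features:
        raise ValueError("feature width does not match the embedding MLP input")
    return mlp(Tensor(features)).data


def binary_tables_tensor(phi: Tensor, g: MLP, n_labels: int,
                         difference: str = "squared",
                         clamp: float = LOGIT_CLAMP) -> dict:
    """Differentiable per-direction pairwise tables from embedded features.

    ``phi``: (B, H, W, D).  Returns {offset: Tensor (B, h', w', K, K)} with
    M = exp(clip(g(d(phi_p, phi_q)))); d symmetric, so both directions of
    an edge share the matrix.
    """
    if difference not in _DIFFERENCES:
        raise ValueError(f"unknown difference function {difference!r}")
    diff_fn = _DIFFERENCES[difference]
    _, height, width, _ = phi.shape
    tables = {}
    for off in OFFSETS:
        src, dst = edge_slices(height, width, off)
        if min(height - off[0], width - abs(off[1])) < 1:
            continue
        phi_src = phi[(slice(None),) + src]
        phi_dst = phi[(slice(None),) + dst]
        d = diff_fn(phi_src, phi_dst)
        logits = ad.clip(g(d), -clamp, clamp)
        b, hh, ww, _ = logits.shape
        tables[off] = ad.exp(ad.reshape(logits, (b, hh, ww, n_labels, n_labels)))
    return tables


def compute_binary_potentials(encoded: np.ndarray, graph: NeighborGraph,
                              g: MLP, difference: str = "squared",
                              clamp: float = LOGIT_CLAMP) -> EdgePotentials:
    """Edge-wise K x K matrices M = exp(g(d(phi_p, phi_q))) on the grid."""
    encoded = np.asarray(encoded, dtype=float)
    if not np.all(np.isfinite(encoded)):
        raise ValueError("encoded features must be finite")
    k2 = g.layers[-1].out_features
    n_labels = int(round(np.sqrt(k2)))
    if n_labels * n_labels != k2:
        raise ValueError("g must output a square number of logits (K*K)")
    tables_t = binary_tables_tensor(Tensor(encoded[None]), g, n_labels,
                                    difference=difference, clamp=clamp)
    tables = {off: t.data[0] for off, t in tables_t.items()}
    for di, dj in OFFSETS:
        if (di, dj) not in tables:
            tables[(di, dj)] = np.zeros((max(graph.height - di, 0),
                                         max(graph.width - abs(dj), 0),
                                         n_labels, n_labels))
    return EdgePotentials(graph.height, graph.width, n_labels, tables)


# ---------------------------------------------------------------------
# baseline (fixed-kernel) pairwise potentials
# ---------------------------------------------------------------------

def potts_tables_tensor(feature: Tensor | None, height: int, width: int,
                        n_labels: int, theta_spatial: float = 1.0,
                        theta_feature: float = 0.1,
                        weight: float = 1.0) -> dict:
    """Potts-compatibility tables: zero on-diagonal, Gaussian kernel off.

    The spatial kernel ``w * exp(-dist^2 / 2 theta_s^2)`` depends only on
    the edge direction.  When ``feature`` (B, H, W, F) is given, it is
    multiplied by ``exp(-||f_p - f_q||^2 / 2 theta_f^2)`` -- pixel
    intensities for the intensity kernel, class posteriors for the
    posterior kernel.  Differentiable when ``feature`` carries gradients.
    """
    offdiag = (1.0 - np.eye(n_labels))
    tables = {}
    for off in OFFSETS:
        if min(height - off[0], width - abs(off[1])) < 1:
            continue
        dist = OFFSET_DISTANCE[off]
        k_spatial = weight * float(np.exp(-dist ** 2 / (2.0 * theta_spatial ** 2)))
        if feature is None:
            h, w = height - off[0], width - abs(off[1])
            tables[off] = Tensor(np.broadcast_to(
                k_spatial * offdiag, (1, h, w, n_labels, n_labels)).copy())
            continue
        src, dst = edge_slices(height, width, off)
        f_src = feature[(slice(None),) + src]
        f_dst = feature[(slice(None),) + dst]
        diff = f_src - f_dst
        sq = ad.tsum(diff * diff, axis=-1)  # (B, h, w)
        kernel = ad.exp(sq * (-1.0 / (2.0 * theta_feature ** 2))) * k_spatial
        b, hh, ww = kernel.shape
        kernel = ad.reshape(kernel, (b, hh, ww, 1, 1))
        tables[off] = kernel * offdiag
    return tables


def baseline_potentials(kind: str, image_or_posterior, graph: NeighborGraph,
                        n_labels: int, theta_spatial: float = 1.0,
                        theta_feature: float = 0.1,
                        weight: float = 1.0) -> EdgePotentials:
    """Fixed-kernel pairwise potentials on the 8-neighbour graph.

    ``kind``: ``spatial`` (pixel distance only), ``intensity`` (distance x
    intensity-difference kernel; input (H, W)), or ``posterior`` (distance
    x posterior-difference kernel; input (H, W, K)).
    """
    if kind == "spatial":
        feature = None
    elif kind in ("intensity", "posterior"):
        arr = np.asarray(image_or_posterior, dtype=float)
        if kind == "intensity":
            if arr.ndim != 2:
                raise ValueError("intensity kernel expects an (H, W) image")
            arr = arr[..., None]
        elif arr.ndim != 3:
            raise ValueError("posterior kernel expects an (H, W, K) array")
        feature = Tensor(arr[None])
    else:
        raise ValueError(f"unknown baseline potential kind {kind!r}")
    tables_t = potts_tables_tensor(feature, graph.height, graph.width, n_labels,
                                   theta_spatial=theta_spatial,
                                   theta_feature=theta_feature, weight=weight)
    tables = {}
    for di, dj in OFFSETS:
        if (di, dj) in tables_t:
            tables[(di, dj)] = tables_t[(di, dj)].data[0]
        else:
            tables[(di, dj)] = np.zeros((max(graph.height - di, 0),
                                         max(graph.width - abs(dj), 0),
                                         n_labels, n_labels))
    return EdgePotentials(graph.height, graph.width, n_labels, tables)
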