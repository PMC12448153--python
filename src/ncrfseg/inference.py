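"""Approximate mean-field inference for the neighbourhood CRF.

The factorised distribution Q is initialised from the unary potentials
(Q = softmax(-psi_u) per pixel) and then refined for a fixed number of
iterations: every pixel gathers a pseudo-potential from its neighbours'
current label distributions through the edge matrices M, the unary
potential is added back, and Q is renormalised.  Updates are synchronous
-- all pixels read the previous iteration's Q -- and the whole procedure
is unrolled through the autodiff engine, so gradients reach every
potential parameter during end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import EdgePotentials, NeighborGraph, edge_slices


@dataclass
class InferenceConfig:
    """Mean-field settings: iteration count N and optional early stop.

    ``tolerance`` = 0 (the default) disables early stopping, matching the
    fixed-N procedure used for training; a positive value stops once the
    max-norm change of Q falls below it (analysis use only).
    """

    iterations: int = 5
    tolerance: float = 0.0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iteration count must be non-negative")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def _stable_softmax(neg_cost: np.ndarray) -> np.ndarray:
    shifted = neg_cost - neg_cost.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def initialize_q(unary: np.ndarray) -> np.ndarray:
    """Q = exp(-psi_u)/Z per pixel: a stable softmax over labels."""
    unary = np.asarray(unary, dtype=float)
    if not np.all(np.isfinite(unary)):
        raise ValueError("unary potentials must be finite")
    return _stable_softmax(-unary)


def message_passing(q: np.ndarray, binary: EdgePotentials,
                    graph: NeighborGraph) -> np.ndarray:
    """Pseudo-potential: each pixel sums M[own label, neighbour label] * Q
    over all in-edges and neighbour labels."""
    q = np.asarray(q, dtype=float)
    if q.shape[:2] != (graph.height, graph.width):
        raise ValueError("Q shape does not match graph")
    psi = np.zeros_like(q)
    if not graph.edges:
        return psi
    if graph.is_full_grid():
        for off, table in binary.tables.items():
            if table.size == 0:
                continue
            src, dst = edge_slices(graph.height, graph.width, off)
            # message into the source pixel: sum over the destination label
            psi[src] += np.einsum("hwab,hwb->hwa", table, q[dst])
            # message into the destination pixel: sum over the source label
            psi[dst] += np.einsum("hwab,hwa->hwb", table, q[src])
        return psi
    for p, pq in graph.edges:
        # directed edge p <- pq: matrix(p, pq) is indexed (label_p, label_pq)
        psi[p] += binary.matrix(p, pq) @ q[pq]
    return psi


def mean_field_inference(unary: np.ndarray, binary: EdgePotentials | None,
                         graph: NeighborGraph,
                         config: InferenceConfig | None = None) -> np.ndarray:
    """Run N synchronous mean-field iterations; returns the final Q."""
    config = config or InferenceConfig()
    unary = np.asarray(unary, dtype=float)
    q = initialize_q(unary)
    if binary is None or not graph.edges:
        return q
    for _ in range(config.iterations):
        psi = unary + message_passing(q, binary, graph)
        q_new = _stable_softmax(-psi)
        if config.tolerance > 0 and np.abs(q_new - q).max() < config.tolerance:
            q = q_new
            break
        q = q_new
    return q


# ---------------------------------------------------------------------
# differentiable (batched tensor) path
# ---------------------------------------------------------------------

def messages_tensor(q: Tensor, tables: dict, height: int, width: int) -> Tensor | None:
    """Batched pseudo-potential for grid-shaped edge tables.

    ``q``: (B, H, W, K); ``tables``: {offset: Tensor (B, h', w', K, K)}.
    Returns (B, H, W, K), or None when no tables are present.

    A single fused autodiff node: the four edge directions are contracted
    and accumulated in place, and the backward pass is hand-derived --
    this loop runs five times per forward pass and dominates the CRF
    head's cost otherwise.
    """
    if not tables:
        return None
    qd = q.data
    slices = {off: tuple((slice(None),) + s for s in edge_slices(height, width, off))
              for off in tables}
    contig = np.ascontiguousarray
    psi = np.zeros_like(qd)
    for off, m in tables.items():
        s_idx, d_idx = slices[off]
        # M[a, b] contracts the sender's label on either side of the edge;
        # slices are copied contiguous first (einsum is slow on views)
        psi[s_idx] += np.einsum("...ab,...b->...a", m.data, contig(qd[d_idx]))
        psi[d_idx] += np.einsum("...ab,...a->...b", m.data, contig(qd[s_idx]))

    def backward(g):
        dq = np.zeros_like(qd) if q.requires_grad else None
        for off, m in tables.items():
            s_idx, d_idx = slices[off]
            g_src = contig(g[s_idx])
            g_dst = contig(g[d_idx])
            if m.requires_grad:
                dm = np.einsum("...a,...b->...ab", g_src, contig(qd[d_idx]))
                dm += np.einsum("...a,...b->...ab", contig(qd[s_idx]), g_dst)
                m._accumulate(dm)
            if dq is not None:
                dq[d_idx] += np.einsum("...ab,...a->...b", m.data, g_src)
                dq[s_idx] += np.einsum("...ab,...b->...a", m.data, g_dst)
        if dq is not None:
            q._accumulate(dq)

    parents = tuple(tables.values()) + (q,)
    return ad._make(psi, parents, backward)


def meanfield_tensor(unary: Tensor, tables: dict, iterations: int):
    """Unrolled mean-field on tensors; returns (log Q, Q), both (B,H,W,K)."""
    _, height, width, _ = unary.shape
    neg_unary = unary * (-1.0)
    if iterations == 0 or not tables:
        logq = ad.log_softmax(neg_unary, axis=-1)
        return logq, ad.exp(logq)
    q = ad.softmax(neg_unary, axis=-1)
    logq = None
    for it in range(iterations):
        psi = unary + messages_tensor(q, tables, height, width)
        neg = psi * (-1.0)
        if it == iterations - 1:
            logq = ad.log_softmax(neg, axis=-1)
            q = ad.exp(logq)
        else:
            q = ad.softmax(neg, axis=-1)
    return logq, q


def ncrf_forward(image, model, n_iterations: int | None = None):
    """Full phase I-III forward pass of a segmentation model.

    Convenience functional wrapper: extracts deep features, computes the
    potentials and runs mean-field, returning the per-pixel label
    distribution as a NumPy array (H, W, K) for a single 2D image.
    See :class:`ncrfseg.model.SegmentationModel` for the trainable object.
    """
    image = np.asarray(image, dtype=model.dtype)
    if image.ndim == 2:
        image = image[None, :, :, None]
    elif image.ndim == 3:
        image = image[None]
    _, q = model.forward(Tensor(image), n_iterations=n_iterations)
    return q.data[0]
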