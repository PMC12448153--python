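"""CRF graph structure, Gibbs energy, and an exact-enumeration oracle.

The label field over an image grid forms a conditional random field on an
8-connected pixel graph: each pixel is linked to the neighbours within
Chebyshev distance 1 (truncated at image borders, no wraparound).  The
Gibbs energy of a labelling is the sum of per-pixel unary costs and
per-edge pairwise costs, each undirected edge counted once.

``exact_marginals`` enumerates every labelling and is the brute-force
oracle against which approximate mean-field inference is validated; it is
never part of the segmentation pipeline itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: Canonical undirected edge directions (source pixel is lexicographically
#: smaller than the destination): east, south, south-east, south-west.
OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def edge_slices(height: int, width: int, offset: tuple[int, int]):
    """Source and destination 2D slices selecting all edges of a direction."""
    di, dj = offset
    if dj >= 0:
        src = (slice(0, height - di), slice(0, width - dj))
        dst = (slice(di, height), slice(dj, width))
    else:
        src = (slice(0, height - di), slice(-dj, width))
        dst = (slice(di, height), slice(0, width + dj))
    return src, dst


@dataclass(frozen=True)
class NeighborGraph:
    """8-connectivity pixel graph with a symmetric directed-edge set."""

    height: int
    width: int
    edges: frozenset = field(default_factory=frozenset)

    @property
    def n_undirected_edges(self) -> int:
        return len(self.edges) // 2

    def neighbors(self, pixel: tuple[int, int]):
        return [q for (p, q) in self.edges if p == pixel]

    def is_full_grid(self) -> bool:
        h, w = self.height, self.width
        expected = 2 * (h * (w - 1) + w * (h - 1) + 2 * (h - 1) * (w - 1))
        return len(self.edges) == expected

    def undirected_edges(self):
        """Each undirected edge once, source lexicographically smaller."""
        return [(p, q) for (p, q) in self.edges if p < q]


def build_neighbor_graph(height: int, width: int) -> NeighborGraph:
    """Build the 8-connected graph; out-of-bounds neighbours are omitted."""
    if height < 1 or width < 1:
        raise ValueError("grid dimensions must be positive")
    edges = set()
    for i in range(height):
        for j in range(width):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < height and 0 <= jj < width:
                        edges.add(((i, j), (ii, jj)))
    return NeighborGraph(height, width, frozenset(edges))


def edgeless_graph(height: int, width: int) -> NeighborGraph:
    """Pixel grid with no pairwise connections (factorised model)."""
    if height < 1 or width < 1:
        raise ValueError("grid dimensions must be positive")
    return NeighborGraph(height, width, frozenset())


class EdgePotentials:
    """Pairwise K x K cost matrices for every undirected grid edge.

    For each canonical direction ``(di, dj)`` in :data:`OFFSETS` a table of
    shape ``(height - di, width - |dj|, K, K)`` stores the matrix ``M`` of
    the edge whose source pixel is the lexicographically smaller endpoint.
    ``M[a, b]`` is the cost of the source taking label ``a`` while the
    destination takes label ``b``.  Because the difference function used to
    build ``M`` is symmetric, both directions of an edge share one matrix;
    a message travelling against the canonical direction indexes ``M``
    transposed.
    """

    def __init__(self, height: int, width: int, n_labels: int,
                 tables: dict[tuple[int, int], np.ndarray]):
        self.height = height
        self.width = width
        self.n_labels = n_labels
        for off in OFFSETS:
            di, dj = off
            want = (height - di, width - abs(dj), n_labels, n_labels)
            got = np.asarray(tables[off]).shape
            if min(want[:2]) > 0 and got != want:
                raise ValueError(f"table for offset {off} has shape {got}, expected {want}")
        self.tables = {off: np.asarray(tables[off], dtype=float) for off in OFFSETS}

    # -- constructors --------------------------------------------------
    @classmethod
    def constant(cls, height: int, width: int, n_labels: int,
                 matrix) -> "EdgePotentials":
        """Same K x K matrix on every edge (scalar -> constant matrix)."""
        m = np.asarray(matrix, dtype=float)
        if m.ndim == 0:
            m = np.full((n_labels, n_labels), float(m))
        tables = {}
        for di, dj in OFFSETS:
            h, w = max(height - di, 0), max(width - abs(dj), 0)
            tables[(di, dj)] = np.broadcast_to(m, (h, w, n_labels, n_labels)).copy()
        return cls(height, width, n_labels, tables)

    @classmethod
    def random(cls, height: int, width: int, n_labels: int,
               rng: np.random.Generator, low: float = 0.9,
               high: float = 1.1) -> "EdgePotentials":
        """Independent symmetric-convention matrices with entries in [low, high)."""
        tables = {}
        for di, dj in OFFSETS:
            h, w = max(height - di, 0), max(width - abs(dj), 0)
            tables[(di, dj)] = rng.uniform(low, high, size=(h, w, n_labels, n_labels))
        return cls(height, width, n_labels, tables)

    # -- access --------------------------------------------------------
    def _locate(self, p: tuple[int, int], q: tuple[int, int]):
        """(offset, table index, transposed?) for the directed edge p->q."""
        di, dj = q[0] - p[0], q[1] - p[1]
        if (di, dj) in OFFSETS:
            i, j = p
            return (di, dj), (i, j if dj >= 0 else j + dj), False
        rev = (-di, -dj)
        if rev not in OFFSETS:
            raise KeyError(f"{p}->{q} is not a grid edge")
        i, j = q
        return rev, (i, j if rev[1] >= 0 else j + rev[1]), True

    def matrix(self, p: tuple[int, int], q: tuple[int, int]) -> np.ndarray:
        """K x K matrix indexed by (label of p, label of q)."""
        off, idx, transposed = self._locate(p, q)
        m = self.tables[off][idx]
        return m.T if transposed else m

    def map_tables(self, fn) -> "EdgePotentials":
        return EdgePotentials(self.height, self.width, self.n_labels,
                              {off: fn(t) for off, t in self.tables.items()})


def gibbs_energy(labels: np.ndarray, unary: np.ndarray,
                 binary: EdgePotentials | None, graph: NeighborGraph) -> float:
    """Energy of a labelling: unary costs plus one pairwise cost per edge.

    ``labels``: (H, W) integers; ``unary``: (H, W, K) costs.  The pairwise
    term reads ``M[a, b]`` with ``a`` the label of the lexicographically
    smaller endpoint, matching the storage convention of
    :class:`EdgePotentials`.
    """
    labels = np.asarray(labels)
    unary = np.asarray(unary, dtype=float)
    if labels.shape != (graph.height, graph.width):
        raise ValueError("label shape does not match graph")
    if unary.shape[:2] != (graph.height, graph.width):
        raise ValueError("unary shape does not match graph")
    energy = float(np.take_along_axis(unary, labels[..., None], axis=2).sum())
    if binary is None or not graph.edges:
        return energy
    if graph.is_full_grid():
        for off in OFFSETS:
            src, dst = edge_slices(graph.height, graph.width, off)
            table = binary.tables[off]
            if table.size == 0:
                continue
            la, lb = labels[src], labels[dst]
            hh, ww = la.shape
            ii, jj = np.meshgrid(np.arange(hh), np.arange(ww), indexing="ij")
            energy += float(table[ii, jj, la, lb].sum())
    else:
        for p, q in graph.undirected_edges():
            energy += float(binary.matrix(p, q)[labels[p], labels[q]])
    return energy


def exact_marginals(unary: np.ndarray, binary: EdgePotentials | None,
                    graph: NeighborGraph, max_bits: float = 20.0) -> np.ndarray:
    """Per-pixel marginals of the exact Gibbs distribution, by enumeration.

    Enumerates all K^(H*W) labellings, weights each by exp(-energy), and
    normalises by the partition function.  Refuses instances whose state
    space exceeds ``max_bits`` bits.
    """
    unary = np.asarray(unary, dtype=float)
    h, w, k = unary.shape
    if (h, w) != (graph.height, graph.width):
        raise ValueError("unary shape does not match graph")
    n = h * w
    if n * np.log2(k) > max_bits:
        raise ValueError(
            f"state space K^(H*W) = {k}^{n} exceeds the {max_bits}-bit "
            "enumeration guard")
    energies = np.empty(k ** n)
    labelings = itertools.product(range(k), repeat=n)
    for idx, flat in enumerate(labelings):
        lab = np.asarray(flat).reshape(h, w)
        energies[idx] = gibbs_energy(lab, unary, binary, graph)
    weights = np.exp(-(energies - energies.min()))
    probs = weights / weights.sum()
    marginals = np.zeros((h, w, k))
    for idx, flat in enumerate(itertools.product(range(k), repeat=n)):
        p = probs[idx]
        for pix, lab in enumerate(flat):
            marginals[pix // w, pix % w, lab] += p
    return marginals
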