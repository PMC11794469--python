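"""Acyclic tournament digraphs encoding each gene's pairwise value order.

For gene ``i`` with row ``a_i``, the direction-1 digraph has an arc
``(p, q)`` iff ``a_{i,p} < a_{i,q}``; the direction-2 digraph is its arc
reversal (``a_{i,p} > a_{i,q}``).  Tied values produce no arc in either.
A row without ties yields a transitive tournament with ``m(m-1)/2`` arcs.

Arcs are stored as flat boolean vectors of length ``m*m`` (entry ``p*m+q``
set iff arc ``p -> q`` present) so that arc-set intersections across many
digraphs reduce to integer matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DimensionError, ExpressionMatrix

__all__ = [
    "TournamentDigraph",
    "DigraphCollection",
    "build_digraphs",
    "shared_arcs",
    "pairwise_shared",
]


@dataclass(frozen=True)
class TournamentDigraph:
    """One gene's pairwise-order digraph in one direction (1 or 2)."""

    gene_index: int
    direction: int
    adjacency: np.ndarray  # (m, m) bool, [p, q] == arc p -> q

    @property
    def m(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_arcs(self) -> int:
        return int(self.adjacency.sum())

    def arcs(self) -> set:
        """Arc set as ordered index pairs (convenience for tests/debug)."""
        return {(int(p), int(q)) for p, q in zip(*np.nonzero(self.adjacency))}


class DigraphCollection:
    """The 2n tournament digraphs of a matrix, packed for bulk counting.

    Digraph ``(gene, direction)`` lives at flat key ``2*gene + direction-1``.
    ``flat[k]`` is that digraph's m*m boolean arc vector.
    """

    def __init__(self, flat: np.ndarray, m: int):
        self.flat = flat
        self.m = m
        self.n = flat.shape[0] // 2
        self._flat_f32 = None
        self._flat_packed = None

    @property
    def flat_f32(self) -> np.ndarray:
        """float32 view of the arc matrix, cached for bulk products."""
        if self._flat_f32 is None:
            self._flat_f32 = self.flat.astype(np.float32)
        return self._flat_f32

    @property
    def flat_packed(self) -> np.ndarray:
        """Bit-packed arc matrix for popcount-based intersection counts."""
        if self._flat_packed is None:
            self._flat_packed = np.packbits(self.flat, axis=1)
        return self._flat_packed

    @staticmethod
    def key(gene_index: int, direction: int) -> int:
        return 2 * gene_index + (direction - 1)

    @staticmethod
    def gene_of(key: int) -> int:
        return key // 2

    @staticmethod
    def direction_of(key: int) -> int:
        return key % 2 + 1

    def digraph(self, gene_index: int, direction: int) -> TournamentDigraph:
        adj = self.flat[self.key(gene_index, direction)].reshape(self.m, self.m)
        return TournamentDigraph(gene_index, direction, adj)

    def __len__(self) -> int:
        return self.flat.shape[0]


def build_digraphs(matrix: ExpressionMatrix) -> DigraphCollection:
    """Construct the 2n acyclic tournament digraphs of a matrix.

    Ties are exact floating-point equality and contribute no arc, so
    the construction is invariant under strictly increasing per-row
    transforms (rank-invariance).
    """
    v = matrix.values
    n, m = v.shape
    # less[i, p, q] == a_{i,p} < a_{i,q}  (direction 1); direction 2 is the
    # transpose, i.e. the arc reversal.
    less = v[:, :, None] < v[:, None, :]
    flat = np.empty((2 * n, m * m), dtype=bool)
    flat[0::2] = less.reshape(n, m * m)
    flat[1::2] = less.transpose(0, 2, 1).reshape(n, m * m)
    return DigraphCollection(flat, m)


def shared_arcs(d1: TournamentDigraph, d2: TournamentDigraph) -> int:
    """Number of arcs two digraphs have in common (symmetric)."""
    if d1.m != d2.m:
        raise DimensionError("digraphs are defined on different vertex sets")
    return int(np.count_nonzero(d1.adjacency & d2.adjacency))


def pairwise_shared(collection: DigraphCollection) -> np.ndarray:
    """(2n, 2n) matrix of shared-arc counts between all digraph pairs."""
    x = collection.flat.astype(np.float32)
    return np.rint(x @ x.T).astype(np.int32)
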