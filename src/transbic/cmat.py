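"""Ordered multipartite structure extraction from the high-frequency digraph.

A complete multipartite acyclic tournament (CMAT) on ordered partite sets
``P1..Pl`` has no arcs inside a set and exactly one arc between any two
vertices of different sets, oriented from the later set to the earlier
one.  ``P1`` is the pure sink set (in-arcs only).  The extraction below
rebuilds the partite sets greedily from a noisy digraph ``D = (V, H)``:
seed each set with the unassigned vertex of highest in-degree (subject to
an out-neighborhood dominance condition for sets after the first) and
fill it with vertices whose neighborhoods correlate with the seed's.

The correlation between ``c`` and the seed ``c_k`` is the Dice
similarity of their neighborhoods,

    gamma(c, c_k) = 2 (|N+(c) ∩ N+(c_k)| + |N-(c) ∩ N-(c_k)|)
                    / (|N(c)| + |N(c_k)|),

with ``N(c) = N+(c) ∪ N-(c)`` — 1 exactly for structurally
identical vertices.  A vertex may join the seed's partite set only when
additionally *no arc* runs between it and the seed: partite sets carry
no internal arcs, and on a complete multipartite structure every pair of
vertices from different sets is joined by an arc, so this constraint
alone makes the extraction the identity on exact inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TransBicParams

__all__ = [
    "CMAT",
    "DegenerateDigraphError",
    "correlation_gamma",
    "extract_cmat",
    "is_valid_cmat",
]


class DegenerateDigraphError(ValueError):
    """The digraph carries no usable structure (no arcs / empty vertex)."""


@dataclass(frozen=True)
class CMAT:
    """Ordered partite sets; implied arcs run from later sets to earlier."""

    partite_sets: tuple

    def __post_init__(self):
        sets = tuple(tuple(sorted(p)) for p in self.partite_sets)
        object.__setattr__(self, "partite_sets", sets)
        flat = [v for p in sets for v in p]
        if len(flat) != len(set(flat)):
            raise ValueError("partite sets must be disjoint")
        if any(len(p) == 0 for p in sets):
            raise ValueError("empty partite set")

    @property
    def l(self) -> int:
        return len(self.partite_sets)

    @property
    def vertices(self) -> tuple:
        return tuple(v for p in self.partite_sets for v in p)

    @property
    def implied_arc_count(self) -> int:
        sizes = [len(p) for p in self.partite_sets]
        total = sum(sizes)
        return (total * total - sum(s * s for s in sizes)) // 2

    def implied_mask(self, m: int) -> np.ndarray:
        """(m, m) mask of all implied arcs (later set -> earlier set)."""
        mask = np.zeros((m, m), dtype=bool)
        for j, earlier in enumerate(self.partite_sets):
            for later in self.partite_sets[j + 1 :]:
                for u in later:
                    for v in earlier:
                        mask[u, v] = True
        return mask


def correlation_gamma(adjacency: np.ndarray, c: int, c_k: int) -> float:
    """Neighborhood correlation between vertex ``c`` and seed ``c_k``."""
    if c == c_k:
        raise ValueError("gamma is defined between distinct vertices")
    out_c, in_c = adjacency[c], adjacency[:, c]
    out_k, in_k = adjacency[c_k], adjacency[:, c_k]
    if not (out_k.any() or in_k.any()):
        raise DegenerateDigraphError(
            f"vertex {c_k} has no incident high-frequency arcs"
        )
    num = int((out_c & out_k).sum()) + int((in_c & in_k).sum())
    den = int((out_c | in_c).sum()) + int((out_k | in_k).sum())
    return 2.0 * num / den


def extract_cmat(adjacency: np.ndarray, params: TransBicParams) -> CMAT:
    """Partite-set extraction from a (noisy) high-frequency digraph.

    Runs the greedy pass of :func:`_extract_once`, then restricts the
    digraph to the vertices it assigned and re-extracts, repeating until
    the vertex set is stable (at most a few passes).  Arcs incident to
    discarded vertices would otherwise distort the correlation of
    genuine bucket mates; on an exact complete multipartite input the
    procedure is the identity.
    """
    m = adjacency.shape[0]
    active = np.ones(m, dtype=bool)
    for _ in range(3):
        restricted = adjacency & active[:, None] & active[None, :]
        cmat = _extract_once(restricted, params)
        new_active = np.zeros(m, dtype=bool)
        new_active[list(cmat.vertices)] = True
        if np.array_equal(new_active, active):
            break
        active = new_active
    return _reinsert_dropped(adjacency, cmat, params)


def _reinsert_dropped(
    adjacency: np.ndarray, cmat: CMAT, params: TransBicParams
) -> CMAT:
    """Error-tolerant completion: re-admit vertices the greedy pass lost.

    A vertex that misses a few arcs can fall below the ratio thresholds
    outright (one absent arc on a degree-3 vertex already does).  Each
    unassigned vertex is tried at every position — inside an existing
    set or as a new singleton set anywhere in the order — and inserted
    where it implies the fewest absent arcs, provided that count is
    within ``ceil(e0 * its implied arcs)``.  A no-op on exact inputs.
    """
    m = adjacency.shape[0]
    sets = [list(p) for p in cmat.partite_sets]
    assigned = set(cmat.vertices)
    e0 = params.error_rate
    for c in range(m):
        if c in assigned or not (adjacency[c].any() or adjacency[:, c].any()):
            continue
        # cheap screen: missing >= implied - (arcs in either direction),
        # so a vertex sparsely connected to the structure can never fit
        ass = list(assigned)
        adj_count = int((adjacency[c, ass] | adjacency[ass, c]).sum())
        max_size = max(len(b) for b in sets)
        min_implied = len(ass) - max_size
        if min_implied - adj_count > int(np.ceil(e0 * len(ass))):
            continue
        l = len(sets)
        sizes = np.array([len(b) for b in sets])
        # per set: arcs c -> members present, and members -> c present
        out_to = np.array([int(adjacency[c, b].sum()) for b in sets])
        in_from = np.array([int(adjacency[b, c].sum()) for b in sets])
        total = int(sizes.sum())
        # new singleton before position p: sets earlier than p need c->v,
        # sets at p or later need v->c
        miss_out = np.concatenate([[0], np.cumsum(sizes - out_to)])
        miss_in = np.concatenate([[0], np.cumsum(sizes - in_from)])
        singleton_missing = miss_out[:-1] + (miss_in[-1] - miss_in[:-1])
        singleton_missing = np.append(singleton_missing, miss_out[-1])
        # membership in set p: same, minus set p's own contribution
        member_missing = (
            singleton_missing[:-1] - (sizes - in_from)
        )
        best = None  # (missing, kind, position, implied)
        for pos in range(l + 1):
            cand = (int(singleton_missing[pos]), 1, pos, total)
            if best is None or cand[:3] < best[:3]:
                best = cand
            if pos < l and total > sizes[pos]:
                cand = (int(member_missing[pos]), 0, pos, total - int(sizes[pos]))
                if cand[:3] < best[:3]:
                    best = cand
        missing, kind, pos, implied = best
        limit = int(np.ceil(e0 * implied))
        if missing <= limit and missing < implied:
            if kind == 0:
                sets[pos].append(c)
            else:
                sets.insert(pos, [c])
            assigned.add(c)
    sets = [tuple(sorted(b)) for b in sets]
    return CMAT(partite_sets=tuple(sets))


def _extract_once(adjacency: np.ndarray, params: TransBicParams) -> CMAT:
    """One greedy pass of ordered partite-set extraction.

    The first set is seeded by the global maximum in-degree vertex; each
    later set by the maximum in-degree vertex among unassigned candidates
    whose out-neighborhood covers at least ``sigma_threshold`` of all
    previously assigned vertices.  Each set is filled with unassigned
    vertices whose gamma against the seed exceeds ``gamma_threshold``
    and that share no arc with the seed.  Vertices never assigned are
    left out of the structure.
    """
    m = adjacency.shape[0]
    if not adjacency.any():
        raise DegenerateDigraphError("digraph has no arcs")
    indeg = adjacency.sum(axis=0)
    neighborhood = adjacency | adjacency.T
    unassigned = np.ones(m, dtype=bool)
    assigned_union = np.zeros(m, dtype=bool)
    sets = []
    while True:
        if not sets:
            cand = np.where(unassigned)[0]
        else:
            n_assigned = int(assigned_union.sum())
            need = params.sigma_threshold * n_assigned
            cover = (adjacency[:, assigned_union]).sum(axis=1)
            cand = np.where(unassigned & (cover >= need))[0]
        if cand.size == 0:
            break
        c_k = int(cand[np.argmax(indeg[cand])])  # argmax -> lowest index tie
        if not neighborhood[c_k].any():
            break  # an isolated seed carries no structure to extend
        unassigned[c_k] = False
        # vectorized gamma of every vertex against c_k
        num = (adjacency & adjacency[c_k][None, :]).sum(axis=1) + (
            adjacency.T & adjacency[:, c_k][None, :]
        ).sum(axis=1)
        gamma = 2.0 * num / np.maximum(
            neighborhood.sum(axis=1) + neighborhood[c_k].sum(), 1
        )
        # an arc to or from the seed rules out co-membership: partite
        # sets have no internal arcs
        joiners = (
            unassigned
            & (gamma > params.gamma_threshold)
            & ~adjacency[c_k]
            & ~adjacency[:, c_k]
        )
        bucket = [c_k] + [int(c) for c in np.where(joiners)[0]]
        unassigned[joiners] = False
        assigned_union[np.array(bucket)] = True
        sets.append(tuple(sorted(bucket)))
    if not sets:
        raise DegenerateDigraphError("no partite set could be seeded")
    return CMAT(partite_sets=tuple(sets))


def is_valid_cmat(adjacency: np.ndarray, cmat: CMAT, e0: float):
    """Error-tolerant containment test of a CMAT in a digraph.

    Returns ``(flag, missing_fraction)`` where ``missing_fraction`` is the
    share of implied arcs absent from the digraph (an arc present in the
    reversed orientation counts as missing) and ``flag`` is True when the
    fraction is at most ``e0``.
    """
    total = cmat.implied_arc_count
    if total == 0:
        raise DegenerateDigraphError("CMAT implies no arcs")
    mask = cmat.implied_mask(adjacency.shape[0])
    present = int((adjacency & mask).sum())
    missing_fraction = (total - present) / total
    return missing_fraction <= e0, missing_fraction
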