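"""Bicluster assembly and the enumeration loop over seed pairs.

For an extracted common subdigraph, every gene whose tournament digraph
contains the implied arcs (up to a tolerated fraction ``e0`` of missing
arcs) is a member: containment of the direction-1 digraph means the gene
decreases along the stored bucket order, direction-2 containment means it
increases.

Significance uses a surrogate null (the original formula is not public).
A random total order of the subdigraph's columns violates at most
``floor(e0 * T)`` of its ``T`` implied cross-bucket arcs with probability
``q0``; counting orders by cross-bucket inversions, ``q0`` is a truncated
Gaussian-multinomial mass, reducing to the linear-extension probability
``p0 = (prod |P_d|!) / (sum |P_d|)!`` at zero tolerance.  The raw
p-value is the upper binomial tail ``P[X >= support]`` with
``X ~ Binomial(#digraphs, q0)``.  Because the structure itself is chosen
by searching the data, the pipeline additionally applies a Bonferroni
factor counting every placement of the same bucket-size shape over the
matrix columns — an expected-count bound on noise structures of equal
shape and support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial

import numpy as np
from scipy.special import betainc, gammaln

from .core import DOWN, UP, BTPBicluster, ExpressionMatrix, TransBicParams
from .cmat import CMAT, DegenerateDigraphError, extract_cmat
from .digraphs import DigraphCollection, build_digraphs, pairwise_shared
from .seeding import SeedSet, grow_seed_set

__all__ = [
    "EnumerationState",
    "collect_members",
    "cmat_pvalue",
    "run_transbic",
]

#: Cell-set Jaccard above which two reported biclusters are merged.
#: Rediscoveries of one module from different seeds differ in a few
#: columns or member genes, so the cut sits well below 1; genuinely
#: distinct modules share almost no cells.
_DUPLICATE_JACCARD = 0.5


@dataclass
class EnumerationState:
    """Bookkeeping of the seed-pair enumeration loop."""

    used_pairs: set = field(default_factory=set)
    covered_digraphs: set = field(default_factory=set)
    accepted: list = field(default_factory=list)


def collect_members(
    collection: DigraphCollection, cmat: CMAT, e0: float
):
    """Member genes of a CMAT with per-gene directions and support count.

    A gene joins with direction ``down`` when its direction-1 digraph
    contains the implied arcs within tolerance ``e0``, ``up`` for
    direction 2; if both qualify the smaller missing fraction wins
    (ties favour ``down``).
    """
    total = cmat.implied_arc_count
    if total == 0:
        return {}, 0
    mask = cmat.implied_mask(collection.m).reshape(-1).astype(np.float32)
    counts = collection.flat_f32 @ mask
    miss = (total - counts) / total
    m1, m2 = miss[0::2], miss[1::2]
    ok1, ok2 = m1 <= e0, m2 <= e0
    down = ok1 & (~ok2 | (m1 <= m2))
    up = ok2 & ~down
    directions = {int(g): DOWN for g in np.nonzero(down)[0]}
    directions.update((int(g), UP) for g in np.nonzero(up)[0])
    return directions, len(directions)


@lru_cache(maxsize=None)
def _gauss_binom(n: int, k: int, tol: int) -> tuple:
    """Coefficients (degree 0..tol) of the Gaussian binomial [n, k]_q."""
    if k < 0 or k > n:
        return (0,) * (tol + 1)
    if k == 0 or k == n:
        return (1,) + (0,) * tol
    left = _gauss_binom(n - 1, k - 1, tol)
    right = _gauss_binom(n - 1, k, tol)
    return tuple(
        left[d] + (right[d - k] if d >= k else 0) for d in range(tol + 1)
    )


@lru_cache(maxsize=None)
def _containment_prob(sizes: tuple, tol: int) -> float:
    """P that a uniform order of the columns violates <= tol implied arcs.

    The cross-bucket inversion count of a uniform arrangement of bucket
    labels has the Gaussian-multinomial generating function
    ``prod_d [A_d + s_d, s_d]_q`` (``A_d`` = columns already placed), so
    the mass at ``<= tol`` inversions is the truncated coefficient sum
    over the plain multinomial.  ``tol = 0`` gives the linear-extension
    probability ``(prod s_d!) / N!``.
    """
    poly = [1] + [0] * tol
    placed = 0
    for s in sizes:
        qb = _gauss_binom(placed + s, s, tol)
        new = [0] * (tol + 1)
        for d1, c1 in enumerate(poly):
            if c1 == 0:
                continue
            for d2 in range(tol + 1 - d1):
                new[d1 + d2] += c1 * qb[d2]
        poly = new
        placed += s
    total = factorial(placed)
    for s in sizes:
        total //= factorial(s)
    return sum(poly) / total


def cmat_pvalue(
    cmat: CMAT,
    support: int,
    total_digraphs: int,
    n_conditions: int = None,
    e0: float = 0.0,
) -> float:
    """Surrogate significance of observing ``support`` member digraphs.

    With default arguments this is the plain upper binomial tail at the
    exact-containment probability ``p0``; passing ``e0`` makes the null
    tolerance-aware, and passing ``n_conditions`` multiplies in the
    Bonferroni count of placements of the same bucket-size shape over
    the matrix columns (capping the result at 1).  Monotone decreasing
    in support; ``support = 0`` gives 1.
    """
    if support > total_digraphs:
        raise ValueError("support cannot exceed the number of digraphs")
    sizes = tuple(len(p) for p in cmat.partite_sets)
    tol = int(e0 * cmat.implied_arc_count)
    q0 = _containment_prob(sizes, tol)
    # upper binomial tail via the regularized incomplete beta function
    if support <= 0:
        tail = 1.0
    else:
        tail = float(betainc(support, total_digraphs - support + 1, q0))
    log_tail = np.log(tail) if tail > 0 else -np.inf
    if n_conditions is not None:
        n_cols = sum(sizes)
        log_count = float(
            gammaln(n_conditions + 1)
            - gammaln(n_conditions - n_cols + 1)
            - sum(gammaln(s + 1) for s in sizes)
        )
        log_tail += log_count
    return float(np.exp(min(log_tail, 0.0)))


def _cells(members, cmat: CMAT) -> frozenset:
    cols = cmat.vertices
    return frozenset((g, c) for g in members for c in cols)


def _refine_structure(
    collection: DigraphCollection,
    cmat: CMAT,
    directions: dict,
    params: TransBicParams,
    max_rounds: int = 6,
):
    """Alternate structure and membership to a fixpoint.

    The seed-set consensus only locates a module approximately; the
    members collected by error-tolerant containment are a much cleaner
    gene set.  Re-reading the structure off the members' own consensus
    arcs (frequency at least ``1 - e0``) and re-collecting members
    converges within a few rounds and removes spurious buckets and
    columns introduced by the noisy high-frequency digraph.
    """
    e0 = params.error_rate
    best = (cmat, directions)
    seen = {tuple(sorted(directions.items()))}
    for _ in range(max_rounds):
        cmat_cur, dirs_cur = best
        if len(dirs_cur) < 2:
            break
        keys = np.array(
            [
                DigraphCollection.key(g, 1 if d == DOWN else 2)
                for g, d in sorted(dirs_cur.items())
            ]
        )
        cnt = collection.flat[keys].sum(axis=0)
        slack = np.sqrt(e0 * (1.0 - e0) / len(keys))
        consensus = (cnt >= (1.0 - e0 - slack) * len(keys)).reshape(
            collection.m, collection.m
        )
        if not consensus.any():
            break
        try:
            cm_new = extract_cmat(consensus, params)
        except DegenerateDigraphError:
            break
        if cm_new.l < 2 or len(cm_new.vertices) < 2:
            break
        dirs_new, support = collect_members(collection, cm_new, e0)
        if support < params.min_genes:
            break
        best = (cm_new, dirs_new)
        key = tuple(sorted(dirs_new.items()))
        if key in seen:
            break
        seen.add(key)
    return best


def run_transbic(
    matrix: ExpressionMatrix,
    params: TransBicParams = None,
    state: EnumerationState = None,
) -> list:
    """Full pipeline: enumerate all significant BTP-biclusters.

    Seed pairs are visited in decreasing shared-arc order; every visited
    pair is marked used, and a pair is skipped once either of its
    digraphs is already covered by an accepted subdigraph.  Accepted biclusters
    (p-value below ``p_threshold``, at least ``min_genes`` members, at
    least ``min_genes`` of them fresh) are deduplicated at cell-set
    Jaccard >= 0.5 and returned sorted by ascending p-value.
    """
    params = params or TransBicParams()
    state = state if state is not None else EnumerationState()
    collection = build_digraphs(matrix)
    nd = len(collection)
    shared = pairwise_shared(collection)

    ii, jj = np.triu_indices(nd, k=1)
    distinct = (ii // 2) != (jj // 2)
    ii, jj = ii[distinct], jj[distinct]
    # visit order: shared desc, then lexicographically smallest key pair
    order = np.lexsort((jj, ii, -shared[ii, jj]))
    ii, jj = ii[order], jj[order]

    covered = np.zeros(nd, dtype=bool)
    accepted = []  # (bicluster, cells)
    accepted_arcs = np.zeros((collection.m, collection.m), dtype=bool)

    for i, j in zip(ii, jj):
        i, j = int(i), int(j)
        # a pair is consumed only when both digraphs are still fresh:
        # re-seeding from an already-covered digraph re-grows the same
        # module as a cloud of near-duplicate variants
        if covered[i] or covered[j]:
            continue
        state.used_pairs.add((i, j))
        seed_set, H = grow_seed_set(
            collection, SeedSet(members=(i, j)), params, pair_overlap=shared
        )
        # the structure is read off the near-consensus of S — the arcs
        # shared by all members up to the same tolerance used for
        # containment — rather than the broader high-frequency cluster
        idx = np.array(seed_set.members)
        cnt = collection.flat[idx].sum(axis=0)
        consensus = (cnt >= (1.0 - params.error_rate) * len(idx)).reshape(
            collection.m, collection.m
        )
        if not consensus.any():
            continue
        try:
            cm = extract_cmat(consensus, params)
        except DegenerateDigraphError:
            continue
        if cm.l < 2 or len(cm.vertices) < 2:
            continue
        directions, support = collect_members(collection, cm, params.error_rate)
        if support < params.min_genes:
            continue

        def fresh_count(dirs):
            return sum(
                not covered[DigraphCollection.key(g, 1 if d == DOWN else 2)]
                for g, d in dirs.items()
            )

        # cheap significance screen before the refinement iterations:
        # structures that are not even marginally significant never are
        fresh = fresh_count(directions)
        if fresh < params.min_genes:
            continue
        p = cmat_pvalue(
            cm, fresh, nd, n_conditions=collection.m, e0=params.error_rate
        )
        if p >= params.p_threshold:
            continue
        cm, directions = _refine_structure(collection, cm, directions, params)
        support = len(directions)
        if cm.l < 2 or len(cm.vertices) < 2 or support < params.min_genes:
            continue
        # a coarsening or sub-order of an accepted module (in either
        # orientation) carries no new ordering information
        implied = cm.implied_mask(collection.m)
        if not (implied & ~accepted_arcs).any():
            continue
        # significance is assessed on the *fresh* support only: digraphs
        # already covered by an accepted module are not new evidence, so
        # fragments and rediscoveries of that module cannot re-qualify
        fresh = fresh_count(directions)
        if fresh < params.min_genes:
            continue
        p = cmat_pvalue(
            cm,
            fresh,
            nd,
            n_conditions=collection.m,
            e0=params.error_rate,
        )
        if p >= params.p_threshold:
            continue
        bicluster = BTPBicluster(
            gene_members=frozenset(directions),
            directions=directions,
            partition=cm.partite_sets,
            p_value=p,
            support=support,
        )
        for g, d in directions.items():
            key = DigraphCollection.key(g, 1 if d == DOWN else 2)
            covered[key] = True
            state.covered_digraphs.add(key)
        accepted_arcs |= implied | implied.T
        cells = _cells(directions, cm)
        merged = False
        for idx, (other, other_cells) in enumerate(accepted):
            inter = len(cells & other_cells)
            union = len(cells | other_cells)
            if union and inter / union >= _DUPLICATE_JACCARD:
                better = bicluster.p_value < other.p_value or (
                    bicluster.p_value == other.p_value
                    and len(cells) > len(other_cells)
                )
                if better:
                    accepted[idx] = (bicluster, cells)
                merged = True
                break
        if not merged:
            accepted.append((bicluster, cells))

    accepted.sort(key=lambda bc: bc[0].p_value)
    state.accepted = [b for b, _ in accepted]
    return state.accepted
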