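"""Seed-set growth: arc frequencies, H/L/M split, and KL admission.

The search for one common subdigraph starts from the digraph pair sharing
the most arcs.  The member set ``S`` then grows one digraph at a time:
arc frequencies over the complete digraph are split by 1-D k-means into
high- (``H``), medium- and low-frequency (``L``) portions, candidate
digraphs are ranked by their best arc overlap with any member of ``S``,
and the best-ranked candidate is admitted when its Kullback-Leibler score

    KL_d(H, L) = F_H log(F_H / F_L) + (1-F_H) log((1-F_H) / (1-F_L)),

with ``F_Z = |Z ∩ A(d)| / |Z|``, exceeds the ``kl_threshold`` and is
enriched in ``H``.  When admission exhausts, members inconsistent with
the rest of ``S`` are trimmed and growth resumes; the loop ends when
trimming finds nothing more to drop or ``H`` has stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import TransBicParams
from .digraphs import DigraphCollection, TournamentDigraph

__all__ = [
    "ArcFrequencyTable",
    "ArcPartition",
    "SeedSet",
    "arcs_to_mask",
    "arc_frequencies",
    "partition_arcs",
    "kl_score",
    "select_initial_pair",
    "grow_seed_set",
]

_EPS = 1e-6  # smoothing for zero-count KL terms


@dataclass(frozen=True)
class ArcFrequencyTable:
    """Per-arc occurrence fraction over the current seed set S."""

    freq: np.ndarray  # (m, m) float in [0, 1]; diagonal unused (0)
    s_size: int


@dataclass(frozen=True)
class ArcPartition:
    """Boolean masks splitting all m(m-1) ordered pairs into H / M / L."""

    H: np.ndarray
    M: np.ndarray
    L: np.ndarray

    def arcs(self, which: str) -> set:
        mask = getattr(self, which)
        return {(int(p), int(q)) for p, q in zip(*np.nonzero(mask))}


@dataclass(frozen=True)
class SeedSet:
    """Ordered digraph membership of S, as flat collection keys."""

    members: tuple

    def __post_init__(self):
        genes = [DigraphCollection.gene_of(k) for k in self.members]
        if len(set(genes)) != len(genes):
            raise ValueError("a gene may contribute only one orientation to S")

    def __len__(self) -> int:
        return len(self.members)

    def genes(self) -> set:
        return {DigraphCollection.gene_of(k) for k in self.members}


def arcs_to_mask(arcs, m: int) -> np.ndarray:
    """Convert an iterable of ordered index pairs to an (m, m) mask."""
    mask = np.zeros((m, m), dtype=bool)
    for p, q in arcs:
        mask[p, q] = True
    return mask


def arc_frequencies(
    seed: SeedSet, collection: DigraphCollection
) -> ArcFrequencyTable:
    """Fraction of digraphs in S containing each arc of the complete digraph."""
    if len(seed) < 2:
        raise ValueError("S must contain at least 2 digraphs")
    idx = np.fromiter(seed.members, dtype=np.int64)
    cnt = collection.flat[idx].sum(axis=0)
    freq = (cnt / len(seed)).reshape(collection.m, collection.m)
    return ArcFrequencyTable(freq=freq, s_size=len(seed))


def _weighted_median(uniq: np.ndarray, weights: np.ndarray) -> float:
    """Median of the multiset given distinct values and multiplicities."""
    cum = np.cumsum(weights)
    n = int(cum[-1])
    hi = int(np.searchsorted(cum, n // 2 + 1))
    if n % 2 == 1:
        return float(uniq[hi])
    lo = int(np.searchsorted(cum, n // 2))
    return float(uniq[lo] + uniq[hi]) / 2.0


def _kmeans3_distinct(uniq: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Deterministic 1-D 3-means on distinct values with multiplicities.

    In one dimension the optimal clusters are value intervals, so the
    exact optimum is found by enumerating the two cut points (ties break
    to the lowest cuts).  Beyond 64 distinct values a Lloyd pass seeded
    at min / median / max is used instead.  Returns a label 0 (low) /
    1 (mid) / 2 (high) per distinct value.
    """
    u = len(uniq)
    if u > 64:
        return _kmeans3_lloyd(uniq, weights)
    w = np.concatenate([[0.0], np.cumsum(weights)])
    x = np.concatenate([[0.0], np.cumsum(uniq * weights)])
    x2 = np.concatenate([[0.0], np.cumsum(uniq * uniq * weights)])

    def seg(a, b):  # within-cluster sum of squares of uniq[a:b]
        W = w[b] - w[a]
        X = x[b] - x[a]
        return (x2[b] - x2[a]) - X * X / W

    c1, c2 = np.meshgrid(np.arange(1, u - 1), np.arange(2, u), indexing="ij")
    valid = c2 > c1
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = np.where(
            valid, seg(0, c1) + seg(c1, c2) + seg(c2, u), np.inf
        )
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    cut1, cut2 = int(c1[i, j]), int(c2[i, j])
    labels = np.zeros(u, dtype=np.int64)
    labels[cut1:cut2] = 1
    labels[cut2:] = 2
    return labels


def _kmeans3_lloyd(uniq: np.ndarray, weights: np.ndarray) -> np.ndarray:
    cent = np.array([uniq[0], _weighted_median(uniq, weights), uniq[-1]])
    uw = uniq * weights
    labels = np.full(len(uniq), -1, dtype=np.int64)
    for _ in range(100):
        cuts = np.array([(cent[0] + cent[1]) / 2, (cent[1] + cent[2]) / 2])
        new_labels = np.searchsorted(cuts, uniq, side="left")
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(3):
            sel = labels == k
            if sel.any():  # empty clusters keep their centroid
                cent[k] = uw[sel].sum() / weights[sel].sum()
    return labels


def _kmeans3_boundaries(values: np.ndarray) -> np.ndarray:
    """Per-value 0/1/2 labels of the deterministic 1-D 3-means."""
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) == 3:  # zero-scatter optimum: one cluster per value
        labels = np.arange(3)
    else:
        labels = _kmeans3_distinct(uniq, counts.astype(float))
    return labels[np.searchsorted(uniq, values)]


def partition_arcs(table: ArcFrequencyTable) -> ArcPartition:
    """Split all ordered pairs into highest / medium / lowest frequency arcs.

    Uses 1-D k-means (k=3) with deterministic initialization.  With fewer
    than three distinct frequency values the split degenerates: arcs at
    the maximum go to H, arcs at the minimum (if distinct) to L, any
    remainder to M.
    """
    m = table.freq.shape[0]
    off = ~np.eye(m, dtype=bool)
    values = table.freq[off]
    distinct = np.unique(values)
    H = np.zeros((m, m), dtype=bool)
    L = np.zeros((m, m), dtype=bool)
    M = np.zeros((m, m), dtype=bool)
    if distinct.size == 1:
        H[off] = True
    elif distinct.size == 2:
        H[off & (table.freq == distinct[-1])] = True
        L[off & (table.freq == distinct[0])] = True
    else:
        labels = _kmeans3_boundaries(values)
        full = np.zeros((m, m), dtype=np.int64)
        full[off] = labels
        H[off] = False
        H[off & (full == 2)] = True
        M[off & (full == 1)] = True
        L[off & (full == 0)] = True
    return ArcPartition(H=H, M=M, L=L)


def _split_counts_flat(cnt: np.ndarray, s_size: int, off: np.ndarray):
    """H and L as flat masks from integer arc counts over S (fast path).

    Clusters the count histogram; label assignment is identical to
    :func:`partition_arcs` on the corresponding frequencies.
    """
    bc = np.bincount(cnt[off], minlength=s_size + 1)
    vals = np.nonzero(bc)[0]
    lut = np.zeros(s_size + 1, dtype=np.int64)
    if len(vals) == 1:
        lut[vals[0]] = 2
    elif len(vals) == 2:
        lut[vals[1]] = 2
    elif len(vals) == 3:
        # three distinct values: one cluster each (zero within-cluster
        # scatter is the unique 3-means optimum)
        lut[vals] = (0, 1, 2)
    else:
        lut[vals] = _kmeans3_distinct(vals / s_size, bc[vals].astype(float))
    lab = lut[cnt]
    H = off & (lab == 2)
    if len(vals) == 1:
        L = np.zeros_like(H)
    else:
        L = off & (lab == 0)
    return H, L


def kl_score(
    digraph: TournamentDigraph, H: np.ndarray, L: np.ndarray
) -> float:
    """Kullback-Leibler admission score of one digraph against H and L."""
    nH = int(H.sum())
    nL = int(L.sum())
    if nH == 0 or nL == 0:
        raise ValueError("KL score undefined for empty H or L")
    fh = np.count_nonzero(digraph.adjacency & H) / nH
    fl = np.count_nonzero(digraph.adjacency & L) / nL
    return _kl_from_fractions(fh, fl)


def _kl_from_fractions(fh: float, fl: float) -> float:
    def term(p, q):
        if p == 0.0:
            return 0.0  # 0 * log(0/x) := 0
        return p * np.log(max(p, _EPS) / min(max(q, _EPS), 1.0))

    return term(fh, fl) + term(1.0 - fh, 1.0 - fl)


def _popcount_overlap(packed: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """|A(d) ∩ arcs| for every packed digraph against one arc vector."""
    packed_vec = np.packbits(vec.reshape(-1))
    return np.bitwise_count(packed & packed_vec).sum(axis=1)


def _kl_scores_bulk(
    collection, H: np.ndarray, L: np.ndarray
) -> np.ndarray:
    """Vectorized KL scores for every digraph at once."""
    packed = collection.flat_packed
    fh = _popcount_overlap(packed, H).astype(float) / H.sum()
    fl = _popcount_overlap(packed, L).astype(float) / L.sum()
    clip = lambda p: np.clip(p, _EPS, 1.0)  # noqa: E731
    kl = fh * np.log(clip(fh) / clip(fl))
    kl[fh == 0.0] = 0.0
    fhb, flb = 1.0 - fh, 1.0 - fl
    t2 = fhb * np.log(clip(fhb) / clip(flb))
    t2[fhb == 0.0] = 0.0
    return kl + t2, fh, fl


def select_initial_pair(
    collection: DigraphCollection,
    exclusions: set = frozenset(),
    covered: set = frozenset(),
) -> Optional[SeedSet]:
    """Admissible digraph pair sharing the most arcs, or None.

    A pair is admissible when its genes differ, it is not in
    ``exclusions`` (unordered key pairs), and at least one of its
    digraphs is not in ``covered``.  Ties break to the lexicographically
    smallest key pair.
    """
    from .digraphs import pairwise_shared

    shared = pairwise_shared(collection)
    nd = len(collection)
    best = None
    best_count = -1
    cov = np.fromiter(
        (k in covered for k in range(nd)), dtype=bool, count=nd
    )
    for i in range(nd):
        gi = DigraphCollection.gene_of(i)
        for j in range(i + 1, nd):
            if DigraphCollection.gene_of(j) == gi:
                continue
            if cov[i] and cov[j]:
                continue
            if (i, j) in exclusions:
                continue
            if shared[i, j] > best_count:
                best_count = shared[i, j]
                best = (i, j)
    if best is None:
        return None
    return SeedSet(members=best)


def _trim_inconsistent(members, pair_overlap: np.ndarray):
    """Members of S whose consensus with the rest is an extreme outlier.

    Each member is scored by its mean arc overlap with the other members;
    a score far below the bulk (over 5 robust standard deviations under
    a median/MAD location-scale fit) marks a digraph that joined on a
    chance overlap with one member but disagrees with the consensus.
    Returns the indices (into ``members``) to drop.
    """
    if len(members) < 4:
        return []
    idx = np.asarray(members)
    sub = pair_overlap[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(sub, np.nan)
    score = np.nanmean(sub, axis=1)
    center = np.median(score)
    mad = np.median(np.abs(score - center))
    scale = 1.4826 * mad
    if scale <= 0:
        return []
    drop = np.where(score < center - 5.0 * scale)[0]
    if len(drop) >= len(members) - 1:
        return []
    return [int(d) for d in drop]


def grow_seed_set(
    collection: DigraphCollection,
    seed: SeedSet,
    params: TransBicParams,
    pair_overlap: Optional[np.ndarray] = None,
):
    """Grow and refine S from a two-digraph seed; returns ``(S, H)``.

    One admission per iteration: candidates (digraphs of genes outside S)
    are ranked by their maximum arc overlap with any member of S (ties:
    lower gene index, direction 1 first) and the best-ranked candidate
    with KL score above ``kl_threshold`` — and enriched in H rather than
    L — joins.  When admission stalls or H stabilizes, members whose
    overlap with the rest of S is an extreme outlier are dropped (their
    genes become ineligible) and admission resumes against the
    re-sharpened H; refinement rounds are capped.  The returned H is the
    high-frequency (top k-means cluster) arc set of the final S.
    """
    if len(seed) != 2:
        raise ValueError("seed must contain exactly 2 digraphs")
    m = collection.m
    packed = collection.flat_packed
    members = list(seed.members)
    cnt = collection.flat[np.array(members)].sum(axis=0).astype(np.int64)
    candidate = np.ones(len(collection), dtype=bool)
    for k in members:
        g = DigraphCollection.gene_of(k)
        candidate[2 * g : 2 * g + 2] = False
    # best arc overlap of every digraph with any current member of S
    overlap = np.maximum(
        np.bitwise_count(packed & packed[members[0]]).sum(axis=1),
        np.bitwise_count(packed & packed[members[1]]).sum(axis=1),
    )
    keys = np.arange(len(collection))

    off = (~np.eye(m, dtype=bool)).reshape(-1)
    prev_H = None
    same_run = 1  # length of the run of identical consecutive H sets
    H = None
    trim_rounds = 0
    while True:
        H, L = _split_counts_flat(cnt, len(members), off)
        stalled = False
        if prev_H is not None and np.array_equal(H, prev_H):
            same_run += 1
            # H stability ends growth only once refinement has started;
            # during initial absorption an unchanged H simply means the
            # admitted digraphs agree with the consensus
            if trim_rounds > 0 and same_run >= params.stabilization_iters:
                stalled = True
        else:
            same_run = 1
        prev_H = H

        admitted = None
        if not stalled and candidate.any() and L.any():
            # walking the overlap ranking down to the first KL pass equals:
            # among KL passers take max overlap, ties to the smallest key;
            # enrichment in H is required because the divergence score is
            # symmetric and would otherwise admit anti-correlated digraphs
            kls, fh, fl = _kl_scores_bulk(collection, H, L)
            passing = candidate & (kls > params.kl_threshold) & (fh > fl)
            if passing.any():
                idx = np.nonzero(passing)[0]
                admitted = int(idx[np.lexsort((keys[idx], -overlap[idx]))[0]])
        if admitted is not None:
            members.append(admitted)
            cnt += collection.flat[admitted]
            g = DigraphCollection.gene_of(admitted)
            candidate[2 * g : 2 * g + 2] = False
            overlap = np.maximum(
                overlap,
                np.bitwise_count(packed & packed[admitted]).sum(axis=1),
            )
            continue

        # admission exhausted (or H stable): refine S by dropping members
        # inconsistent with the consensus, then try growing again
        if trim_rounds >= 3:
            break
        trim_rounds += 1
        if pair_overlap is None:
            from .digraphs import pairwise_shared

            pair_overlap = pairwise_shared(collection)
        drop = _trim_inconsistent(members, pair_overlap)
        if not drop:
            break
        for d in sorted(drop, reverse=True):
            cnt -= collection.flat[members[d]]
            members.pop(d)
        if len(members) < 2:
            break
        overlap = pair_overlap[:, np.array(members)].max(axis=1)
        prev_H = None
        same_run = 1

    return SeedSet(members=tuple(members)), H.reshape(m, m)
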