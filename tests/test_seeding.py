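import itertools

import numpy as np
import pytest

from transbic.core import ExpressionMatrix, TransBicParams
from transbic.digraphs import TournamentDigraph, build_digraphs
from transbic.seeding import (
    ArcFrequencyTable,
    SeedSet,
    arc_frequencies,
    arcs_to_mask,
    grow_seed_set,
    kl_score,
    partition_arcs,
    select_initial_pair,
)


def matrix_of(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n, m = rows.shape
    return ExpressionMatrix(
        rows, tuple(f"g{i}" for i in range(n)), tuple(f"c{j}" for j in range(m))
    )


class TestArcFrequencies:
    def test_identical_pair(self):
        coll = build_digraphs(matrix_of([[1, 2, 3], [4, 5, 6]]))
        table = arc_frequencies(SeedSet((0, 2)), coll)
        assert table.s_size == 2
        assert table.freq[0, 1] == 1.0 and table.freq[1, 0] == 0.0

    def test_digraph_plus_reversal(self):
        coll = build_digraphs(matrix_of([[1, 2, 3], [3, 2, 1]]))
        table = arc_frequencies(SeedSet((0, 2)), coll)
        off = ~np.eye(3, dtype=bool)
        assert np.all(table.freq[off] == 0.5)

    def test_three_of_four(self):
        rows = [[1, 2, 3], [1, 2, 3], [1, 3, 2], [2, 1, 3]]
        coll = build_digraphs(matrix_of(rows))
        table = arc_frequencies(SeedSet((0, 2, 4, 6)), coll)
        assert table.freq[0, 1] == 0.75  # c0 < c1 in three of the four rows

    def test_conservation(self):
        rng = np.random.default_rng(5)
        coll = build_digraphs(matrix_of(rng.normal(size=(4, 6))))
        seed = SeedSet((0, 3, 4, 7))
        table = arc_frequencies(seed, coll)
        total_arcs = sum(
            coll.digraph(k // 2, k % 2 + 1).n_arcs for k in seed.members
        )
        assert table.freq.sum() * len(seed) == pytest.approx(total_arcs)


def wcss_three_split(values):
    """Brute-force optimal 1-D 3-clustering by within-cluster sum of squares."""
    values = sorted(values)
    n = len(values)
    best, best_parts = None, None
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            parts = [values[:i], values[i:j], values[j:]]
            cost = sum(
                sum((v - np.mean(p)) ** 2 for v in p) for p in parts if p
            )
            if best is None or cost < best - 1e-12:
                best, best_parts = cost, parts
    return best_parts


class TestPartitionArcs:
    def _table(self, assignments):
        """Build a 3-condition frequency table from six ordered-pair values."""
        freq = np.zeros((3, 3))
        pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        for (p, q), f in zip(pairs, assignments):
            freq[p, q] = f
        return ArcFrequencyTable(freq=freq, s_size=4)

    def test_perfectly_separated(self):
        part = partition_arcs(self._table([1.0, 0.0, 1.0, 0.0, 0.5, 0.5]))
        assert part.arcs("H") == {(0, 1), (0, 2)}
        assert part.arcs("L") == {(1, 0), (2, 0)}
        assert part.arcs("M") == {(1, 2), (2, 1)}

    def test_single_value_degenerate(self):
        part = partition_arcs(self._table([0.5] * 6))
        assert len(part.arcs("H")) == 6
        assert not part.arcs("M") and not part.arcs("L")

    def test_matches_wcss_oracle(self):
        values = [0.9, 0.85, 0.5, 0.45, 0.1, 0.05]
        part = partition_arcs(self._table(values))
        lo, mid, hi = wcss_three_split(values)
        freq = self._table(values).freq
        assert sorted(freq[p, q] for p, q in part.arcs("H")) == sorted(hi)
        assert sorted(freq[p, q] for p, q in part.arcs("M")) == sorted(mid)
        assert sorted(freq[p, q] for p, q in part.arcs("L")) == sorted(lo)

    def test_masks_partition_all_ordered_pairs(self):
        rng = np.random.default_rng(0)
        freq = np.round(rng.uniform(size=(5, 5)), 2)
        np.fill_diagonal(freq, 0.0)
        part = partition_arcs(ArcFrequencyTable(freq=freq, s_size=10))
        combined = part.H | part.M | part.L
        assert combined.sum() == 20
        assert not (part.H & part.M).any()
        assert not (part.H & part.L).any()
        assert not (part.M & part.L).any()


def digraph_from_arcs(arcs, m):
    return TournamentDigraph(
        gene_index=0, direction=1, adjacency=arcs_to_mask(arcs, m)
    )


class TestKlScore:
    # all masks live on m=4 (12 ordered pairs)
    H = arcs_to_mask([(0, 1), (0, 2), (0, 3), (1, 2)], 4)
    L = arcs_to_mask([(1, 0), (2, 0), (3, 0), (2, 1)], 4)

    def test_full_h_no_l(self):
        d = digraph_from_arcs([(0, 1), (0, 2), (0, 3), (1, 2)], 4)
        assert kl_score(d, self.H, self.L) == pytest.approx(
            np.log(1e6), rel=1e-6
        )

    def test_balanced_intersections_score_zero(self):
        d = digraph_from_arcs([(0, 1), (0, 2), (1, 0), (2, 0)], 4)
        assert kl_score(d, self.H, self.L) == pytest.approx(0.0, abs=1e-12)

    def test_three_quarters_enrichment(self):
        d = digraph_from_arcs([(0, 1), (0, 2), (0, 3), (2, 1)], 4)
        expected = 0.75 * np.log(3.0) + 0.25 * np.log(1.0 / 3.0)
        assert kl_score(d, self.H, self.L) == pytest.approx(expected, rel=1e-9)

    def test_empty_h_rejected(self):
        d = digraph_from_arcs([(0, 1)], 4)
        with pytest.raises(ValueError):
            kl_score(d, np.zeros((4, 4), bool), self.L)


class TestSelectInitialPair:
    def test_identical_rows_give_top_pair(self):
        coll = build_digraphs(matrix_of([[1, 2, 3, 4], [1, 2, 3, 4]]))
        seed = select_initial_pair(coll)
        assert seed is not None and len(seed) == 2
        assert set(seed.genes()) == {0, 1}

    def test_exhaustion_returns_none(self):
        coll = build_digraphs(matrix_of([[1, 2, 3], [1, 2, 3]]))
        all_pairs = {
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if i // 2 != j // 2
        }
        assert select_initial_pair(coll, exclusions=all_pairs) is None

    def test_tie_break_matches_brute_force(self):
        rows = [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]]
        coll = build_digraphs(matrix_of(rows))
        from transbic.digraphs import shared_arcs

        def brute(exclusions):
            best = None
            for i, j in itertools.combinations(range(6), 2):
                if i // 2 == j // 2 or (i, j) in exclusions:
                    continue
                s = shared_arcs(
                    coll.digraph(i // 2, i % 2 + 1), coll.digraph(j // 2, j % 2 + 1)
                )
                if best is None or s > best[0]:
                    best = (s, (i, j))
            return best[1]

        assert select_initial_pair(coll).members == brute(set())
        excl = {select_initial_pair(coll).members}
        assert select_initial_pair(coll, exclusions=excl).members == brute(excl)


class TestGrowSeedSet:
    def test_identical_rows_absorb_all_genes(self):
        rows = np.tile(np.arange(6, dtype=float), (10, 1))
        coll = build_digraphs(matrix_of(rows))
        seed = SeedSet((0, 2))
        final, H = grow_seed_set(coll, seed, TransBicParams())
        assert len(final) == 10
        assert all(k % 2 == 0 for k in final.members)  # all direction 1
        assert H.sum() == 15  # complete transitive tournament on 6 vertices

    def test_no_admission_when_threshold_unreachable(self):
        rng = np.random.default_rng(2)
        coll = build_digraphs(matrix_of(rng.normal(size=(6, 8))))
        params = TransBicParams(kl_threshold=1e9)
        final, H = grow_seed_set(coll, SeedSet((0, 2)), params)
        assert final.members == (0, 2)
        assert H is not None

    def test_seed_genes_never_duplicated(self):
        rng = np.random.default_rng(7)
        coll = build_digraphs(matrix_of(rng.normal(size=(12, 8))))
        final, _ = grow_seed_set(coll, SeedSet((0, 2)), TransBicParams())
        genes = [k // 2 for k in final.members]
        assert len(genes) == len(set(genes))

    def test_planted_module_dominates_growth(self):
        # strong-signal regime: module spans most conditions, so growth
        # should absorb nearly all planted digraphs before any noise
        from transbic.synthetic import generate_background, implant_bicluster

        bg = generate_background(60, 20, seed=42)
        rows = list(range(15))
        cols = list(range(15))
        mat, entry = implant_bicluster(
            bg, rows, cols, "btp", {"n_buckets": 4}, seed=42
        )
        coll = build_digraphs(mat)
        from transbic.digraphs import pairwise_shared
        from transbic.core import DOWN

        planted = {
            2 * g + (0 if d == DOWN else 1): g
            for g, d in entry.directions.items()
        }
        shared = pairwise_shared(coll)
        keys = sorted(planted)
        sub = shared[np.ix_(keys, keys)].astype(float)
        np.fill_diagonal(sub, -1)
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        seed = SeedSet((min(keys[a], keys[b]), max(keys[a], keys[b])))
        final, _ = grow_seed_set(coll, seed, TransBicParams(), pair_overlap=shared)
        matching = sum(1 for k in final.members if k in planted)
        assert matching >= 12
        assert matching / len(final) >= 0.8
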