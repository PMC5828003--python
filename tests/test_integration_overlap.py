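"""Gene-set union, locus clustering, UpSet cells and the resampling null."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regshare.integration_overlap import (
    GeneSet,
    cluster_loci,
    expected_overlap,
    randomization_test,
    union_sources,
    upset_counts,
)
from regshare.regulatory_map import RegulatoryHit


class TestUnionSources:
    def test_union_and_provenance(self):
        hits = [
            RegulatoryHit("rs1", "A", "gtex_single", 0.01),
            RegulatoryHit("rs2", "A", "fantom5", 1.0),
            RegulatoryHit("rs2", "B", "fantom5", 1.0),
        ]
        gs = union_sources(hits, "LUAD")
        assert gs.genes == {"A", "B"}
        assert gs.provenance["A"] == {"gtex_single", "fantom5"}
        assert gs.provenance["B"] == {"fantom5"}

    def test_empty_sources_give_empty_set(self):
        gs = union_sources([], "LUAD")
        assert gs.genes == set()

    def test_provenance_keys_must_match_genes(self):
        with pytest.raises(ValueError):
            GeneSet("LUAD", {"A"}, {})

    def test_provenance_reproduces_per_source_upset(self):
        """Exclusive cells computed from provenance equal upset_counts on
        the per-source gene sets (set-algebra oracle on a toy instance)."""
        hits = [
            RegulatoryHit("rs1", "A", "gtex_single", 0.01),
            RegulatoryHit("rs1", "A", "gtex_multi", 0.9),
            RegulatoryHit("rs2", "B", "gtex_single", 0.02),
            RegulatoryHit("rs3", "C", "fantom5", 1.0),
            RegulatoryHit("rs3", "A", "impet", 1.0),
            RegulatoryHit("rs4", "D", "probe_eqtl", 0.05),
        ]
        gs = union_sources(hits, "X")
        sources = sorted({s for srcs in gs.provenance.values() for s in srcs})
        per_source = {
            s: {g for g, srcs in gs.provenance.items() if s in srcs}
            for s in sources
        }
        report = upset_counts(per_source)
        for gene, srcs in gs.provenance.items():
            assert gene in report.members(*srcs)
        assert report.union_size == len(gs.genes)


class TestClusterLoci:
    def test_gap_chaining_example(self):
        spans = [("g1", "chr1", 1_000_000, 1_100_000),
                 ("g2", "chr1", 1_500_000, 1_600_000),
                 ("g3", "chr1", 3_000_000, 3_100_000)]
        clustering = cluster_loci(spans, distance_bp=1_000_000)
        parts = {frozenset(c.genes) for c in clustering.clusters}
        assert parts == {frozenset({"g1", "g2"}), frozenset({"g3"})}

    def test_single_gene_single_cluster(self):
        clustering = cluster_loci([("g", "1", 0, 10)])
        assert clustering.n_loci == 1

    def test_different_chromosomes_never_co_cluster(self):
        clustering = cluster_loci([("a", "1", 0, 10), ("b", "2", 0, 10)])
        assert clustering.n_loci == 2

    def test_overlapping_intervals_always_co_cluster(self):
        clustering = cluster_loci([("a", "1", 0, 100), ("b", "1", 50, 60)],
                                  distance_bp=1)
        assert clustering.n_loci == 1

    @staticmethod
    def _brute_force_partition(spans, d):
        """Transitive closure of the pairwise gap <= d relation."""
        def gap(x, y):
            if x[1] != y[1]:
                return None
            lo, hi = sorted([x, y], key=lambda t: t[2])
            return max(0, hi[2] - lo[3])

        parent = {s[0]: s[0] for s in spans}

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        for i, x in enumerate(spans):
            for y in spans[i + 1:]:
                g = gap(x, y)
                if g is not None and g <= d:
                    parent[find(x[0])] = find(y[0])
        groups = {}
        for s in spans:
            groups.setdefault(find(s[0]), set()).add(s[0])
        return {frozenset(v) for v in groups.values()}

    def test_matches_transitive_closure_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(1, 25))
            spans = []
            for i in range(n):
                start = int(rng.integers(0, 10_000))
                spans.append((f"g{i}", str(rng.integers(1, 3)), start,
                              start + int(rng.integers(1, 2_000))))
            d = int(rng.integers(1, 3_000))
            got = {frozenset(c.genes) for c in cluster_loci(spans, d).clusters}
            assert got == self._brute_force_partition(spans, d)


class TestUpsetCounts:
    def test_worked_three_set_example(self):
        report = upset_counts({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 5}})
        assert report.cell("A", "B", "C") == 1
        assert report.cell("A", "B") == 1
        assert report.cell("A") == 1
        assert report.cell("B") == 1
        assert report.cell("C") == 1
        assert report.cell("A", "C") == 0
        assert report.cell("B", "C") == 0
        assert report.union_size == 5

    def test_identical_sets_fill_only_full_cell(self):
        report = upset_counts({"A": {1, 2}, "B": {1, 2}})
        assert report.cell("A", "B") == 2
        assert report.cell("A") == 0 and report.cell("B") == 0

    def test_disjoint_sets_fill_only_singletons(self):
        report = upset_counts({"A": {1}, "B": {2}})
        assert report.cell("A") == 1 and report.cell("B") == 1
        assert report.cell("A", "B") == 0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            upset_counts({"A": {1}})

    @given(st.lists(st.sets(st.integers(0, 30)), min_size=2, max_size=4))
    def test_cells_partition_the_union(self, sets):
        labeled = {f"S{i}": s for i, s in enumerate(sets)}
        report = upset_counts(labeled)
        union = set().union(*labeled.values())
        assert sum(report.exclusive_cells.values()) == len(union)
        assert report.union_size == len(union)


class TestRandomizationTest:
    def test_sizes_equal_pool_force_full_overlap(self):
        pool = {f"rs{i}" for i in range(5)}
        res = randomization_test([5, 5, 5], pool, n_trials=50, seed=0,
                                 observed_overlap=5)
        assert res.overlap_distribution == {5: 50}
        assert res.empirical_p == 1.0

    def test_single_element_pool(self):
        res = randomization_test([1, 1, 1], {"rs1"}, n_trials=20, seed=0,
                                 observed_overlap=1)
        assert res.overlap_distribution == {1: 20}
        assert res.empirical_p == 1.0

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            randomization_test([3], {"a", "b"}, n_trials=10, seed=0)

    def test_reproducible_for_fixed_seed(self):
        pool = {f"rs{i}" for i in range(50)}
        a = randomization_test([10, 10], pool, n_trials=500, seed=3)
        b = randomization_test([10, 10], pool, n_trials=500, seed=3)
        assert a.overlap_distribution == b.overlap_distribution

    def test_empirical_p_counts_at_least_as_extreme_trials(self):
        pool = {f"rs{i}" for i in range(20)}
        res = randomization_test([10, 10], pool, n_trials=1000, seed=4,
                                 observed_overlap=5)
        n_ge = sum(c for v, c in res.overlap_distribution.items() if v >= 5)
        assert res.empirical_p == (1 + n_ge) / 1001

    def test_mean_overlap_matches_analytic_expectation(self):
        pool = {f"rs{i}" for i in range(100)}
        n_trials = 20_000
        res = randomization_test([10, 10, 10], pool, n_trials=n_trials, seed=5)
        values = np.array(list(res.overlap_distribution.keys()))
        freqs = np.array(list(res.overlap_distribution.values()))
        mean = (values * freqs).sum() / n_trials
        var = ((values - mean) ** 2 * freqs).sum() / n_trials
        se = np.sqrt(var / n_trials)
        exact = expected_overlap([10, 10, 10], 100)
        assert exact == pytest.approx(0.1)
        assert abs(mean - exact) <= 3 * max(se, 1e-9)

    def test_agrees_with_independent_brute_force_at_small_pool(self):
        """Compare against a from-scratch random.sample simulation, N=20."""
        pool = [f"rs{i}" for i in range(20)]
        sizes = [5, 5, 5]
        n_trials = 10_000
        res = randomization_test(sizes, set(pool), n_trials=n_trials, seed=6)
        rng = random.Random(606)
        brute = Counter()
        for _ in range(n_trials):
            sets = [set(rng.sample(pool, s)) for s in sizes]
            brute[len(set.intersection(*sets))] += 1

        def mean_se(counter):
            vals = np.array(list(counter.keys()), dtype=float)
            freqs = np.array(list(counter.values()), dtype=float)
            m = (vals * freqs).sum() / n_trials
            v = ((vals - m) ** 2 * freqs).sum() / n_trials
            return m, np.sqrt(v / n_trials)

        exact = expected_overlap(sizes, 20)
        m1, se1 = mean_se(res.overlap_distribution)
        m2, se2 = mean_se(brute)
        assert abs(m1 - exact) <= 3 * se1
        assert abs(m2 - exact) <= 3 * se2
        # distributions agree cell-wise within Monte-Carlo error
        for k in set(res.overlap_distribution) | set(brute):
            f1 = res.overlap_distribution.get(k, 0) / n_trials
            f2 = brute.get(k, 0) / n_trials
            se = np.sqrt(max(f1, f2) * (1 - min(f1, f2)) / n_trials)
            assert abs(f1 - f2) <= max(4 * se, 0.005)
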