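import itertools

import numpy as np
import pandas as pd
import pytest

from coexmod.agreement import AgreementMatrix
from coexmod.discovery import (
    AgreementClustering,
    ModuleSet,
    SignificanceDistribution,
    agreement_cluster,
    filter_significant,
    iterate_discovery,
    merge_similar,
    objective,
    random_cluster_sizes,
    resample_profiles,
    select_clusterable,
)

from conftest import random_agreement_matrix

DELTA = 0.7


def block_am(sizes, high=1.0, low=0.0):
    """Block-diagonal agreement matrix: `high` within blocks, `low` between."""
    n = sum(sizes)
    m = np.full((n, n), low)
    start = 0
    for s in sizes:
        m[start : start + s, start : start + s] = high
        start += s
    np.fill_diagonal(m, 1.0)
    return AgreementMatrix(object_ids=[f"g{i}" for i in range(n)], entries=m)


# ---------------------------------------------------------------------------
# clusterable-subset selection


class TestSelectClusterable:
    def test_no_moderate_entries_selects_everything(self):
        am = block_am([3, 4])
        selected, removed = select_clusterable(am, DELTA)
        assert selected == am.object_ids
        assert removed == []

    def test_worked_seven_gene_example(self, worked_example_am):
        selected, removed = select_clusterable(worked_example_am, DELTA)
        assert selected == ["x", "z", "t", "v"]
        assert set(removed) == {"y", "u", "w"}

    def test_greedy_trace_matches_step_oracle(self, rng):
        # oracle: recompute moderate counts from scratch after each removal
        am = random_agreement_matrix(rng, 6)
        _, removed = select_clusterable(am, DELTA)
        active = list(range(6))
        expected = []
        while True:
            sub = am.entries[np.ix_(active, active)]
            mod = (sub > 1 - DELTA) & (sub < DELTA)
            np.fill_diagonal(mod, False)
            counts = mod.sum(axis=1)
            if counts.max() == 0:
                break
            worst = int(np.argmax(counts))
            expected.append(am.object_ids[active[worst]])
            del active[worst]
        assert removed == expected

    def test_selected_subset_has_no_moderate_entries(self, rng):
        for _ in range(5):
            am = random_agreement_matrix(rng, 12)
            selected, _ = select_clusterable(am, DELTA)
            sub = am.subset(selected).entries
            off = sub[np.triu_indices(len(selected), 1)]
            assert not np.any((off > 1 - DELTA) & (off < DELTA))

    def test_delta_validation(self, rng):
        with pytest.raises(ValueError):
            select_clusterable(random_agreement_matrix(rng, 4), delta=0.4)


# ---------------------------------------------------------------------------
# agreement-constrained clustering


class TestAgreementCluster:
    def test_worked_example_clusters(self, worked_example_am):
        sub = worked_example_am.subset(["x", "z", "t", "v"])
        clusters = agreement_cluster(sub, DELTA)
        assert sorted(map(sorted, clusters)) == [["t"], ["v", "x", "z"]]

    def test_two_blocks(self):
        am = block_am([3, 2])
        clusters = agreement_cluster(am, DELTA)
        assert sorted(map(sorted, clusters)) == [["g0", "g1", "g2"], ["g3", "g4"]]

    def test_singleton_input(self):
        am = AgreementMatrix(object_ids=["only"], entries=np.eye(1))
        assert agreement_cluster(am, DELTA) == [["only"]]

    def test_every_cluster_satisfies_min_pairwise_delta(self, rng):
        for _ in range(5):
            am = random_agreement_matrix(rng, 10)
            selected, _ = select_clusterable(am, DELTA)
            if not selected:
                continue
            for cluster in agreement_cluster(am.subset(selected), DELTA):
                if len(cluster) >= 2:
                    sub = am.subset(cluster).entries
                    assert sub[np.triu_indices(len(cluster), 1)].min() >= DELTA


# ---------------------------------------------------------------------------
# iterative discovery


class TestIterateDiscovery:
    def test_worked_example_full_trace(self, worked_example_am):
        ms = iterate_discovery(worked_example_am, DELTA)
        assert sorted(map(sorted, ms.clusters)) == [["t"], ["u", "y"], ["v", "x", "z"]]
        assert ms.unassigned == ["w"]
        by_cluster = {tuple(sorted(c)): it for c, it in zip(ms.clusters, ms.provenance)}
        assert by_cluster[("u", "y")] == 2
        assert by_cluster[("v", "x", "z")] == 1

    def test_all_ones_single_cluster(self):
        am = block_am([5], high=1.0)
        ms = iterate_discovery(am, DELTA)
        assert ms.n_clusters == 1
        assert sorted(ms.clusters[0]) == am.object_ids
        assert ms.unassigned == []

    def test_three_blocks_one_iteration(self):
        am = block_am([4, 3, 3])
        ms = iterate_discovery(am, DELTA)
        assert ms.n_clusters == 3
        assert set(ms.provenance) == {1}
        assert ms.unassigned == []

    def test_partition_covers_all_genes(self, rng):
        am = random_agreement_matrix(rng, 15)
        ms = iterate_discovery(am, DELTA)
        all_ids = sorted(ms.assigned + ms.unassigned)
        assert all_ids == sorted(am.object_ids)

    def test_estimator_wrapper_labels(self, worked_example_am):
        est = AgreementClustering(delta=DELTA)
        labels = est.fit_predict(worked_example_am)
        assert labels.shape == (7,)
        assert labels[6] == -1  # w unassigned
        assert est.get_params() == {"delta": DELTA}


# ---------------------------------------------------------------------------
# significance


class TestSignificance:
    def test_worked_distribution_thresholds(self):
        # 40 random clusters arranged so the p-value curve yields the worked
        # cutoffs: 10 at p = 0.05 and 8 at p = 0.1
        sizes = [12, 10, 9, 8, 7] + [2] * 35
        dist = SignificanceDistribution(random_cluster_sizes=sizes)
        assert dist.p_value(10) == pytest.approx(0.05)
        assert dist.p_value(9) == pytest.approx(0.075)
        assert dist.p_value(8) == pytest.approx(0.1)
        assert dist.p_value(7) == pytest.approx(0.125)
        assert dist.threshold(p=0.05) == 10
        assert dist.threshold(p=0.1) == 8

    def test_all_small_clusters_cutoff_above_max(self):
        dist = SignificanceDistribution(random_cluster_sizes=[2] * 100)
        assert dist.threshold(p=0.05) == 3

    def test_constructed_multiset_matches_oracle_scan(self):
        sizes = [2] * 90 + [5] * 8 + [12] * 2
        dist = SignificanceDistribution(random_cluster_sizes=sizes)
        # independent oracle: scan the printed p-value formula directly
        def oracle(p):
            for cs in range(2, max(sizes) + 2):
                if sum(s >= cs for s in sizes) / len(sizes) <= p:
                    return cs
        for p in (0.01, 0.05, 0.1, 0.5):
            assert dist.threshold(p) == oracle(p)

    def test_p_value_non_increasing_and_threshold_monotone(self, rng):
        sizes = rng.integers(2, 30, size=200).tolist()
        dist = SignificanceDistribution(random_cluster_sizes=sizes)
        pvals = [dist.p_value(cs) for cs in range(2, 32)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))
        cutoffs = [dist.threshold(p) for p in (0.01, 0.05, 0.1, 0.2)]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))

    def test_empty_distribution_defaults_with_warning(self):
        dist = SignificanceDistribution(random_cluster_sizes=[])
        with pytest.warns(UserWarning, match="defaulting"):
            assert dist.threshold(0.05) == 2

    def test_resampling_schemes(self, rng):
        X = rng.standard_normal((6, 10))
        perm = resample_profiles(X, np.random.default_rng(0), "permutation")
        np.testing.assert_allclose(np.sort(perm, axis=1), np.sort(X, axis=1))
        hull = resample_profiles(X, np.random.default_rng(0), "convex-hull")
        assert hull.shape == X.shape
        assert hull.min() >= X.min() - 1e-12 and hull.max() <= X.max() + 1e-12
        with pytest.raises(ValueError):
            resample_profiles(X, np.random.default_rng(0), "bootstrap")

    def test_random_cluster_sizes_runs_end_to_end(self, rng):
        X = rng.standard_normal((24, 8))
        dist = random_cluster_sizes(X, n_clusters=3, n_resamples=2, random_state=0)
        assert all(s >= 2 for s in dist.random_cluster_sizes)


class TestFilterSignificant:
    def test_keeps_clusters_at_or_above_cutoff(self):
        ms = ModuleSet(clusters=[[f"a{i}" for i in range(12)],
                                 [f"b{i}" for i in range(9)],
                                 [f"c{i}" for i in range(3)]])
        out = filter_significant(ms, 10)
        assert out.sizes == [12]
        assert len(out.unassigned) == 12
        boundary = filter_significant(ms, 9)  # inclusive boundary
        assert sorted(boundary.sizes) == [9, 12]

    def test_zero_cutoff_is_identity(self):
        ms = ModuleSet(clusters=[["a"], ["b", "c"]])
        out = filter_significant(ms, 0)
        assert out.clusters == ms.clusters


# ---------------------------------------------------------------------------
# merging and the homogeneity+separation objective


def brute_force_objective(clusters, sims):
    """Independent evaluation: explicit loops over Eq.-style sums."""
    K = len(sims)
    n = len(clusters)
    total = 0.0
    for k in range(K):
        sim = sims[k]
        for cp in clusters:
            if len(cp) < 2:
                continue
            h = sum(sim[i][j] for i in cp for j in cp if i != j)
            total += h / (len(cp) * (len(cp) - 1)) / (K * n)
    if n >= 2:
        for k in range(K):
            sim = sims[k]
            for p in range(n):
                for q in range(p + 1, n):
                    s = sum(1 - sim[i][j] for i in clusters[p] for j in clusters[q])
                    total += (s / (len(clusters[p]) * len(clusters[q]))) * 2 / (K * n * (n - 1))
    return total


def profiles_from_rows(rows):
    return pd.DataFrame(np.asarray(rows, dtype=float),
                        index=[f"g{i}" for i in range(len(rows))])


def trivial_map(n):
    return {f"g{i}": [f"g{i}"] for i in range(n)}


class TestObjective:
    def test_identical_profiles_homogeneity_one(self, rng):
        base = rng.standard_normal(10)
        prof = profiles_from_rows([base, base])
        ms = ModuleSet(clusters=[["g0", "g1"]])
        assert objective(ms, [prof], [trivial_map(2)]) == pytest.approx(1.0)

    def test_anticorrelated_singletons_separation_two(self, rng):
        base = rng.standard_normal(10)
        prof = profiles_from_rows([base, -base])
        ms = ModuleSet(clusters=[["g0"], ["g1"]])
        assert objective(ms, [prof], [trivial_map(2)]) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_fixture(self, rng):
        rows = rng.standard_normal((7, 12))
        prof = profiles_from_rows(rows)
        ms = ModuleSet(clusters=[["g0", "g1", "g2"], ["g3", "g4"], ["g5", "g6"]])
        got = objective(ms, [prof], [trivial_map(7)])
        sim = np.corrcoef(rows)
        idx = [[0, 1, 2], [3, 4], [5, 6]]
        assert got == pytest.approx(brute_force_objective(idx, [sim]), abs=1e-12)

    def test_zero_variance_profile_warns(self):
        prof = profiles_from_rows([[1.0] * 5, [0.0, 1.0, 2.0, 3.0, 4.0]])
        ms = ModuleSet(clusters=[["g0", "g1"]])
        with pytest.warns(UserWarning, match="zero-variance"):
            objective(ms, [prof], [trivial_map(2)])


class TestMergeSimilar:
    @staticmethod
    def _split_fixture(rng):
        t = np.linspace(0, 1, 12)
        wave = np.sin(2 * np.pi * t)
        rows = [wave + 0.01 * rng.standard_normal(12) for _ in range(6)]
        rows += [t * 3 + 0.01 * rng.standard_normal(12) for _ in range(3)]
        return profiles_from_rows(rows)

    def test_artificially_split_cluster_is_merged(self, rng):
        prof = self._split_fixture(rng)
        ms = ModuleSet(clusters=[["g0", "g1", "g2"], ["g3", "g4", "g5"], ["g6", "g7", "g8"]])
        out = merge_similar(ms, [prof], [trivial_map(9)])
        assert sorted(map(sorted, out.clusters)) == [
            ["g0", "g1", "g2", "g3", "g4", "g5"],
            ["g6", "g7", "g8"],
        ]

    def test_anticorrelated_clusters_never_merge(self, rng):
        base = rng.standard_normal(10)
        rows = [base, base + 0.01 * rng.standard_normal(10), -base, -base + 0.01 * rng.standard_normal(10)]
        prof = profiles_from_rows(rows)
        ms = ModuleSet(clusters=[["g0", "g1"], ["g2", "g3"]])
        out = merge_similar(ms, [prof], [trivial_map(4)])
        assert out.n_clusters == 2

    def test_greedy_matches_exhaustive_on_small_fixture(self, rng):
        prof = self._split_fixture(rng)
        clusters = [["g0", "g1"], ["g2", "g3"], ["g4", "g5"], ["g6", "g7", "g8"]]
        ms = ModuleSet(clusters=clusters)
        out = merge_similar(ms, [prof], [trivial_map(9)])
        got = objective(out, [prof], [trivial_map(9)])

        # exhaustive oracle over every coarsening reachable by merges
        sim = np.corrcoef(prof.to_numpy())
        idx = [[0, 1], [2, 3], [4, 5], [6, 7, 8]]
        best = -np.inf
        for n_parts in range(1, 5):
            for assignment in itertools.product(range(n_parts), repeat=4):
                if len(set(assignment)) != n_parts:
                    continue
                merged = [sum((idx[i] for i in range(4) if assignment[i] == p), [])
                          for p in range(n_parts)]
                best = max(best, brute_force_objective(merged, [sim]))
        assert got == pytest.approx(best, abs=1e-9)

    def test_objective_never_decreases_and_count_never_grows(self, rng):
        rows = rng.standard_normal((8, 10))
        prof = profiles_from_rows(rows)
        ms = ModuleSet(clusters=[["g0", "g1"], ["g2", "g3"], ["g4", "g5"], ["g6", "g7"]])
        before = objective(ms, [prof], [trivial_map(8)])
        out = merge_similar(ms, [prof], [trivial_map(8)])
        after = objective(out, [prof], [trivial_map(8)])
        assert after >= before - 1e-12
        assert out.n_clusters <= ms.n_clusters


def test_module_set_rejects_overlap():
    with pytest.raises(ValueError, match="disjoint"):
        ModuleSet(clusters=[["a", "b"], ["b", "c"]])
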