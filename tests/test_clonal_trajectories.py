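import itertools

import numpy as np
import pytest

from clonokit import clonal_trajectories as ct
from clonokit import synthetic_data as sd
from clonokit.core_model import DIAGNOSIS, R1, R2


def cluster(cid, d, r1, r2=None, n=100):
    ccf = {DIAGNOSIS: d, R1: r1}
    if r2 is not None:
        ccf[R2] = r2
    return ct.MutationCluster(cid, n, ccf)


def tree_from(parent_map, clusters):
    root = next(i for i, p in parent_map.items() if p is None)
    return ct.CloneTree(list(clusters), dict(parent_map), root)


class TestCcf:
    def test_basic(self):
        assert ct.ccf_from_af(0.2, 0.8) == pytest.approx(0.5)

    def test_clipped(self):
        assert ct.ccf_from_af(0.6, 0.5) == 1.0

    def test_bad_purity(self):
        with pytest.raises(ValueError):
            ct.ccf_from_af(0.2, 0.0)


class TestClusterVafs:
    @staticmethod
    def _counts(centers, n_per, depth=90, seed=0):
        rng = np.random.default_rng(seed)
        counts = {}
        i = 0
        for (c_d, c_r), n in zip(centers, n_per):
            for _ in range(n):
                key = f"v{i}"
                i += 1
                counts[key] = {}
                for tp, c in ((DIAGNOSIS, c_d), (R1, c_r)):
                    d = rng.poisson(depth)
                    a = rng.binomial(d, 0.8 * c / 2) if d else 0
                    counts[key][tp] = (a, d)
        return counts

    def test_two_planted_clusters_recovered(self):
        counts = self._counts([(1.0, 1.0), (0.2, 0.9)], [200, 200], seed=1)
        res = ct.cluster_vafs(counts, {DIAGNOSIS: 0.8, R1: 0.8}, max_clusters=6, seed=2)
        assert len(res.clusters) == 2
        centers = sorted(
            (c.ccf[DIAGNOSIS], c.ccf[R1]) for c in res.clusters
        )
        assert centers[0] == pytest.approx((0.2, 0.9), abs=0.05)
        assert centers[1] == pytest.approx((1.0, 1.0), abs=0.05)

    def test_identical_ccf_single_cluster(self):
        counts = self._counts([(0.8, 0.8)], [150], seed=3)
        res = ct.cluster_vafs(counts, {DIAGNOSIS: 0.8, R1: 0.8}, max_clusters=5, seed=4)
        assert len(res.clusters) == 1

    def test_deterministic_under_seed(self):
        counts = self._counts([(1.0, 1.0), (0.3, 0.8)], [60, 60], seed=5)
        a = ct.cluster_vafs(counts, {DIAGNOSIS: 0.8, R1: 0.8}, seed=6)
        b = ct.cluster_vafs(counts, {DIAGNOSIS: 0.8, R1: 0.8}, seed=6)
        assert a.assignments == b.assignments

    def test_single_timepoint_errors(self):
        counts = {"v": {DIAGNOSIS: (10, 90)}}
        with pytest.raises(ValueError):
            ct.cluster_vafs(counts, {DIAGNOSIS: 0.8})

    def test_min_cluster_size_merging(self):
        counts = self._counts([(1.0, 1.0), (0.5, 0.5)], [100, 2], seed=7)
        res = ct.cluster_vafs(counts, {DIAGNOSIS: 0.8, R1: 0.8}, seed=8, min_cluster_size=5)
        assert all(c.n_variants >= 5 for c in res.clusters)


# --- brute-force tree oracle ------------------------------------------------

def brute_force_trees(clusters, eps, root):
    """All rooted parent vectors over the clusters that are acyclic,
    root-connected and satisfy the sum rule at every node and timepoint."""
    K = len(clusters)
    tps = list(clusters[root].ccf.keys())
    nodes = [i for i in range(K) if i != root]
    out = []
    for combo in itertools.product(*[[j for j in range(K) if j != i] for i in nodes]):
        parent = {root: None}
        parent.update(dict(zip(nodes, combo)))
        # acyclicity / connectivity to root
        ok = True
        for i in nodes:
            seen = set()
            j = i
            while j is not None:
                if j in seen:
                    ok = False
                    break
                seen.add(j)
                j = parent[j]
            if not ok or root not in seen:
                ok = False
                break
        if not ok:
            continue
        for node in range(K):
            kids = [i for i in nodes if parent[i] == node]
            for tp in tps:
                if sum(clusters[k].ccf.get(tp, 0) for k in kids) > clusters[node].ccf.get(tp, 0) + eps:
                    ok = False
        if ok:
            out.append(tuple(parent[i] for i in range(K)))
    out.sort(key=lambda t: tuple(-1 if p is None else p for p in t))
    return out


class TestEnumerateTrees:
    def test_unique_tree_example(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.6, 0.1), cluster(2, 0.3, 0.8)]
        trees = ct.enumerate_trees(clusters, eps=0.05, root=0)
        assert trees == [(None, 0, 0)]

    def test_single_cluster(self):
        assert ct.enumerate_trees([cluster(0, 1.0, 1.0)]) == [(None,)]

    def test_no_consistent_tree(self):
        # two "dominant" clusters that cannot nest either way and overflow as siblings
        clusters = [cluster(0, 1.0, 0.1), cluster(1, 0.9, 0.9), cluster(2, 0.9, 0.2)]
        trees = ct.enumerate_trees(clusters, eps=0.01, root=0)
        assert trees == []

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(11)
        for trial in range(150):
            k = int(rng.integers(2, 6))
            clusters = [cluster(0, 1.0, 1.0)]
            for i in range(1, k):
                clusters.append(
                    cluster(i, float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
                )
            got = ct.enumerate_trees(clusters, eps=0.05, root=0)
            expected = brute_force_trees(clusters, eps=0.05, root=0)
            assert got == expected, f"trial {trial}"


class TestBuildCloneTree:
    def test_single_cluster_trivial(self):
        res = ct.build_clone_tree([cluster(0, 1.0, 1.0)])
        assert res.tree is not None and res.probability_score == 1.0

    def test_unique_topology_and_sum_rule(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.6, 0.1), cluster(2, 0.3, 0.8)]
        res = ct.build_clone_tree(clusters)
        assert res.tree.topology() == (None, 0, 0)
        assert res.tree.check_sum_rule(0.05)

    def test_no_tree_result(self):
        clusters = [cluster(0, 1.0, 0.1), cluster(1, 0.9, 0.9), cluster(2, 0.9, 0.2)]
        res = ct.build_clone_tree(clusters, eps=0.01)
        assert res.tree is None and res.probability_score == 0.0

    def test_bootstrap_score_stable_for_clear_tree(self):
        cfg = sd.SimConfig(seed=21)
        tree, _ = sd.simulate_clone_tree(cfg, trajectory=ct.RISING)
        reads = sd.simulate_variant_reads(tree, cfg, purities={DIAGNOSIS: 0.8, R1: 0.8})
        res = ct.cluster_vafs(reads.variant_counts, reads.purities, max_clusters=6, seed=3)
        tr = ct.build_clone_tree(
            res.clusters,
            assignments=res.assignments,
            variant_ccfs=res.variant_ccfs,
            n_resamples=50,
            seed=3,
        )
        assert tr.tree is not None
        assert tr.probability_score >= 0.9

    def test_too_many_clusters(self):
        clusters = [cluster(i, 1.0, 1.0) for i in range(12)]
        with pytest.raises(ValueError):
            ct.build_clone_tree(clusters)


class TestClassifyTrajectory:
    def test_persistent_founding_major_override(self):
        # founding clone is the diagnostic major; relapse major is its child
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.0, 0.7)]
        tree = tree_from({0: None, 1: 0}, clusters)
        call = ct.classify_trajectory(tree)
        assert call.label == ct.PERSISTENT

    def test_persistent_nested(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.7, 0.9), cluster(2, 0.0, 0.6)]
        tree = tree_from({0: None, 1: 0, 2: 1}, clusters)
        assert ct.classify_trajectory(tree).label == ct.PERSISTENT

    def test_rising_subclone(self):
        # diagnostic subclone (0.2) expands; new child is relapse major
        clusters = [
            cluster(0, 1.0, 1.0),
            cluster(1, 0.6, 0.02),
            cluster(2, 0.2, 0.95),
            cluster(3, 0.0, 0.7),
        ]
        tree = tree_from({0: None, 1: 0, 2: 0, 3: 2}, clusters)
        call = ct.classify_trajectory(tree)
        assert call.label == ct.RISING
        assert call.evidence["anchor"] == 2

    def test_founding(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.8, 0.0), cluster(2, 0.0, 0.9)]
        tree = tree_from({0: None, 1: 0, 2: 0}, clusters)
        assert ct.classify_trajectory(tree).label == ct.FOUNDING

    def test_low_purity_undetermined(self):
        call = ct.classify_trajectory(None, relapse_purity=0.1)
        assert call.label == ct.UNDETERMINED and call.reason == "low purity"

    def test_no_tree_undetermined(self):
        call = ct.classify_trajectory(None, relapse_purity=0.8)
        assert call.label == ct.UNDETERMINED and call.reason == "no consistent tree"

    def test_purity_invariance(self):
        """CCFs are purity-corrected, so halving purity (and AF with it)
        leaves the classification unchanged."""
        for purity in (1.0, 0.5, 0.3):
            afs = {  # (dx af, r1 af) at purity 1.0 for 4 clones
                0: (0.5, 0.5), 1: (0.3, 0.01), 2: (0.1, 0.475), 3: (0.0, 0.35),
            }
            clusters = [
                cluster(
                    i,
                    ct.ccf_from_af(a * purity, purity),
                    ct.ccf_from_af(b * purity, purity),
                )
                for i, (a, b) in afs.items()
            ]
            tree = tree_from({0: None, 1: 0, 2: 0, 3: 2}, clusters)
            assert ct.classify_trajectory(tree).label == ct.RISING

    def test_undetermined_requires_reason(self):
        with pytest.raises(ValueError):
            ct.TrajectoryCall("P", "diagnosis->r1", ct.UNDETERMINED)


class TestDeepSequencingReassignment:
    def _founding_call(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.8, 0.0), cluster(2, 0.0, 0.9)]
        tree = tree_from({0: None, 1: 0, 2: 0}, clusters)
        assignments = {"vA": 1, "vB": 2}
        return ct.classify_trajectory(tree, assignments=assignments)

    def test_detected_promotes_to_rising(self):
        call = self._founding_call()
        out = ct.reassign_with_deep_sequencing(call, {"vB": 0.02})
        assert out.label == ct.RISING
        assert out.evidence["deep_sequencing_detected"] == {"vB": 0.02}

    def test_zero_afs_unchanged(self):
        call = self._founding_call()
        assert ct.reassign_with_deep_sequencing(call, {"vB": 0.0}) == call

    def test_non_lineage_variant_ignored(self):
        call = self._founding_call()
        # vA sits on the eradicated diagnostic branch, not the relapse lineage
        assert ct.reassign_with_deep_sequencing(call, {"vA": 0.5}).label == ct.FOUNDING

    def test_non_founding_input_errors(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.0, 0.7)]
        tree = tree_from({0: None, 1: 0}, clusters)
        call = ct.classify_trajectory(tree)  # persistent
        with pytest.raises(ValueError):
            ct.reassign_with_deep_sequencing(call, {})


class TestRelapseToRelapse:
    def test_persistent_r1_to_r2(self):
        clusters = [
            cluster(0, 1.0, 1.0, 1.0),
            cluster(1, 0.0, 0.8, 0.85),
            cluster(2, 0.0, 0.0, 0.4),
        ]
        tree = tree_from({0: None, 1: 0, 2: 1}, clusters)
        call = ct.relapse_to_relapse_trajectory(tree)
        assert call.label == ct.PERSISTENT
        assert call.interval == "r1->r2"

    def test_rising_r1_to_r2(self):
        clusters = [
            cluster(0, 1.0, 1.0, 1.0),
            cluster(1, 0.0, 0.7, 0.02),
            cluster(2, 0.0, 0.15, 0.9),
            cluster(3, 0.0, 0.0, 0.6),
        ]
        tree = tree_from({0: None, 1: 0, 2: 0, 3: 2}, clusters)
        assert ct.relapse_to_relapse_trajectory(tree).label == ct.RISING

    def test_missing_r2_errors(self):
        clusters = [cluster(0, 1.0, 1.0), cluster(1, 0.0, 0.7)]
        tree = tree_from({0: None, 1: 0}, clusters)
        with pytest.raises(ValueError):
            ct.relapse_to_relapse_trajectory(tree)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("trajectory", [ct.PERSISTENT, ct.RISING, ct.FOUNDING])
    def test_simulated_trajectory_recovered(self, trajectory):
        hits = 0
        n = 6
        for s in range(n):
            cfg = sd.SimConfig(seed=300 + s)
            tree, _ = sd.simulate_clone_tree(cfg, trajectory=trajectory)
            assert tree.check_sum_rule(1e-9)
            reads = sd.simulate_variant_reads(
                tree, cfg, purities={DIAGNOSIS: 0.7, R1: 0.7}
            )
            res = ct.cluster_vafs(reads.variant_counts, reads.purities, max_clusters=6, seed=s)
            tr = ct.build_clone_tree(res.clusters, n_resamples=0)
            if tr.tree is not None:
                assert tr.tree.check_sum_rule(0.05)
            call = ct.classify_trajectory(tr.tree)
            hits += call.label == trajectory
        assert hits >= n - 1
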