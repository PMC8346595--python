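"""Multi-timepoint VAF clustering, clone-tree construction and clonal
trajectory classification.

Somatic variants observed at two or more timepoints are clustered with a
finite binomial mixture over joint cancer-cell fractions (CCF = min(1,
2*AF/purity) under a diploid copy-neutral model), the component count chosen
by BIC.  Rooted clone trees over the clusters are enumerated under the
pigeonhole sum rule (a parent's CCF at every timepoint must cover the sum of
its children's within a tolerance), a consensus topology is picked by
bootstrap stability, and each diagnosis->relapse interval is classified as a
persistent, rising or founding trajectory, or left undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .core_model import DIAGNOSIS, R1, R2

PERSISTENT = "persistent"
RISING = "rising"
FOUNDING = "founding"
UNDETERMINED = "undetermined"
TRAJECTORY_LABELS = (PERSISTENT, RISING, FOUNDING, UNDETERMINED)


def ccf_from_af(af: float, purity: float) -> float:
    """Cancer-cell fraction under the diploid copy-neutral assumption."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    return min(1.0, 2.0 * af / purity)


@dataclass
class MutationCluster:
    cluster_id: int
    n_variants: int
    ccf: dict  # timepoint -> mean CCF

    def __post_init__(self):
        for tp, c in self.ccf.items():
            if not (-1e-9 <= c <= 1 + 1e-9):
                raise ValueError(f"CCF out of [0,1] at {tp}: {c}")
            self.ccf[tp] = float(min(1.0, max(0.0, c)))


@dataclass
class CloneTree:
    clusters: list  # MutationCluster, index = node id
    parent: dict  # node id -> parent id (root maps to None)
    root: int

    def children(self, node: int) -> list[int]:
        return [i for i, p in self.parent.items() if p == node]

    def ancestors(self, node: int) -> list[int]:
        out = []
        p = self.parent[node]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out

    def timepoints(self) -> list[str]:
        return list(self.clusters[self.root].ccf.keys())

    def ccf(self, node: int, tp: str) -> float:
        return self.clusters[node].ccf.get(tp, 0.0)

    def exclusive_prevalence(self, node: int, tp: str) -> float:
        """Clone-exclusive prevalence: own CCF minus the CCF carried by
        descendants (stacked-proportion semantics)."""
        v = self.ccf(node, tp) - sum(self.ccf(c, tp) for c in self.children(node))
        return max(0.0, v)

    def topology(self) -> tuple:
        return tuple(self.parent[i] for i in range(len(self.clusters)))

    def check_sum_rule(self, eps: float = 0.05) -> bool:
        for node in range(len(self.clusters)):
            kids = self.children(node)
            for tp in self.timepoints():
                if sum(self.ccf(k, tp) for k in kids) > self.ccf(node, tp) + eps:
                    return False
        return True


@dataclass
class TrajectoryCall:
    patient: str
    interval: str
    label: str
    probability_score: float | None = None
    evidence: dict = field(default_factory=dict)
    reason: str | None = None

    def __post_init__(self):
        if self.label == UNDETERMINED and not self.reason:
            raise ValueError("undetermined calls must record a reason")


# ---------------------------------------------------------------------------
# VAF clustering (binomial mixture + BIC)
# ---------------------------------------------------------------------------

@dataclass
class VafClusterResult:
    clusters: list  # MutationCluster
    assignments: dict  # variant key -> cluster id
    timepoints: list
    variant_ccfs: dict  # variant key -> per-timepoint observed CCF array
    bic_by_k: dict


def _em_binomial_mixture(alt, depth, theta_scale, K, rng, n_iter=200, tol=1e-8):
    """EM for a K-component binomial mixture over joint timepoints.

    theta_scale[t] = purity_t / 2 maps a CCF center to a binomial success
    probability.  Returns (loglik, centers K x T, responsibilities n x K).
    """
    n, T = alt.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_ccf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0) / theta_scale
    obs_ccf = np.clip(obs_ccf, 0.0, 1.0)
    # init centers from random data points
    idx = rng.choice(n, size=K, replace=n < K)
    centers = obs_ccf[idx].copy()
    log_pi = np.full(K, -np.log(K))
    ll_prev = -np.inf
    resp = np.full((n, K), 1.0 / K)
    for _ in range(n_iter):
        theta = np.clip(centers * theta_scale, 1e-6, 1 - 1e-6)  # K x T
        logp = np.zeros((n, K))
        for k in range(K):
            logp[:, k] = binom.logpmf(alt, depth, theta[k][None, :]).sum(axis=1)
        logp += log_pi[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        w = resp.sum(axis=0)
        log_pi = np.log(np.maximum(w / n, 1e-12))
        num = resp.T @ alt  # K x T
        den = resp.T @ depth
        centers = np.clip(
            np.where(den > 0, num / np.maximum(den, 1e-12), centers * theta_scale)
            / theta_scale,
            0.0,
            1.0,
        )
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return ll_prev, centers, resp


def cluster_vafs(
    variant_counts: Mapping,
    purities: Mapping[str, float],
    max_clusters: int = 10,
    min_cluster_size: int = 5,
    seed: int = 0,
    n_init: int = 3,
) -> VafClusterResult:
    """Cluster variants on their joint multi-timepoint CCFs.

    ``variant_counts`` maps a variant key to {timepoint: (alt_count, depth)}
    and must cover at least two timepoints.  The component count is chosen by
    BIC over 1..max_clusters; clusters smaller than ``min_cluster_size`` are
    merged into the nearest surviving cluster.
    """
    timepoints = sorted(
        {tp for counts in variant_counts.values() for tp in counts},
        key=lambda t: (t != DIAGNOSIS, t),
    )
    if len(timepoints) < 2:
        raise ValueError("clustering requires at least two timepoints")
    keys = list(variant_counts.keys())
    n, T = len(keys), len(timepoints)
    alt = np.zeros((n, T))
    depth = np.zeros((n, T))
    for i, k in enumerate(keys):
        for j, tp in enumerate(timepoints):
            a, d = variant_counts[k].get(tp, (0, 0))
            alt[i, j], depth[i, j] = a, d
    theta_scale = np.array([purities[tp] / 2.0 for tp in timepoints])

    rng = np.random.default_rng(seed)
    best = None
    bic_by_k = {}
    for K in range(1, min(max_clusters, n) + 1):
        best_k = None
        for _ in range(n_init):
            ll, centers, resp = _em_binomial_mixture(alt, depth, theta_scale, K, rng)
            if best_k is None or ll > best_k[0]:
                best_k = (ll, centers, resp)
        ll, centers, resp = best_k
        n_params = K * T + (K - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        bic_by_k[K] = bic
        if best is None or bic < best[0]:
            best = (bic, K, centers, resp)

    _, K, centers, resp = best
    labels = resp.argmax(axis=1)

    # merge undersized clusters into the nearest surviving center
    while True:
        sizes = np.bincount(labels, minlength=K)
        small = [k for k in range(K) if 0 < sizes[k] < min_cluster_size]
        keep = [k for k in range(K) if sizes[k] >= min_cluster_size]
        if not small or not keep:
            break
        k = small[0]
        tgt = min(keep, key=lambda j: float(np.sum((centers[j] - centers[k]) ** 2)))
        labels[labels == k] = tgt
        with np.errstate(invalid="ignore"):
            mask = labels == tgt
            num = alt[mask].sum(axis=0)
            den = depth[mask].sum(axis=0)
            centers[tgt] = np.clip(
                np.where(den > 0, num / np.maximum(den, 1e-12), 0.0) / theta_scale, 0, 1
            )

    used = sorted(set(labels.tolist()))
    remap = {old: new for new, old in enumerate(used)}
    clusters = []
    for old in used:
        mask = labels == old
        num = alt[mask].sum(axis=0)
        den = depth[mask].sum(axis=0)
        ccf = np.clip(
            np.where(den > 0, num / np.maximum(den, 1e-12), 0.0) / theta_scale, 0, 1
        )
        clusters.append(
            MutationCluster(
                remap[old],
                int(mask.sum()),
                {tp: float(ccf[j]) for j, tp in enumerate(timepoints)},
            )
        )
    assignments = {k: remap[labels[i]] for i, k in enumerate(keys)}
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0) / theta_scale
    variant_ccfs = {k: np.clip(obs[i], 0, 1) for i, k in enumerate(keys)}
    return VafClusterResult(clusters, assignments, timepoints, variant_ccfs, bic_by_k)


# ---------------------------------------------------------------------------
# Clone-tree enumeration
# ---------------------------------------------------------------------------

def _pick_root(clusters: Sequence[MutationCluster]) -> int:
    tps = list(clusters[0].ccf.keys())
    dominant = [
        i
        for i, c in enumerate(clusters)
        if all(
            c.ccf.get(tp, 0) >= max(o.ccf.get(tp, 0) for o in clusters) - 1e-12
            for tp in tps
        )
    ]
    if dominant:
        return dominant[0]
    return max(
        range(len(clusters)),
        key=lambda i: (sum(clusters[i].ccf.values()), clusters[i].n_variants),
    )


def enumerate_trees(
    clusters: Sequence[MutationCluster], eps: float = 0.05, root: int | None = None
) -> list[tuple]:
    """All sum-rule-consistent rooted trees over the clusters.

    Returned as parent tuples (index -> parent index, root -> None), in
    lexicographic order (None sorts first).  Branch-and-bound: a parent must
    cover each child's CCF at every timepoint within eps (edge feasibility)
    and partial children sums are pruned as they grow.
    """
    K = len(clusters)
    if root is None:
        root = _pick_root(clusters)
    if K == 1:
        return [(None,)]
    tps = list(clusters[root].ccf.keys())
    nodes = [i for i in range(K) if i != root]

    feasible = {
        i: [
            j
            for j in range(K)
            if j != i
            and all(
                clusters[j].ccf.get(tp, 0) >= clusters[i].ccf.get(tp, 0) - eps
                for tp in tps
            )
        ]
        for i in nodes
    }
    if any(not f for f in feasible.values()):
        return []

    results = []
    parent = [None] * K
    child_sum = {j: {tp: 0.0 for tp in tps} for j in range(K)}

    def creates_cycle(i, j):
        seen = {i}
        while j is not None:
            if j in seen:
                return True
            seen.add(j)
            j = parent[j]
        return False

    def rec(pos: int):
        if pos == len(nodes):
            results.append(tuple(parent))
            return
        i = nodes[pos]
        for j in sorted(feasible[i]):
            if creates_cycle(i, j):
                continue
            ok = True
            for tp in tps:
                if (
                    child_sum[j][tp] + clusters[i].ccf.get(tp, 0)
                    > clusters[j].ccf.get(tp, 0) + eps
                ):
                    ok = False
                    break
            if not ok:
                continue
            parent[i] = j
            for tp in tps:
                child_sum[j][tp] += clusters[i].ccf.get(tp, 0)
            rec(pos + 1)
            for tp in tps:
                child_sum[j][tp] -= clusters[i].ccf.get(tp, 0)
            parent[i] = None
        return

    rec(0)
    results.sort(key=lambda t: tuple(-1 if p is None else p for p in t))
    return results


def _best_topology(clusters, eps, root):
    trees = enumerate_trees(clusters, eps=eps, root=root)
    return trees[0] if trees else None


@dataclass
class TreeResult:
    tree: CloneTree | None
    probability_score: float
    n_valid_trees: int


def build_clone_tree(
    clusters: Sequence[MutationCluster],
    eps: float = 0.05,
    assignments: Mapping | None = None,
    variant_ccfs: Mapping | None = None,
    n_resamples: int = 100,
    seed: int = 0,
) -> TreeResult:
    """Consensus clone tree with a bootstrap stability score.

    The point tree is the lexicographically first sum-rule-consistent
    topology on the full data (root = dominant cluster).  When per-variant
    CCFs and assignments are given, variant-to-cluster bootstrap resampling
    re-estimates cluster centers ``n_resamples`` times; the consensus is the
    modal best topology and the probability score its frequency.  With no
    consistent tree on the full data the result is empty (feeds an
    undetermined trajectory).
    """
    if len(clusters) > 11:
        raise ValueError("tree enumeration supports at most 11 clusters")
    clusters = list(clusters)
    root = _pick_root(clusters)
    topo = _best_topology(clusters, eps, root)
    n_valid = len(enumerate_trees(clusters, eps=eps, root=root))
    if topo is None:
        return TreeResult(None, 0.0, 0)
    if len(clusters) == 1:
        tree = CloneTree(clusters, {0: None}, 0)
        return TreeResult(tree, 1.0, 1)

    score = 1.0
    if assignments is not None and variant_ccfs is not None and n_resamples > 0:
        rng = np.random.default_rng(seed)
        keys = list(assignments.keys())
        tps = list(clusters[0].ccf.keys())
        members = {c.cluster_id: [] for c in clusters}
        for k in keys:
            members[assignments[k]].append(np.asarray(variant_ccfs[k], dtype=float))
        counts = {}
        for _ in range(n_resamples):
            boot = []
            for c in clusters:
                mem = members[c.cluster_id]
                if mem:
                    pick = rng.integers(0, len(mem), size=len(mem))
                    center = np.mean([mem[p] for p in pick], axis=0)
                    ccf = {tp: float(np.clip(center[j], 0, 1)) for j, tp in enumerate(tps)}
                else:
                    ccf = dict(c.ccf)
                boot.append(MutationCluster(c.cluster_id, c.n_variants, ccf))
            t = _best_topology(boot, eps, root)
            counts[t] = counts.get(t, 0) + 1
        consensus, freq = max(
            counts.items(), key=lambda kv: (kv[1], kv[0] is not None)
        )
        if consensus is not None:
            topo = consensus
        score = freq / n_resamples

    parent = {i: topo[i] for i in range(len(clusters))}
    return TreeResult(CloneTree(clusters, parent, root), score, n_valid)


# ---------------------------------------------------------------------------
# Trajectory classification
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryThresholds:
    present: float = 0.05
    purity_min: float = 0.2


def _major_clone(tree: CloneTree, tp: str, present: float) -> int | None:
    candidates = [
        i
        for i in range(len(tree.clusters))
        if tree.exclusive_prevalence(i, tp) >= present
    ]
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda i: (tree.exclusive_prevalence(i, tp), tree.clusters[i].n_variants),
    )


def classify_trajectory(
    tree: CloneTree | None,
    patient: str = "",
    baseline_tp: str = DIAGNOSIS,
    relapse_tp: str = R1,
    relapse_purity: float | None = None,
    thresholds: TrajectoryThresholds | None = None,
    probability_score: float | None = None,
    assignments: Mapping | None = None,
) -> TrajectoryCall:
    """Classify one baseline->relapse interval.

    Let M_D and M_R be the major clones (by clone-exclusive prevalence) at
    baseline and relapse, and A the nearest ancestor-or-self of M_R whose
    CCF at baseline reaches the presence threshold.  The label is persistent
    when A is M_D (this subsumes the founding-clone-as-major override),
    founding when A is the founding clone (or no non-root ancestor is
    present at baseline), and rising when A is a present, non-major baseline
    subclone.  Low relapse purity or a missing tree yields undetermined.
    """
    th = thresholds or TrajectoryThresholds()
    interval = f"{baseline_tp}->{relapse_tp}"
    if relapse_purity is not None and relapse_purity < th.purity_min:
        return TrajectoryCall(
            patient, interval, UNDETERMINED, probability_score, reason="low purity"
        )
    if tree is None:
        return TrajectoryCall(
            patient, interval, UNDETERMINED, probability_score, reason="no consistent tree"
        )
    m_d = _major_clone(tree, baseline_tp, th.present)
    m_r = _major_clone(tree, relapse_tp, th.present)
    if m_d is None or m_r is None:
        return TrajectoryCall(
            patient,
            interval,
            UNDETERMINED,
            probability_score,
            reason="no clone present above threshold",
        )
    lineage = [m_r] + tree.ancestors(m_r)
    anchor = next(
        (n for n in lineage if tree.ccf(n, baseline_tp) >= th.present), tree.root
    )
    if anchor == m_d:
        label = PERSISTENT
    elif anchor == tree.root:
        label = FOUNDING
    else:
        label = RISING
    relapse_lineage = [n for n in lineage if tree.ccf(n, baseline_tp) < th.present]
    evidence = {
        "major_baseline": m_d,
        "major_relapse": m_r,
        "anchor": anchor,
        "baseline_prevalence": tree.exclusive_prevalence(m_d, baseline_tp),
        "relapse_prevalence": tree.exclusive_prevalence(m_r, relapse_tp),
        "relapse_lineage_clusters": relapse_lineage,
    }
    if assignments is not None:
        evidence["relapse_lineage_variants"] = sorted(
            k for k, cl in assignments.items() if cl in relapse_lineage
        )
    return TrajectoryCall(patient, interval, label, probability_score, evidence)


def reassign_with_deep_sequencing(
    call: TrajectoryCall,
    deep_afs: Mapping,
    af_detect: float = 0.01,
) -> TrajectoryCall:
    """Promote a founding call to rising when deep resequencing detects a
    relapse-lineage variant in the baseline sample."""
    if call.label != FOUNDING:
        raise ValueError("reassignment applies to founding calls only")
    lineage = call.evidence.get("relapse_lineage_variants")
    keys = lineage if lineage else list(deep_afs.keys())
    detected = {k: deep_afs[k] for k in keys if k in deep_afs and deep_afs[k] >= af_detect}
    if not detected:
        return call
    evidence = dict(call.evidence)
    evidence["deep_sequencing_detected"] = detected
    return TrajectoryCall(
        call.patient, call.interval, RISING, call.probability_score, evidence
    )


def relapse_to_relapse_trajectory(
    tree: CloneTree,
    patient: str = "",
    relapse_purity: float | None = None,
    thresholds: TrajectoryThresholds | None = None,
    probability_score: float | None = None,
) -> TrajectoryCall:
    """Classify the first->second relapse interval with r1 as baseline."""
    if tree is None or R2 not in tree.timepoints():
        raise ValueError("no second-relapse data available")
    return classify_trajectory(
        tree,
        patient=patient,
        baseline_tp=R1,
        relapse_tp=R2,
        relapse_purity=relapse_purity,
        thresholds=thresholds,
        probability_score=probability_score,
    )
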