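"""96-channel mutation catalogs, de novo NMF signature extraction, reference
matching and parsimonious signature-set selection.

The catalog layout is the canonical pyrimidine-centric 96-channel order
(A[C>A]A ... T[T>G]T).  De novo extraction uses Frobenius-loss NMF with
multiplicative updates and multiple random restarts; the factorization rank
is chosen by a residual-sum-of-squares elbow.  Reference selection proceeds
in stages — best match per de novo signature, then dendrogram-branch
neighbours, then next-best candidates until two per de novo signature —
stopping at the first stage whose per-sample reconstruction cosines are
statistically equivalent (paired t-test) to the de novo baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import ttest_rel
from sklearn.decomposition import NMF

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: canonical channel order: substitution-major, then 5' flank, then 3' flank
CHANNELS96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS96)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def channel_of(five: str, ref: str, alt: str, three: str) -> str:
    """Map a flanked substitution to its pyrimidine-centric channel."""
    if ref in "AG":
        five, three = _revcomp(three), _revcomp(five)
        ref, alt = _revcomp(ref), _revcomp(alt)
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class MutationCatalog:
    """Per-sample 96-channel substitution counts (samples x 96)."""

    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError("catalog must be samples x 96")
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def burdens(self) -> np.ndarray:
        return self.counts.sum(axis=1)


DE_NOVO = "de_novo"
REFERENCE = "reference"


@dataclass
class SignatureSet:
    """Column-stochastic 96 x K signature matrix with labels."""

    labels: list
    matrix: np.ndarray
    provenance: str = REFERENCE

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("signature matrix must be 96 x K")
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("labels length mismatch")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("signature columns must sum to 1 within 1e-9")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "SignatureSet":
        idx = [self.labels.index(l) for l in labels]
        return SignatureSet(list(labels), self.matrix[:, idx], self.provenance)


@dataclass
class ExposureMatrix:
    """Non-negative per-sample signature contributions (mutation counts)."""

    sample_ids: list
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("exposures must be non-negative")

    def fractions(self) -> np.ndarray:
        totals = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.values / totals, 0.0)
        return out


def read_signature_tsv(path, provenance: str = REFERENCE) -> SignatureSet:
    """Read a COSMIC-layout TSV: first column channel labels, one column per
    signature; rows may be in any channel order."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS96) - set(df.index)
    if missing:
        raise ValueError(f"signature TSV missing channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CHANNELS96)]
    mat = df.to_numpy(dtype=float)
    mat = mat / mat.sum(axis=0, keepdims=True)
    return SignatureSet(list(df.columns), mat, provenance)


def write_signature_tsv(path, sigs: SignatureSet):
    import pandas as pd

    pd.DataFrame(sigs.matrix, index=list(CHANNELS96), columns=sigs.labels).to_csv(
        path, sep="\t", index_label="channel"
    )
    return path


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

def build_catalog(variants, reference) -> MutationCatalog:
    """Count SNVs into 96 channels per sample; indels are ignored.

    ``reference`` maps chromosome -> sequence.  A mismatch between the
    variant's ref allele and the reference base is an error.
    """
    per_sample: dict[str, np.ndarray] = {}
    order: list[str] = []
    for v in variants:
        if v.var_class != "SNV":
            continue
        seq = reference[v.interval.chrom]
        pos = v.interval.start
        if seq[pos] != v.ref_allele:
            raise ValueError(
                f"reference mismatch at {v.interval.chrom}:{pos}: "
                f"ref={seq[pos]} variant={v.ref_allele}"
            )
        if pos == 0 or pos + 1 >= len(seq):
            raise ValueError(f"variant at sequence edge: {v.interval.chrom}:{pos}")
        ch = channel_of(seq[pos - 1], v.ref_allele, v.alt_allele, seq[pos + 1])
        if v.sample_id not in per_sample:
            per_sample[v.sample_id] = np.zeros(96, dtype=int)
            order.append(v.sample_id)
        per_sample[v.sample_id][_CHANNEL_INDEX[ch]] += 1
    if not order:
        return MutationCatalog([], np.zeros((0, 96), dtype=int))
    return MutationCatalog(order, np.vstack([per_sample[s] for s in order]))


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# De novo extraction
# ---------------------------------------------------------------------------

@dataclass
class DeNovoResult:
    signatures: SignatureSet
    exposures: ExposureMatrix
    rss_by_rank: dict
    rank: int


def _best_nmf(X: np.ndarray, rank: int, n_restarts: int, rng: np.random.Generator):
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    best = None
    for _ in range(n_restarts):
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=2000,
            tol=1e-6,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)  # samples x rank
        H = model.components_  # rank x 96
        rss = float(np.sum((X - W @ H) ** 2))
        if best is None or rss < best[0]:
            best = (rss, W, H)
    return best


def extract_de_novo(
    catalog: MutationCatalog,
    rank_range=range(2, 6),
    n_restarts: int = 50,
    seed: int = 0,
    elbow_threshold: float = 0.2,
) -> DeNovoResult:
    """NMF extraction with RSS-based rank selection.

    The best restart (lowest RSS) is kept at each rank.  Walking up the rank
    range, the first rank whose relative RSS improvement over the previous
    rank drops below ``elbow_threshold`` ends the search and the previous
    rank is selected; if improvements never flatten, the largest rank wins.
    """
    X = catalog.counts.astype(float)
    if X.size == 0 or X.sum() == 0:
        raise ValueError("catalog is empty or all-zero")
    ranks = sorted(rank_range)
    if ranks[0] < 2 or ranks[-1] > max(2, catalog.n_samples - 1):
        raise ValueError(f"rank range {ranks} outside [2, n_samples-1]")
    rng = np.random.default_rng(seed)
    fits = {}
    rss_by_rank = {}
    selected = ranks[-1]
    prev_rss = None
    for r in ranks:
        rss, W, H = _best_nmf(X, r, n_restarts, rng)
        fits[r] = (W, H)
        rss_by_rank[r] = rss
        if prev_rss is not None and prev_rss > 0:
            improvement = (prev_rss - rss) / prev_rss
            if improvement < elbow_threshold:
                selected = r - 1
                break
        prev_rss = rss
    W, H = fits[selected]
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    S = (H / scale[:, None]).T  # 96 x K column-stochastic
    E = W * scale[None, :]
    labels = [f"DN{i + 1}" for i in range(selected)]
    return DeNovoResult(
        SignatureSet(labels, S, DE_NOVO),
        ExposureMatrix(list(catalog.sample_ids), labels, E),
        rss_by_rank,
        selected,
    )


# ---------------------------------------------------------------------------
# Reference matching and refitting
# ---------------------------------------------------------------------------

def match_to_reference(
    de_novo: SignatureSet, reference: SignatureSet, threshold: float = 0.65
):
    """Reference signatures with cosine > threshold to any de novo signature.

    Returns (candidate labels in reference order, full de-novo x reference
    cosine table).
    """
    table = np.zeros((de_novo.k, reference.k))
    for i in range(de_novo.k):
        for j in range(reference.k):
            table[i, j] = cosine_similarity(de_novo.matrix[:, i], reference.matrix[:, j])
    candidates = [
        reference.labels[j] for j in range(reference.k) if (table[:, j] > threshold).any()
    ]
    return candidates, table


def refit_exposures(
    catalog: MutationCatalog, signatures: SignatureSet
) -> tuple[ExposureMatrix, np.ndarray]:
    """Per-sample NNLS refit of counts on a fixed signature matrix.

    Returns exposures and the per-sample cosine between the observed and
    reconstructed 96-channel profiles (0 for empty samples).
    """
    S = signatures.matrix
    n = catalog.n_samples
    E = np.zeros((n, signatures.k))
    cosines = np.zeros(n)
    for i in range(n):
        y = catalog.counts[i].astype(float)
        if y.sum() == 0:
            continue
        x, _ = nnls(S, y)
        E[i] = x
        recon = S @ x
        cosines[i] = cosine_similarity(y, recon) if recon.any() else 0.0
    return ExposureMatrix(list(catalog.sample_ids), list(signatures.labels), E), cosines


# ---------------------------------------------------------------------------
# Parsimonious selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStage:
    name: str
    labels: list
    cosines: np.ndarray
    median_cosine: float
    p_value: float
    accepted: bool
    notes: str = ""


@dataclass
class SelectionTrace:
    baseline_cosines: np.ndarray
    baseline_median: float
    stages: list = field(default_factory=list)


def _paired_p(cosines: np.ndarray, baseline: np.ndarray) -> float:
    diffs = cosines - baseline
    if np.allclose(diffs, diffs[0] if diffs.size else 0.0):
        # zero-variance differences: reconstructions are equivalent (or
        # uniformly shifted); t-test is undefined, treat identical as p=1
        return 1.0 if np.allclose(diffs, 0.0) else 0.0
    res = ttest_rel(cosines, baseline)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _branch_members(cand_labels: list, dist: np.ndarray, anchor: str) -> list:
    """Members of the smallest average-linkage cluster containing ``anchor``
    with at least two members."""
    if len(cand_labels) < 2:
        return list(cand_labels)
    Z = linkage(squareform(dist, checks=False), method="average")
    n = len(cand_labels)
    clusters = {i: {i} for i in range(n)}
    a = cand_labels.index(anchor)
    for row in range(Z.shape[0]):
        left, right = int(Z[row, 0]), int(Z[row, 1])
        merged = clusters[left] | clusters[right]
        clusters[n + row] = merged
        if a in merged:
            return [cand_labels[i] for i in sorted(merged)]
    return list(cand_labels)


def select_parsimonious_set(
    de_novo: SignatureSet,
    reference: SignatureSet,
    catalog: MutationCatalog,
    alpha: float = 0.05,
    threshold: float = 0.65,
    max_per_de_novo: int = 2,
) -> tuple[SelectionTrace, SignatureSet]:
    """Staged reduction of matched reference signatures to a parsimonious set.

    Stage 1 takes the best reference match per de novo signature; stage 2
    adds, per de novo signature, the most similar unselected candidate within
    its dendrogram branch (average linkage on 1 - cosine between candidates);
    later stages top up until ``max_per_de_novo`` candidates are attributed
    per de novo signature.  After each stage the catalog is refit and the
    per-sample reconstruction cosines compared to the de novo baseline by
    two-sided paired t-test; selection stops at the first stage with
    p > alpha.
    """
    candidates, table = match_to_reference(de_novo, reference, threshold)
    if not candidates:
        raise ValueError("no reference candidates exceed the matching threshold")
    _, baseline = refit_exposures(catalog, de_novo)
    trace = SelectionTrace(baseline, float(np.median(baseline)))

    cand_idx = {l: reference.labels.index(l) for l in candidates}
    # candidate pairwise distance for the dendrogram
    m = len(candidates)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            c = cosine_similarity(
                reference.matrix[:, cand_idx[candidates[i]]],
                reference.matrix[:, cand_idx[candidates[j]]],
            )
            dist[i, j] = dist[j, i] = 1.0 - c

    def cosine_to_dn(i_dn: int, label: str) -> float:
        return table[i_dn, reference.labels.index(label)]

    selected: list[str] = []
    attributed: dict[int, list[str]] = {i: [] for i in range(de_novo.k)}

    def add_for(i_dn: int, pool: list) -> str | None:
        avail = [l for l in pool if l not in selected]
        if not avail:
            return None
        # ties broken by label order
        best = max(avail, key=lambda l: (cosine_to_dn(i_dn, l), l))
        selected.append(best)
        attributed[i_dn].append(best)
        return best

    def evaluate(name: str, notes: str = "") -> SelectionStage:
        subset = reference.subset(sorted(selected, key=reference.labels.index))
        _, cosines = refit_exposures(catalog, subset)
        p = _paired_p(cosines, baseline)
        accepted = p > alpha or alpha >= 1.0  # degenerate alpha accepts any stage
        stage = SelectionStage(
            name, list(subset.labels), cosines, float(np.median(cosines)), p, accepted, notes
        )
        trace.stages.append(stage)
        return stage

    # stage 1: best match per de novo signature
    for i in range(de_novo.k):
        add_for(i, candidates)
    stage = evaluate("stage1_best_match")
    final = stage

    # stage 2: dendrogram-branch neighbour of each best match
    if not stage.accepted:
        for i in range(de_novo.k):
            if len(attributed[i]) >= max_per_de_novo or not attributed[i]:
                continue
            branch = _branch_members(candidates, dist, attributed[i][0])
            add_for(i, branch)
        stage = evaluate("stage2_branch_expansion")
        final = stage

    # further stages: next-best candidates until max_per_de_novo each
    stage_no = 3
    while not stage.accepted:
        added = 0
        for i in range(de_novo.k):
            while len(attributed[i]) < max_per_de_novo:
                if add_for(i, candidates) is None:
                    break
                added += 1
        if added == 0:
            trace.stages.append(
                SelectionStage(
                    f"stage{stage_no}_exhausted",
                    sorted(selected, key=reference.labels.index),
                    stage.cosines,
                    stage.median_cosine,
                    stage.p_value,
                    False,
                    notes="candidate pool exhausted before equivalence reached",
                )
            )
            break
        stage = evaluate(f"stage{stage_no}_top_up")
        final = stage
        stage_no += 1

    final_set = reference.subset(sorted(selected, key=reference.labels.index))
    return trace, final_set
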