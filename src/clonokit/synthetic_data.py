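"""Deterministic generators for every input the pipeline consumes.

Provides signature-mixture 96-channel catalogs, clone trees with
per-timepoint prevalences satisfying the sum rule by construction,
read-count-level variant tables (binomial sampling at Poisson depths),
artifact variants violating each downstream filter rule, and a toy
reference genome with planted homopolymers, repeats, gaps, regulatory
regions and population variants.

One global seed drives independent per-stage substreams, so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clonal_trajectories import (
    FOUNDING,
    PERSISTENT,
    RISING,
    CloneTree,
    MutationCluster,
)
from .core_model import (
    DIAGNOSIS,
    NON_SILENT,
    R1,
    R2,
    GenomicInterval,
    IntervalSet,
    SampleMeta,
    SomaticVariant,
    write_reference,
    write_regions,
    write_variants,
)
from .signature_analysis import REFERENCE, SignatureSet
from .variant_filters import (
    PopulationIndex,
    RULE_DEPTH,
    RULE_HOMOPOLYMER,
    RULE_LOW_AF,
    RULE_NEAR_INDEL,
    RULE_POPULATION,
    RULE_REPEAT,
    SNV_RULES,
)


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 10
    burden_range: tuple = (152, 1343)
    signature_weights: dict = field(default_factory=dict)
    clone_count_range: tuple = (2, 4)
    timepoints: tuple = (DIAGNOSIS, R1)
    depth_mean: float = 90.0
    purity_range: tuple = (0.4, 0.95)
    artifact_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.burden_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid burden_range {self.burden_range}")
        unknown = set(self.artifact_rates) - set(SNV_RULES)
        if unknown:
            raise ValueError(f"unknown artifact rule ids: {sorted(unknown)}")


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent, named RNG substream derived from the global seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Reference signatures and catalogs
# ---------------------------------------------------------------------------

def make_reference_signatures(
    n_signatures: int = 8, seed: int = 0, concentration: float = 0.08
) -> SignatureSet:
    """Sparse, well-separated synthetic reference signatures (96 x K)."""
    rng = substream(seed, "reference-signatures")
    cols = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    labels = [f"SIG{i + 1}" for i in range(n_signatures)]
    return SignatureSet(labels, cols, REFERENCE)


def simulate_catalogs(signatures: SignatureSet, config: SimConfig):
    """Draw per-sample 96-channel catalogs from a signature mixture.

    Each sample's total burden is uniform over ``burden_range`` and its
    96-vector multinomial with probabilities = signature matrix x mixing
    weights.  ``signature_weights`` maps signature label to either a scalar
    (shared across samples) or a length-``n_samples`` sequence.  Returns
    (counts matrix samples x 96, true exposure fractions samples x K,
    burdens).
    """
    rng = substream(config.seed, "catalogs")
    n = config.n_samples
    labels = list(config.signature_weights.keys())
    if not labels:
        raise ValueError("signature_weights must name at least one signature")
    W = np.zeros((n, len(labels)))
    for j, lab in enumerate(labels):
        w = config.signature_weights[lab]
        W[:, j] = np.full(n, float(w)) if np.isscalar(w) else np.asarray(w, dtype=float)
    sums = W.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("per-sample mixing proportions must sum to 1 within 1e-9")
    S = np.column_stack([signatures.column(lab) for lab in labels])  # 96 x K
    lo, hi = config.burden_range
    burdens = rng.integers(lo, hi + 1, size=n)
    counts = np.zeros((n, 96), dtype=int)
    for i in range(n):
        probs = S @ W[i]
        probs = probs / probs.sum()
        if burdens[i] > 0:
            counts[i] = rng.multinomial(burdens[i], probs)
    return counts, W, burdens


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------

def _u(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def simulate_clone_tree(
    config: SimConfig, trajectory: str = PERSISTENT
) -> tuple[CloneTree, list[int]]:
    """Build a rooted clone tree whose prevalences realize the requested
    trajectory; the sum rule holds exactly by construction.

    The CCF patterns are chosen so that the sum rule makes the planted
    topology the unique consistent one (sibling placements overflow the
    parent at some timepoint, nested placements invert an inequality).
    Returns the tree and per-clone mutation-cluster sizes.
    """
    rng = substream(config.seed, f"clone-tree-{trajectory}")
    tps = list(config.timepoints)
    if DIAGNOSIS not in tps or len(tps) < 2:
        raise ValueError("timepoints must include diagnosis and at least one relapse")
    want_r2 = R2 in tps
    lo_k, hi_k = config.clone_count_range
    if trajectory == RISING and hi_k < 4:
        raise ValueError("rising trajectory needs at least 4 clones")
    if hi_k < 3:
        raise ValueError("trajectory simulation needs at least 3 clones")

    def ccf(d, r1, r2=None):
        out = {DIAGNOSIS: d, R1: r1}
        if want_r2:
            out[R2] = r2 if r2 is not None else r1
        return out

    clusters: list[MutationCluster] = []
    parent: dict[int, int | None] = {}

    def add(ccfs, par):
        cid = len(clusters)
        clusters.append(MutationCluster(cid, 0, ccfs))
        parent[cid] = par
        return cid

    root = add(ccf(1.0, 1.0, 1.0), None)
    if trajectory == PERSISTENT:
        a_d, a_r = _u(rng, 0.6, 0.8), _u(rng, 0.85, 0.95)
        b_r = _u(rng, 0.55, a_r - 0.1)
        a = add(ccf(a_d, a_r), root)
        b = add(ccf(0.0, b_r), a)
        relapse_major = b
    elif trajectory == RISING:
        a_d, a_r = _u(rng, 0.55, 0.7), _u(rng, 0.0, 0.03)
        b_d = _u(rng, 0.1, min(0.3, 0.95 - a_d))
        b_r = _u(rng, 0.9, 0.96)
        c_r = _u(rng, max(0.6, b_r / 2 + 0.12), b_r - 0.05)
        a = add(ccf(a_d, a_r), root)
        b = add(ccf(b_d, b_r), root)
        c = add(ccf(0.0, c_r), b)
        relapse_major = c
    elif trajectory == FOUNDING:
        a_d = _u(rng, 0.6, 0.85)
        b_r = _u(rng, 0.7, 0.95)
        a = add(ccf(a_d, _u(rng, 0.0, 0.03)), root)
        b = add(ccf(0.0, b_r), root)
        relapse_major = b
    else:
        raise ValueError(f"cannot target trajectory {trajectory!r}")

    if want_r2:
        # second relapse repeats the r1 pattern and adds a fresh subclone on
        # the relapse-major lineage, so r1 -> r2 is persistent
        pm = clusters[relapse_major].ccf[R1]
        add({DIAGNOSIS: 0.0, R1: 0.0, R2: _u(rng, 0.35, max(0.4, pm - 0.1))}, relapse_major)

    sizes = [int(rng.integers(80, 160)) for _ in clusters]
    for c, s in zip(clusters, sizes):
        c.n_variants = s
    return CloneTree(clusters, parent, root), sizes


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    variants_by_timepoint: dict  # timepoint -> list[SomaticVariant]
    variant_counts: dict  # key -> {timepoint: (alt, depth)}
    truth_clone: dict  # key -> clone id
    purities: dict  # timepoint -> purity


def simulate_variant_reads(
    tree: CloneTree,
    config: SimConfig,
    purities: Mapping[str, float] | None = None,
    patient_id: str = "SIM",
    reference: Mapping[str, str] | None = None,
    clean_positions: Sequence[tuple] | None = None,
) -> SimulatedReads:
    """Sample read counts for every clone's mutations at every timepoint.

    Expected AF = purity x CCF / 2 (diploid copy-neutral); per-variant depth
    is Poisson(depth_mean) and the alt count binomial.  Variants are placed
    on a virtual chromosome unless reference positions are supplied.
    """
    rng = substream(config.seed, f"reads-{patient_id}")
    tps = tree.timepoints()
    if purities is None:
        purities = {
            tp: _u(rng, *config.purity_range) for tp in tps
        }
    variants_by_tp: dict[str, list] = {tp: [] for tp in tps}
    variant_counts: dict = {}
    truth: dict = {}
    pos_iter = iter(clean_positions) if clean_positions is not None else None
    cursor = 1000
    for clone in tree.clusters:
        for _ in range(clone.n_variants):
            if pos_iter is not None:
                chrom, pos = next(pos_iter)
                ref = reference[chrom][pos]
                alt = {"A": "T", "C": "A", "G": "C", "T": "G"}[ref]
            else:
                chrom, pos, ref, alt = "chrV", cursor, "A", "T"
                cursor += 10
            key = (chrom, pos, ref, alt)
            truth[key] = clone.cluster_id
            counts = {}
            for tp in tps:
                depth = int(rng.poisson(config.depth_mean))
                p = purities[tp] * clone.ccf.get(tp, 0.0) / 2.0
                alt_n = int(rng.binomial(depth, p)) if depth > 0 else 0
                counts[tp] = (alt_n, depth)
                variants_by_tp[tp].append(
                    SomaticVariant(
                        patient_id=patient_id,
                        sample_id=f"{patient_id}_{tp}",
                        timepoint=tp,
                        interval=GenomicInterval(chrom, pos, pos + 1),
                        ref_allele=ref,
                        alt_allele=alt,
                        var_class="SNV",
                        tumor_depth=depth,
                        alt_count=alt_n,
                        af=alt_n / depth if depth > 0 else 0.0,
                        germline_depth=30,
                    )
                )
            variant_counts[key] = counts
    return SimulatedReads(variants_by_tp, variant_counts, truth, dict(purities))


# ---------------------------------------------------------------------------
# Toy reference genome with planted features
# ---------------------------------------------------------------------------

_CHROM_LENGTHS = {"chrS1": 60_000, "chrS2": 40_000}
_PLANTED_RUNS = {  # chrom -> list of (start, length, base)
    "chrS1": [(5_000, 10, "A"), (15_000, 8, "G"), (25_000, 7, "T")],
    "chrS2": [(8_000, 12, "T")],
}
_REPEATS = [("chrS1", 30_000, 31_000), ("chrS2", 12_000, 12_500)]
_GAPS = [("chrS1", 40_000, 42_000), ("chrS2", 20_000, 20_500)]
_REGULATORY = [
    ("chrS1", 2_000, 2_600, "H3K27ac"),
    ("chrS1", 10_000, 10_400, "H3K4me3"),
    ("chrS1", 34_000, 34_800, "H3K4me1"),
    ("chrS2", 5_000, 5_600, "DNase1"),
    ("chrS2", 25_000, 25_400, "TFBS"),
]
_CONSERVED = [("chrS1", 2_100, 2_300)]
_POPULATION_POSITIONS = {
    "chrS1": [1_234, 3_456, 7_890, 18_000, 22_222],
    "chrS2": [1_500, 9_999, 30_303],
}


@dataclass
class ToyAnnotations:
    repeats: list
    gaps: list
    regulatory: list
    conserved: list
    population: PopulationIndex
    population_records: list
    chrom_means: dict

    def repeat_index(self) -> IntervalSet:
        return IntervalSet(self.repeats)

    def gap_index(self) -> IntervalSet:
        return IntervalSet(self.gaps)

    def regulatory_index(self) -> IntervalSet:
        return IntervalSet(self.regulatory)

    def conserved_index(self) -> IntervalSet:
        return IntervalSet(self.conserved)


def build_toy_reference(seed: int = 0) -> tuple[dict, ToyAnnotations]:
    """~100 kb over two synthetic chromosomes.

    The random backbone never repeats a base more than three times, so the
    only homopolymers of filterable length are the planted ones.
    """
    rng = substream(seed, "toy-reference")
    bases = np.array(list("ACGT"))
    chroms = {}
    for name, length in _CHROM_LENGTHS.items():
        seq = []
        run = 0
        prev = None
        draws = rng.integers(0, 4, size=length * 2)
        di = 0
        while len(seq) < length:
            b = bases[draws[di] % 4]
            di += 1
            if b == prev:
                if run >= 3:
                    continue
                run += 1
            else:
                prev, run = b, 1
            seq.append(b)
        s = "".join(seq)
        for start, ln, base in _PLANTED_RUNS.get(name, []):
            s = s[:start] + base * ln + s[start + ln :]
        chroms[name] = s
    repeats = [GenomicInterval(c, a, b, label="repeat") for c, a, b in _REPEATS]
    gaps = [GenomicInterval(c, a, b, label="gap") for c, a, b in _GAPS]
    regulatory = [GenomicInterval(c, a, b, label=l) for c, a, b, l in _REGULATORY]
    conserved = [GenomicInterval(c, a, b, label="phastcons") for c, a, b in _CONSERVED]
    pop_records = []
    for chrom, positions in _POPULATION_POSITIONS.items():
        for p in positions:
            ref = chroms[chrom][p]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            pop_records.append((chrom, p, ref, alt))
    ann = ToyAnnotations(
        repeats=repeats,
        gaps=gaps,
        regulatory=regulatory,
        conserved=conserved,
        population=PopulationIndex(records=pop_records),
        population_records=pop_records,
        chrom_means={c: 30.0 for c in chroms},
    )
    return chroms, ann


def _planted_blacklist(ann: ToyAnnotations, pad: int = 10) -> dict[str, set]:
    bad: dict[str, set] = {c: set() for c in _CHROM_LENGTHS}
    for chrom, runs in _PLANTED_RUNS.items():
        for start, ln, _ in runs:
            bad[chrom].update(range(start - pad, start + ln + pad))
    for iv in ann.repeats + ann.gaps:
        bad[iv.chrom].update(range(iv.start - 6, iv.end + 6))
    for chrom, pos, _, _ in ann.population_records:
        bad[chrom].update(range(pos - 6, pos + 7))
    return bad


def sample_clean_positions(
    n: int,
    ann: ToyAnnotations,
    rng: np.random.Generator,
    spacing: int = 12,
    avoid: Sequence[tuple] = (),
) -> list[tuple]:
    """Positions guaranteed to violate no annotation-based filter rule.

    ``avoid`` pre-seeds already-occupied (chrom, pos) sites so new positions
    keep their distance from existing variants as well.
    """
    bad = _planted_blacklist(ann)
    taken: dict[str, set] = {c: set() for c in _CHROM_LENGTHS}
    for chrom, pos in avoid:
        taken.setdefault(chrom, set()).add(pos)
    out = []
    chrom_names = sorted(_CHROM_LENGTHS)
    while len(out) < n:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(50, _CHROM_LENGTHS[chrom] - 50))
        if pos in bad[chrom]:
            continue
        if any((pos + d) in taken[chrom] for d in range(-spacing, spacing + 1)):
            continue
        taken[chrom].add(pos)
        out.append((chrom, pos))
    return out


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def _mk_variant(
    patient_id, timepoint, chrom, pos, ref, alt, depth, alt_n, gdp=30, fclass=NON_SILENT
):
    return SomaticVariant(
        patient_id=patient_id,
        sample_id=f"{patient_id}_{timepoint}",
        timepoint=timepoint,
        interval=GenomicInterval(chrom, pos, pos + len(ref)),
        ref_allele=ref,
        alt_allele=alt,
        var_class="SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
        tumor_depth=depth,
        alt_count=alt_n,
        af=alt_n / depth if depth else 0.0,
        germline_depth=gdp,
        functional_class=fclass,
    )


def _other_base(b: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


def inject_artifacts(
    variants: Sequence[SomaticVariant],
    reference: Mapping[str, str],
    ann: ToyAnnotations,
    config: SimConfig,
    patient_id: str = "SIM",
    timepoint: str = DIAGNOSIS,
):
    """Append variants violating exactly the requested rules.

    ``config.artifact_rates`` maps rule id to the number of violators to
    add.  Returns (augmented variant list, truth mapping variant key ->
    rule id or "clean").
    """
    rng = substream(config.seed, "artifacts")
    truth = {v.key: "clean" for v in variants}
    out = list(variants)
    occupied = [(v.interval.chrom, v.interval.start) for v in variants]
    clean_iter = iter(
        sample_clean_positions(
            2 * sum(config.artifact_rates.values()) + 8, ann, rng, avoid=occupied
        )
    )

    def clean_site():
        chrom, pos = next(clean_iter)
        ref = reference[chrom][pos]
        return chrom, pos, ref

    for rule, count in config.artifact_rates.items():
        for _ in range(int(count)):
            if rule == RULE_DEPTH:
                chrom, pos, ref = clean_site()
                v = _mk_variant(
                    patient_id, timepoint, chrom, pos, ref, _other_base(ref), 90, 40, gdp=95
                )
            elif rule == RULE_LOW_AF:
                chrom, pos, ref = clean_site()
                v = _mk_variant(
                    patient_id, timepoint, chrom, pos, ref, _other_base(ref), 100, 2
                )
            elif rule == RULE_REPEAT:
                iv = ann.repeats[int(rng.integers(len(ann.repeats)))]
                pos = int(rng.integers(iv.start, iv.end))
                ref = reference[iv.chrom][pos]
                v = _mk_variant(
                    patient_id, timepoint, iv.chrom, pos, ref, _other_base(ref), 90, 40
                )
            elif rule == RULE_HOMOPOLYMER:
                chrom = "chrS1"
                start, ln, base = _PLANTED_RUNS[chrom][
                    int(rng.integers(len(_PLANTED_RUNS[chrom])))
                ]
                pos = start - 1 if rng.random() < 0.5 else start + ln
                ref = reference[chrom][pos]
                v = _mk_variant(
                    patient_id, timepoint, chrom, pos, ref, _other_base(ref), 90, 40
                )
            elif rule == RULE_NEAR_INDEL:
                chrom, pos, ref = clean_site()
                ins = ref + "ACG"
                indel = _mk_variant(
                    patient_id, timepoint, chrom, pos, ref, ins, 90, 30
                )
                truth[indel.key] = "clean"
                out.append(indel)
                snv_pos = pos + 3
                ref2 = reference[chrom][snv_pos]
                v = _mk_variant(
                    patient_id, timepoint, chrom, snv_pos, ref2, _other_base(ref2), 90, 40
                )
            elif rule == RULE_POPULATION:
                chrom, pos, ref, alt = ann.population_records[
                    int(rng.integers(len(ann.population_records)))
                ]
                v = _mk_variant(patient_id, timepoint, chrom, pos, ref, alt, 90, 40)
            else:
                raise ValueError(f"unknown artifact rule {rule!r}")
            truth[v.key] = rule
            out.append(v)
    return out, truth


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(outdir, config: SimConfig | None = None) -> dict:
    """Write a complete, loadable input bundle; byte-identical under a seed.

    Contents: toy reference FASTA, repeat/gap/regulatory/conserved BEDs, a
    population VCF, per-sample tumor VCFs with injected artifacts, a
    metadata TSV and an artifact truth table.  Returns the path map.
    """
    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, ann = build_toy_reference(config.seed)
    paths = {}
    paths["reference"] = write_reference(outdir / "reference.fa", reference)
    paths["repeats"] = write_regions(outdir / "repeats.bed", ann.repeats)
    paths["gaps"] = write_regions(outdir / "gaps.bed", ann.gaps)
    paths["regulatory"] = write_regions(outdir / "regulatory.bed", ann.regulatory)
    paths["conserved"] = write_regions(outdir / "conserved.bed", ann.conserved)

    pop_path = outdir / "population.vcf"
    with pop_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in ann.population_records:
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    paths["population"] = pop_path

    rng = substream(config.seed, "bundle")
    rates = config.artifact_rates or {r: 2 for r in SNV_RULES}
    cfg = SimConfig(
        seed=config.seed,
        n_samples=config.n_samples,
        burden_range=config.burden_range,
        depth_mean=config.depth_mean,
        artifact_rates=rates,
    )
    truth_rows = []
    meta_rows = []
    for i in range(config.n_samples):
        pid = f"SIM_{i + 1:03d}"
        n_clean = int(rng.integers(20, 40))
        positions = sample_clean_positions(n_clean, ann, substream(config.seed, f"pos-{pid}"))
        clean = []
        for chrom, pos in positions:
            ref = reference[chrom][pos]
            depth = int(rng.poisson(config.depth_mean))
            depth = max(depth, 10)
            alt_n = int(rng.binomial(depth, 0.45))
            alt_n = max(alt_n, int(np.ceil(0.05 * depth)))
            clean.append(
                _mk_variant(pid, DIAGNOSIS, chrom, pos, ref, _other_base(ref), depth, alt_n)
            )
        per_cfg = SimConfig(seed=config.seed + 7919 * (i + 1), artifact_rates=rates)
        augmented, truth = inject_artifacts(clean, reference, ann, per_cfg, patient_id=pid)
        vcf_path = outdir / f"{pid}.vcf"
        write_variants(vcf_path, augmented, sample_id=pid)
        paths[pid] = vcf_path
        for key, label in sorted(truth.items(), key=str):
            truth_rows.append((pid, *key, label))
        meta_rows.append((pid, f"{_u(substream(config.seed, f'purity-{pid}'), *config.purity_range):.3f}"))

    truth_path = outdir / "artifact_truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("patient_id\tchrom\tpos\tref\talt\trule\n")
        for row in truth_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths["truth"] = truth_path

    meta_path = outdir / "samples.tsv"
    with meta_path.open("w") as fh:
        fh.write("patient_id\tpurity\n")
        for pid, purity in meta_rows:
            fh.write(f"{pid}\t{purity}\n")
    paths["meta"] = meta_path
    return paths
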