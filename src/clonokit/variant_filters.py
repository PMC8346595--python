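"""Downstream somatic SNV/indel filter cascade, SV filters and replicate
concordance.

Filter rules are evaluated independently of one another, so the cascade is
order-free: a variant survives iff it violates no rule, and every removed
variant carries the full set of rules it violated.

Rule identifiers
----------------
``depth_anomaly``
    germline depth at the site exceeds ``depth_fold`` x the germline
    chromosomal mean.
``low_af``
    tumor AF strictly below the applicable threshold (default 5%; 10% for
    samples flagged for a pre-sample transplant or excess dbSNP overlap).
``repeat_overlap``
    variant overlaps an annotated repeat region.
``homopolymer``
    variant interval, expanded by 1 bp, intersects a run of >= 7 identical
    reference bases.
``near_indel``
    SNV within 5 bp of an indel called in the same sample.
``population_variant``
    present in a population variant set (allele match for SNVs; position
    match within 1 bp for indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_model import (
    DEL,
    DUP,
    INDEL,
    SNV,
    GenomicInterval,
    IntervalSet,
    SampleMeta,
    SomaticVariant,
    StructuralVariant,
)

RULE_DEPTH = "depth_anomaly"
RULE_LOW_AF = "low_af"
RULE_REPEAT = "repeat_overlap"
RULE_HOMOPOLYMER = "homopolymer"
RULE_NEAR_INDEL = "near_indel"
RULE_POPULATION = "population_variant"

SNV_RULES = (
    RULE_DEPTH,
    RULE_LOW_AF,
    RULE_REPEAT,
    RULE_HOMOPOLYMER,
    RULE_NEAR_INDEL,
    RULE_POPULATION,
)

SV_POPULATION = "population"
SV_LOW_COVERAGE = "low_coverage"
SV_GAP = "gap"
SV_DEL_DUP = "del_dup_overlap"
SV_EXCLUDED_GENE = "excluded_gene"


@dataclass
class FilterConfig:
    af_min_default: float = 0.05
    af_min_flagged: float = 0.10
    depth_fold: float = 3.0
    homopolymer_min_len: int = 7
    homopolymer_flank_bp: int = 1
    indel_flank_bp: int = 5
    dbsnp_sample_fraction: float = 0.90
    indel_population_slop_bp: int = 1
    sv_reciprocal_overlap: float = 0.50
    sv_window_bp: int = 10_000
    sv_window_min_cov: float = 10.0

    def __post_init__(self):
        for name in (
            "af_min_default",
            "af_min_flagged",
            "depth_fold",
            "homopolymer_min_len",
            "indel_flank_bp",
            "sv_window_bp",
            "sv_window_min_cov",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dbsnp_sample_fraction", "sv_reciprocal_overlap"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ChromDepthProfile:
    """Mean germline depth per chromosome.

    A per-position accessor may be supplied; without one, the variant's own
    recorded germline depth is the per-site quantity.
    """

    chrom_means: Mapping[str, float]
    position_depth: callable | None = None

    def mean(self, chrom: str) -> float:
        try:
            m = self.chrom_means[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} absent from depth profile")
        if m <= 0:
            raise ValueError(f"non-positive mean depth for {chrom}")
        return m

    def depth_at(self, v: SomaticVariant) -> float:
        if self.position_depth is not None:
            return self.position_depth(v.interval.chrom, v.interval.start)
        return v.germline_depth


def filter_depth_anomaly(
    v: SomaticVariant, prof: ChromDepthProfile, cfg: FilterConfig
) -> bool:
    """Return True when the variant passes (failure is a strict inequality)."""
    site_depth = prof.depth_at(v)
    return site_depth <= cfg.depth_fold * prof.mean(v.interval.chrom)


def filter_low_af(v: SomaticVariant, meta: SampleMeta, cfg: FilterConfig) -> bool:
    """Return True when the variant passes the AF floor.

    Samples from a patient transplanted before sampling, or whose call set
    overlaps dbSNP in more than ``dbsnp_sample_fraction`` of calls, use the
    raised ``af_min_flagged`` threshold; "below" is strict, so an AF exactly
    at threshold passes.
    """
    flagged = meta.bmt_flag or meta.dbsnp_overlap_fraction > cfg.dbsnp_sample_fraction
    threshold = cfg.af_min_flagged if flagged else cfg.af_min_default
    return v.af >= threshold


def _homopolymer_hit(
    v: SomaticVariant, reference: Mapping[str, str], cfg: FilterConfig
) -> bool:
    seq = reference.get(v.interval.chrom)
    if seq is None:
        raise ValueError(f"no reference sequence for {v.interval.chrom}")
    lo = max(0, v.interval.start - cfg.homopolymer_flank_bp)
    hi = min(len(seq), v.interval.end + cfg.homopolymer_flank_bp)
    # scan a window wide enough to see any qualifying run touching [lo, hi)
    wlo = max(0, lo - cfg.homopolymer_min_len)
    whi = min(len(seq), hi + cfg.homopolymer_min_len)
    run_start = wlo
    for i in range(wlo + 1, whi + 1):
        if i == whi or seq[i] != seq[run_start]:
            if i - run_start >= cfg.homopolymer_min_len:
                if run_start < hi and i > lo:  # run intersects expanded interval
                    return True
            run_start = i
    return False


def filter_annotation_overlaps(
    v: SomaticVariant,
    repeats: IntervalSet,
    population: "PopulationIndex",
    indels: Sequence[SomaticVariant],
    reference: Mapping[str, str],
    cfg: FilterConfig,
) -> set[str]:
    """Return the set of annotation rules violated by ``v``."""
    failed = set()
    if repeats.any_overlap(v.interval):
        failed.add(RULE_REPEAT)
    if _homopolymer_hit(v, reference, cfg):
        failed.add(RULE_HOMOPOLYMER)
    if v.var_class == SNV:
        pos = v.interval.start
        for ind in indels:
            if ind.sample_id != v.sample_id:
                continue
            if ind.interval.chrom != v.interval.chrom:
                continue
            gap = max(ind.interval.start - pos, pos - (ind.interval.end - 1), 0)
            if gap <= cfg.indel_flank_bp:
                failed.add(RULE_NEAR_INDEL)
                break
    if population.contains(v, slop_bp=cfg.indel_population_slop_bp):
        failed.add(RULE_POPULATION)
    return failed


class PopulationIndex:
    """Population-variant membership queries.

    SNVs match on chrom + position + both alleles; indels match on position
    only, within a configurable slop after left-alignment.
    """

    def __init__(self, variants: Iterable[SomaticVariant] = (), records: Iterable[tuple] = ()):
        self._snvs: set[tuple] = set()
        self._indel_pos: dict[str, set[int]] = {}
        for v in variants:
            self._add(v.interval.chrom, v.interval.start, v.ref_allele, v.alt_allele)
        for chrom, pos0, ref, alt in records:
            self._add(chrom, pos0, ref, alt)

    def _add(self, chrom: str, pos0: int, ref: str, alt: str):
        if len(ref) == 1 and len(alt) == 1:
            self._snvs.add((chrom, pos0, ref, alt))
        else:
            self._indel_pos.setdefault(chrom, set()).add(pos0)

    def contains(self, v: SomaticVariant, slop_bp: int = 1) -> bool:
        if v.var_class == SNV:
            return (
                v.interval.chrom,
                v.interval.start,
                v.ref_allele,
                v.alt_allele,
            ) in self._snvs
        positions = self._indel_pos.get(v.interval.chrom, ())
        return any(
            p in positions
            for p in range(v.interval.start - slop_bp, v.interval.start + slop_bp + 1)
        )


@dataclass
class CascadeResult:
    survivors: list[SomaticVariant]
    removed: list[SomaticVariant]
    rule_counts: dict[str, int]

    def __post_init__(self):
        assert len(self.survivors) + len(self.removed) >= 0


def run_cascade(
    variants: Sequence[SomaticVariant],
    *,
    depth_profile: ChromDepthProfile,
    metas: Mapping[str, SampleMeta],
    repeats: IntervalSet,
    population: PopulationIndex,
    reference: Mapping[str, str],
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """Apply all six downstream rules; survivors fail none.

    ``metas`` maps sample_id -> SampleMeta (for the AF-threshold exception).
    Indels in ``variants`` themselves provide the near-indel annotation.
    """
    cfg = cfg or FilterConfig()
    indels = [v for v in variants if v.var_class == INDEL]
    rule_counts = {r: 0 for r in SNV_RULES}
    survivors, removed = [], []
    for v in variants:
        failed = set()
        if not filter_depth_anomaly(v, depth_profile, cfg):
            failed.add(RULE_DEPTH)
        meta = metas.get(v.sample_id) or metas.get(v.patient_id)
        if meta is None:
            raise KeyError(f"no metadata for sample {v.sample_id}")
        if not filter_low_af(v, meta, cfg):
            failed.add(RULE_LOW_AF)
        failed |= filter_annotation_overlaps(
            v, repeats, population, indels, reference, cfg
        )
        v.filter_flags = failed
        if failed:
            removed.append(v)
            for r in failed:
                rule_counts[r] += 1
        else:
            survivors.append(v)
    assert len(survivors) + len(removed) == len(variants)
    return CascadeResult(survivors, removed, rule_counts)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min of mutual overlap fractions; 0 when disjoint or on different chroms."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def _windows(span: GenomicInterval, window_bp: int) -> Iterable[int]:
    first = span.start // window_bp
    last = (span.end - 1) // window_bp
    return range(first, last + 1)


def filter_structural_variants(
    svs: Sequence[StructuralVariant],
    population_svs: Sequence[StructuralVariant],
    germline_cov: Mapping[str, Sequence[float]],
    gaps: IntervalSet,
    excluded_genes: frozenset | set,
    whitelist: frozenset | set,
    cfg: FilterConfig | None = None,
) -> tuple[list[StructuralVariant], dict[int, set[str]]]:
    """Apply the three SV removal rules plus the gene exclusion list.

    ``germline_cov`` maps chromosome -> per-window mean coverages (windows of
    ``sv_window_bp``).  An SV whose gene set intersects ``whitelist`` is kept
    regardless of any failed rule.  Returns surviving SVs and, keyed by input
    index, the removal reasons of dropped SVs.
    """
    cfg = cfg or FilterConfig()
    dups_by_sample: dict[str, list[StructuralVariant]] = {}
    for sv in svs:
        if sv.sv_type == DUP:
            dups_by_sample.setdefault(sv.sample_id, []).append(sv)

    survivors: list[StructuralVariant] = []
    reasons: dict[int, set[str]] = {}
    for i, sv in enumerate(svs):
        failed = set()
        for pop in population_svs:
            if pop.sv_type != sv.sv_type or sv.sv_type == "TRA":
                continue
            if reciprocal_overlap(sv.span, pop.span) >= cfg.sv_reciprocal_overlap:
                failed.add(SV_POPULATION)
                break
        if sv.sv_type != "TRA":
            span = sv.span
            cov = germline_cov.get(span.chrom)
            if cov is not None:
                for w in _windows(span, cfg.sv_window_bp):
                    if w < len(cov) and cov[w] < cfg.sv_window_min_cov:
                        failed.add(SV_LOW_COVERAGE)
                        break
            if gaps.any_overlap(span):
                failed.add(SV_GAP)
            if sv.sv_type == DEL:
                for dup in dups_by_sample.get(sv.sample_id, ()):
                    if span.overlaps(dup.span):
                        failed.add(SV_DEL_DUP)
                        break
        if sv.genes & set(excluded_genes):
            failed.add(SV_EXCLUDED_GENE)
        if failed and not (sv.genes & set(whitelist)):
            reasons[i] = failed
        else:
            survivors.append(sv)
    return survivors, reasons


def replicate_concordance(
    callsets: Sequence[set],
) -> tuple[float, float, float]:
    """Fractions of the union of calls present in all three, exactly two and
    exactly one of three technical replicates."""
    if len(callsets) != 3:
        raise ValueError("exactly three replicate call sets required")
    union = set().union(*callsets)
    if not union:
        raise ValueError("replicate call sets are all empty")
    tally = {1: 0, 2: 0, 3: 0}
    for key in union:
        tally[sum(key in s for s in callsets)] += 1
    n = len(union)
    return tally[3] / n, tally[2] / n, tally[1] / n
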