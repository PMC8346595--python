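"""Non-coding variant gating and recurrence-hotspot clustering.

Gating keeps non-coding SNVs that overlap at least one regulatory annotation
and are absent from population variant sets; conservation overlap is
recorded as a label only.  Gated variants are then clustered per chromosome
by complete-linkage agglomeration on genomic distance, cut so that every
cluster's maximum pairwise distance stays strictly below the width
threshold, and clusters recurring in fewer than ``min_patients`` distinct
patients are discarded.

Complete linkage is used because it enforces the within-cluster diameter
bound directly.  In one dimension the closest cluster pair under complete
linkage is always adjacent in sorted order, so the agglomeration below works
on contiguous runs; ties are broken toward the leftmost pair, which makes
the output canonical and independent of input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import NON_CODING, GenomicInterval, IntervalSet, SomaticVariant
from .variant_filters import PopulationIndex

CONSERVED_LABEL = "conserved"


@dataclass
class GatedVariant:
    variant: SomaticVariant
    region_labels: frozenset
    conserved: bool = False


@dataclass
class HotspotCluster:
    chrom: str
    span: GenomicInterval
    variants: list = field(default_factory=list)
    patients: frozenset = frozenset()
    region_labels: frozenset = frozenset()

    @property
    def max_pairwise_distance(self) -> int:
        positions = [g.variant.interval.start for g in self.variants]
        return max(positions) - min(positions)


def gate_noncoding(
    variants: Iterable[SomaticVariant],
    regulatory: IntervalSet,
    population: PopulationIndex,
    conserved: IntervalSet | None = None,
) -> list[GatedVariant]:
    """Keep non-coding SNVs inside regulatory annotation and absent from the
    population sets; annotate (never filter on) conservation overlap."""
    out = []
    for v in variants:
        if v.var_class != "SNV" or v.functional_class != NON_CODING:
            continue
        hits = regulatory.overlapping(v.interval)
        if not hits:
            continue
        if population.contains(v):
            continue
        labels = frozenset(h.label for h in hits if h.label)
        flag = conserved.any_overlap(v.interval) if conserved is not None else False
        out.append(GatedVariant(v, labels, flag))
    return out


def _complete_linkage_runs(
    positions: Sequence[int], width: float
) -> list[tuple[int, int]]:
    """Agglomerate sorted positions into contiguous runs.

    Returns (start_index, end_index) pairs (inclusive) over the sorted
    position list.  Merging proceeds by repeatedly fusing the adjacent run
    pair with the smallest merged diameter while that diameter is < width;
    ties pick the leftmost pair.
    """
    runs = [(i, i) for i in range(len(positions))]
    while len(runs) > 1:
        best_k, best_d = None, None
        for k in range(len(runs) - 1):
            d = positions[runs[k + 1][1]] - positions[runs[k][0]]
            if best_d is None or d < best_d:
                best_k, best_d = k, d
        if best_d is None or best_d >= width:
            break
        i, _ = runs[best_k]
        _, j = runs.pop(best_k + 1)
        runs[best_k] = (i, j)
    return runs


def cluster_hotspots(
    gated: Sequence[GatedVariant],
    cluster_width: float = 100,
    min_patients: int = 2,
) -> list[HotspotCluster]:
    """Cluster gated variants into recurrence hotspots.

    Variants on different chromosomes never cluster together (infinite
    distance).  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[GatedVariant]] = {}
    for g in gated:
        by_chrom.setdefault(g.variant.interval.chrom, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda g: g.variant.interval.start)
        positions = [g.variant.interval.start for g in members]
        for i, j in _complete_linkage_runs(positions, cluster_width):
            group = members[i : j + 1]
            patients = frozenset(g.variant.patient_id for g in group)
            if len(patients) < min_patients:
                continue
            lo = min(g.variant.interval.start for g in group)
            hi = max(g.variant.interval.start for g in group) + 1
            labels = frozenset().union(*(g.region_labels for g in group))
            clusters.append(
                HotspotCluster(chrom, GenomicInterval(chrom, lo, hi), group, patients, labels)
            )
    clusters.sort(key=lambda c: (c.chrom, c.span.start))
    return clusters


def expression_gate(gene: str, fpkm: float) -> bool:
    """A gene counts as expressed when log2(FPKM) > 1, i.e. FPKM > 2."""
    if fpkm < 0:
        raise ValueError(f"negative FPKM for {gene}: {fpkm}")
    return fpkm > 0 and math.log2(fpkm) > 1


def write_hotspot_tsv(path, clusters: Sequence[HotspotCluster]):
    with open(path, "w") as fh:
        fh.write("# hotspot clusters: max pairwise distance < width, >= min patients\n")
        fh.write("chrom\tstart\tend\tn_variants\tn_patients\tgenes\tlabels\n")
        for c in clusters:
            genes = sorted({g.variant.gene for g in c.variants if g.variant.gene})
            fh.write(
                f"{c.chrom}\t{c.span.start}\t{c.span.end}\t{len(c.variants)}\t"
                f"{len(c.patients)}\t{','.join(genes)}\t{','.join(sorted(c.region_labels))}\n"
            )
    return path
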