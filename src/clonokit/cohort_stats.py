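"""Cohort-level tallies, exact tests, burden summaries and the final report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_model import DIAGNOSIS, R1, R2, REMISSION, SampleMeta


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Exact two-sided p: sum of hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed
    one (standard two-sided convention)."""
    row1 = t.a + t.b
    n = t.total
    col1 = t.a + t.c
    dist = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(t.a)
    # small relative tolerance guards against float noise on ties
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


@dataclass
class TrajectoryTally:
    counts_by_label: dict
    n_consensus: int
    n_score_above_080: int
    n_score_below_065: int


def tally_trajectories(metas: Iterable[SampleMeta]) -> TrajectoryTally:
    """Patients per trajectory label, plus consensus-model score counts.

    "above 0.8" and "below 0.65" are strict comparisons; a score of exactly
    0.8 counts in neither bucket.
    """
    counts: dict[str, int] = {}
    n_consensus = n_above = n_below = 0
    for m in metas:
        if m.trajectory_label:
            counts[m.trajectory_label] = counts.get(m.trajectory_label, 0) + 1
        if m.probability_score is not None:
            n_consensus += 1
            if m.probability_score > 0.8:
                n_above += 1
            if m.probability_score < 0.65:
                n_below += 1
    return TrajectoryTally(counts, n_consensus, n_above, n_below)


def tally_gene_by_trajectory(metas: Iterable[SampleMeta], gene: str) -> dict[str, int]:
    """Distinct patients per trajectory carrying ``gene`` among their
    critical genes at any timepoint."""
    counts: dict[str, int] = {}
    for m in metas:
        label = m.trajectory_label
        if not label:
            continue
        if any(gene in genes for genes in m.critical_genes.values()):
            counts[label] = counts.get(label, 0) + 1
    return counts


@dataclass
class SampleInventory:
    n_patients: int
    n_diagnosis: int
    n_remission: int
    n_r1: int
    n_r2: int

    @property
    def tumor_total(self) -> int:
        return self.n_diagnosis + self.n_r1 + self.n_r2

    @property
    def grand_total(self) -> int:
        return self.tumor_total + self.n_remission


def sample_inventory(metas: Sequence[SampleMeta]) -> SampleInventory:
    """Genome counts by timepoint: one diagnosis, remission and first-relapse
    genome per patient, plus a second-relapse genome where recorded."""
    n = len(metas)
    n_r2 = sum(1 for m in metas if m.has_second_relapse)
    return SampleInventory(n, n, n, n, n_r2)


def burden_summary(
    burdens_by_timepoint: Mapping[str, Sequence[int]],
) -> dict[str, dict]:
    """Median (even-n: mean of middle pair) and min-max range per timepoint;
    empty groups are omitted."""
    out = {}
    for tp, counts in burdens_by_timepoint.items():
        if not len(counts):
            continue
        arr = np.asarray(counts)
        out[tp] = {
            "median": float(np.median(arr)),
            "min": int(arr.min()),
            "max": int(arr.max()),
            "n": int(arr.size),
        }
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_SECTION_ORDER = ("cohort", "burdens", "signatures", "hotspots", "drivers", "trajectories")


def render_report(
    *,
    metas: Sequence[SampleMeta] | None = None,
    burdens: Mapping | None = None,
    signature_attributions: Mapping | None = None,
    hotspots: Sequence | None = None,
    driver_calls: Sequence | None = None,
    trajectory_calls: Sequence | None = None,
    require: Sequence[str] = ("cohort",),
) -> str:
    """Assemble a deterministic markdown report from stage outputs.

    Sections are emitted in a fixed order and only when their input is
    present; any section listed in ``require`` but missing its input is an
    error.
    """
    sections = {
        "cohort": metas,
        "burdens": burdens,
        "signatures": signature_attributions,
        "hotspots": hotspots,
        "drivers": driver_calls,
        "trajectories": trajectory_calls,
    }
    missing = [s for s in require if sections.get(s) is None]
    if missing:
        raise ValueError(f"missing mandatory report inputs: {', '.join(missing)}")

    lines = ["# Cohort analysis report", ""]
    if metas is not None:
        inv = sample_inventory(list(metas))
        tally = tally_trajectories(metas)
        lines += [
            "## Cohort",
            "",
            f"- patients: {inv.n_patients}",
            f"- tumor genomes: {inv.tumor_total}",
            f"- total genomes: {inv.grand_total}",
            f"- second-relapse patients: {inv.n_r2}",
            f"- consensus models: {tally.n_consensus} "
            f"(scores >0.8: {tally.n_score_above_080}, <0.65: {tally.n_score_below_065})",
        ]
        for label in sorted(tally.counts_by_label):
            lines.append(f"- trajectory {label}: {tally.counts_by_label[label]}")
        lines.append("")
    if burdens is not None:
        lines += ["## Mutation burdens", "", "| timepoint | n | median | range |", "|---|---|---|---|"]
        for tp in sorted(burdens):
            s = burdens[tp]
            lines.append(f"| {tp} | {s['n']} | {s['median']:g} | {s['min']}-{s['max']} |")
        lines.append("")
    if signature_attributions is not None:
        lines += ["## Signature attributions", "", "| sample | signature | mutations |", "|---|---|---|"]
        for sample in sorted(signature_attributions):
            for label, value in sorted(signature_attributions[sample].items()):
                lines.append(f"| {sample} | {label} | {value:.1f} |")
        lines.append("")
    if hotspots is not None:
        lines += ["## Regulatory hotspots", "", "| chrom | start | end | variants | patients |", "|---|---|---|---|---|"]
        for h in hotspots:
            lines.append(
                f"| {h.chrom} | {h.span.start} | {h.span.end} | {len(h.variants)} | {len(h.patients)} |"
            )
        lines.append("")
    if driver_calls is not None:
        lines += ["## Driver calls", "", "| gene | verdict | criteria |", "|---|---|---|"]
        for c in sorted(driver_calls, key=lambda c: c.gene):
            lines.append(f"| {c.gene} | {c.verdict} | {','.join(sorted(c.criteria_met))} |")
        lines.append("")
    if trajectory_calls is not None:
        lines += ["## Trajectories", "", "| patient | interval | label | score |", "|---|---|---|---|"]
        for c in sorted(trajectory_calls, key=lambda c: (c.patient, c.interval)):
            score = "as published" if c.probability_score is None else f"{c.probability_score:.2f}"
            lines.append(f"| {c.patient} | {c.interval} | {c.label} | {score} |")
        lines.append("")
    return "\n".join(lines)
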