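"""Driver-gene rule engine.

A gene is called a driver when either
  * it is a known driver and its mutations satisfy the functional criteria
    (non-silent, clonal AF, RNA expression) in at least one patient, or
  * it is novel and additionally reaches tool significance and recurrence
    across at least ``min_patients`` patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_model import DIAGNOSIS, NON_SILENT, R1, R2, SomaticVariant

CRIT_SIGNIFICANCE = "significance"
CRIT_RECURRENCE = "recurrence"
CRIT_NON_SILENT = "non_silent"
CRIT_CLONAL_AF = "clonal_af"
CRIT_RNA = "rna_expressed"


@dataclass
class PatientHit:
    variant_key: tuple
    timepoint: str
    af: float
    functional_class: str
    rna_expressed: bool = False


@dataclass
class GeneEvidence:
    gene: str
    tool_p_values: Mapping[str, float] = field(default_factory=dict)
    patient_hits: Mapping[str, list] = field(default_factory=dict)
    known_driver: bool = False

    def __post_init__(self):
        for tool, p in self.tool_p_values.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {tool} out of [0,1]: {p}")


@dataclass
class DriverCall:
    gene: str
    verdict: bool
    criteria_met: frozenset
    rationale: str


@dataclass
class DriverConfig:
    p_max: float = 0.05
    af_clonal: float = 0.25
    min_patients: int = 2


def evaluate_driver(e: GeneEvidence, cfg: DriverConfig | None = None) -> DriverCall:
    """Apply the five driver criteria, with the known-driver shortcut.

    Known drivers need only the functional criteria (non-silent, clonal AF,
    RNA expression) and a single patient suffices; novel genes additionally
    need tool significance (min p <= p_max) and recurrence.
    """
    cfg = cfg or DriverConfig()
    if not e.patient_hits:
        raise ValueError(f"no patient hits recorded for {e.gene}")
    met = set()
    if e.tool_p_values and min(e.tool_p_values.values()) <= cfg.p_max:
        met.add(CRIT_SIGNIFICANCE)
    non_silent_patients = {
        p
        for p, hits in e.patient_hits.items()
        if any(h.functional_class == NON_SILENT for h in hits)
    }
    if len(non_silent_patients) >= cfg.min_patients:
        met.add(CRIT_RECURRENCE)
    if non_silent_patients:
        met.add(CRIT_NON_SILENT)
    all_hits = [h for hits in e.patient_hits.values() for h in hits]
    if any(h.af >= cfg.af_clonal for h in all_hits):
        met.add(CRIT_CLONAL_AF)
    if any(h.rna_expressed for h in all_hits):
        met.add(CRIT_RNA)

    functional = {CRIT_NON_SILENT, CRIT_CLONAL_AF, CRIT_RNA}
    if e.known_driver:
        verdict = functional <= met
        why = "known driver: criteria 3-5" + (" met" if verdict else " not met")
    else:
        needed = functional | {CRIT_SIGNIFICANCE, CRIT_RECURRENCE}
        verdict = needed <= met
        why = "novel gene: criteria 1-5" + (" met" if verdict else " not met")
    return DriverCall(e.gene, verdict, frozenset(met), why)


DIAGNOSIS_ONLY = "diagnosis_only"
RELAPSE_ONLY = "relapse_only"
BOTH = "both"


def summarize_driver_timepoints(
    calls: Sequence[DriverCall], evidence: Mapping[str, GeneEvidence]
) -> dict[str, str]:
    """Classify each called driver gene by its union of carrier timepoints."""
    out = {}
    for call in calls:
        if not call.verdict:
            continue
        tps = {
            h.timepoint
            for hits in evidence[call.gene].patient_hits.values()
            for h in hits
        }
        at_dx = DIAGNOSIS in tps
        at_rel = bool(tps & {R1, R2})
        if at_dx and at_rel:
            out[call.gene] = BOTH
        elif at_dx:
            out[call.gene] = DIAGNOSIS_ONLY
        elif at_rel:
            out[call.gene] = RELAPSE_ONLY
    return out


def biallelic_hits(
    variants: Iterable[SomaticVariant],
    deletions: Iterable[tuple],
) -> list[tuple]:
    """Genes with a heterozygous deletion plus a non-silent mutation in the
    same sample.

    ``deletions`` holds (sample_id, gene, zygosity) tuples from an external
    CNA caller; zygosity is "het" or "hom".
    """
    mutated = {
        (v.sample_id, v.gene)
        for v in variants
        if v.gene and v.functional_class == NON_SILENT
    }
    out = []
    for sample_id, gene, zygosity in deletions:
        if zygosity == "het" and (sample_id, gene) in mutated:
            out.append((gene, sample_id))
    return sorted(set(out))


def load_known_drivers(path) -> frozenset:
    """Read a known-driver gene list: one symbol per line, '#' comments."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if s:
                genes.add(s)
    return frozenset(genes)


def read_tool_p_table(path) -> dict[str, dict[str, float]]:
    """Read a (gene, tool, p) TSV into gene -> {tool: p}."""
    import csv

    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["gene"], {})[row["tool"]] = float(row["p"])
    return out
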