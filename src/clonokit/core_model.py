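"""Domain types, coordinate conventions and shared readers/writers.

All positional data are held as 0-based half-open intervals; VCF positions
(1-based) are converted on read and back on write.  Missing values in
delimited tables ("na", "Na", "NA", empty cell) normalize to ``None``.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

# Timepoint labels used throughout the pipeline.
DIAGNOSIS = "diagnosis"
R1 = "r1"
R2 = "r2"
REMISSION = "remission"
TIMEPOINTS = (DIAGNOSIS, R1, R2, REMISSION)

#: tokens normalized to a missing value when parsing delimited tables
MISSING_TOKENS = frozenset({"na", ""})


def parse_missing(token: str | None):
    """Return ``None`` for any recognised missing token, else the stripped string."""
    if token is None:
        return None
    s = token.strip()
    if s.lower() in MISSING_TOKENS:
        return None
    return s


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally labelled."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


SNV = "SNV"
INDEL = "indel"

NON_SILENT = "non_silent"
SILENT = "silent"
NON_CODING = "non_coding"
UNKNOWN = "unknown"
FUNCTIONAL_CLASSES = (NON_SILENT, SILENT, NON_CODING, UNKNOWN)


@dataclass
class SomaticVariant:
    """One called somatic SNV or indel with counts and annotations."""

    patient_id: str
    sample_id: str
    timepoint: str
    interval: GenomicInterval
    ref_allele: str
    alt_allele: str
    var_class: str
    tumor_depth: int
    alt_count: int
    af: float
    germline_depth: int = 0
    gene: str = ""
    functional_class: str = UNKNOWN
    caller_set: frozenset = frozenset()
    filter_flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.alt_count > self.tumor_depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.var_class == SNV and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise ValueError("SNV requires single-base ref and alt")
        if self.tumor_depth > 0:
            expected = self.alt_count / self.tumor_depth
            if abs(self.af - expected) > 1e-9:
                raise ValueError(
                    f"af {self.af} inconsistent with {self.alt_count}/{self.tumor_depth}"
                )

    @property
    def key(self) -> tuple:
        """Identity key: chrom, 0-based position, ref, alt."""
        return (
            self.interval.chrom,
            self.interval.start,
            self.ref_allele,
            self.alt_allele,
        )


@dataclass
class SampleMeta:
    """Per-patient clinical and pipeline metadata."""

    patient_id: str
    timepoint: str = DIAGNOSIS
    purity: float = 1.0
    subtype: str | None = None
    bmt_flag: bool = False
    dbsnp_overlap_fraction: float = 0.0
    risk_group: str | None = None
    time_to_first_relapse_months: float | None = None
    time_to_second_relapse_months: float | None = None
    trajectory_label: str | None = None
    probability_score: float | None = None
    critical_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    @property
    def has_second_relapse(self) -> bool:
        return self.time_to_second_relapse_months is not None


DEL, DUP, INV, TRA = "DEL", "DUP", "INV", "TRA"
SV_TYPES = (DEL, DUP, INV, TRA)


@dataclass
class StructuralVariant:
    """A somatic structural variant with two breakpoint intervals."""

    sample_id: str
    sv_type: str
    breakpoint_a: GenomicInterval
    breakpoint_b: GenomicInterval
    genes: frozenset = frozenset()

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type != TRA:
            if self.breakpoint_a.chrom != self.breakpoint_b.chrom:
                raise ValueError(f"{self.sv_type} breakpoints must share a chromosome")
            if self.breakpoint_a.start > self.breakpoint_b.start:
                raise ValueError("breakpoint_a must not lie right of breakpoint_b")

    @property
    def span(self) -> GenomicInterval:
        """Full extent on the chromosome (non-TRA only)."""
        if self.sv_type == TRA:
            raise ValueError("TRA has no single-chromosome span")
        return GenomicInterval(
            self.breakpoint_a.chrom, self.breakpoint_a.start, self.breakpoint_b.end
        )


class IntervalSet:
    """Overlap queries over a static collection of intervals.

    Per-chromosome sorted arrays with a running-max of ends, queried by
    bisection; O(log n + k) per lookup.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._max_end: dict[str, list[int]] = {}
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._starts[chrom] = [iv.start for iv in ivs]
            run = []
            m = 0
            for iv in ivs:
                m = max(m, iv.end)
                run.append(m)
            self._max_end[chrom] = run

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return []
        hi = bisect_right(self._starts[query.chrom], query.end - 1)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._max_end[query.chrom][i] <= query.start:
                break
            if ivs[i].end > query.start:
                out.append(ivs[i])
        out.reverse()
        return out

    def any_overlap(self, query: GenomicInterval) -> bool:
        return bool(self.overlapping(query))


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GDP,Number=1,Type=Integer,Description="Germline depth at site">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Calling tools">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def _left_trim(pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared leading bases of ref/alt, advancing the anchor position.

    Keeps at least one base on each allele (VCF-style anchored indels keep
    their anchor when nothing else remains).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos0 = ref[1:], alt[1:], pos0 + 1
    return pos0, ref, alt


def read_variants(path, meta: SampleMeta) -> list[SomaticVariant]:
    """Read somatic variants from a VCF, converting to 0-based coordinates.

    Tumor depth and alt count are taken from the first sample's DP/AD FORMAT
    fields.  Germline depth, gene, functional class and caller provenance are
    read from the GDP/GENE/FCLASS/CALLERS INFO keys when present.
    """
    out = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if rec.ALT is None or len(rec.ALT) != 1:
                raise ValueError(
                    f"{path}: record at {rec.CHROM}:{rec.POS} must have exactly one ALT"
                )
            alt = rec.ALT[0]
            ref = rec.REF
            try:
                depth = int(rec.format("DP")[0][0])
                ad = rec.format("AD")[0]
                alt_count = int(ad[1])
            except (TypeError, KeyError, IndexError) as exc:
                raise ValueError(
                    f"{path}: missing DP/AD fields at {rec.CHROM}:{rec.POS}"
                ) from exc
            pos0, ref, alt = _left_trim(rec.POS - 1, ref, alt)
            var_class = SNV if len(ref) == 1 and len(alt) == 1 else INDEL
            callers = rec.INFO.get("CALLERS")
            caller_set = (
                frozenset(str(callers).split(",")) if callers else frozenset()
            )
            gdp = rec.INFO.get("GDP")
            out.append(
                SomaticVariant(
                    patient_id=meta.patient_id,
                    sample_id=f"{meta.patient_id}_{meta.timepoint}",
                    timepoint=meta.timepoint,
                    interval=GenomicInterval(rec.CHROM, pos0, pos0 + len(ref)),
                    ref_allele=ref,
                    alt_allele=alt,
                    var_class=var_class,
                    tumor_depth=depth,
                    alt_count=alt_count,
                    af=alt_count / depth if depth > 0 else 0.0,
                    germline_depth=int(gdp) if gdp is not None else 0,
                    gene=str(rec.INFO.get("GENE") or ""),
                    functional_class=str(rec.INFO.get("FCLASS") or UNKNOWN),
                    caller_set=caller_set,
                )
            )
    finally:
        vcf.close()
    return out


def write_variants(path, variants: Sequence[SomaticVariant], sample_id: str = "TUMOR"):
    """Write variants as an uncompressed VCF (1-based positions restored)."""
    path = Path(path)
    recs = sorted(variants, key=lambda v: (v.interval.chrom, v.interval.start))
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for v in recs:
            info = [f"GDP={v.germline_depth}"]
            if v.gene:
                info.append(f"GENE={v.gene}")
            if v.functional_class != UNKNOWN:
                info.append(f"FCLASS={v.functional_class}")
            if v.caller_set:
                info.append("CALLERS=" + ",".join(sorted(v.caller_set)))
            fh.write(
                "\t".join(
                    [
                        v.interval.chrom,
                        str(v.interval.start + 1),
                        ".",
                        v.ref_allele,
                        v.alt_allele,
                        ".",
                        "PASS",
                        ";".join(info),
                        "DP:AD",
                        f"{v.tumor_depth}:{v.tumor_depth - v.alt_count},{v.alt_count}",
                    ]
                )
                + "\n"
            )
    return path


def read_population_vcf(path) -> list[tuple]:
    """Read a sites-only population VCF as (chrom, pos0, ref, alt) records."""
    out = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            for alt in rec.ALT or []:
                pos0, ref, a = _left_trim(rec.POS - 1, rec.REF, alt)
                out.append((rec.CHROM, pos0, ref, a))
    finally:
        vcf.close()
    return out


def read_regions(path) -> list[GenomicInterval]:
    """Read a BED3+ file; 0-based half-open preserved; column 4 kept as label."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            label = cols[3] if len(cols) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label=label))
    return out


def write_regions(path, intervals: Iterable[GenomicInterval]):
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def _parse_float(token):
    s = parse_missing(token)
    return None if s is None else float(s)


def _parse_genes(token) -> frozenset:
    s = parse_missing(token)
    if s is None:
        return frozenset()
    return frozenset(g.strip() for g in s.split(",") if g.strip())


def read_cohort_tables(path_t1, path_t2) -> list[SampleMeta]:
    """Parse the clinical and trajectory tables into per-patient metadata.

    ``path_t1`` supplies subtype/risk/relapse timing/BMT status, ``path_t2``
    the trajectory label, consensus probability score and critical-gene cells
    per timepoint.  A duplicated patient_id in either table is an error.
    """
    metas: dict[str, SampleMeta] = {}
    with open(path_t1) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["patient_id"].strip()
            if pid in metas:
                raise ValueError(f"duplicate patient_id {pid} in {path_t1}")
            metas[pid] = SampleMeta(
                patient_id=pid,
                subtype=parse_missing(row.get("subtype_revised")),
                bmt_flag=row.get("bmt_after_first_relapse", "").strip().lower()
                in {"1", "yes", "true"},
                risk_group=parse_missing(row.get("risk_group")),
                time_to_first_relapse_months=_parse_float(
                    row.get("time_to_first_relapse_months")
                ),
                time_to_second_relapse_months=_parse_float(
                    row.get("time_to_second_relapse_months")
                ),
            )
    seen_t2 = set()
    with open(path_t2) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["patient_id"].strip()
            if pid in seen_t2:
                raise ValueError(f"duplicate patient_id {pid} in {path_t2}")
            seen_t2.add(pid)
            meta = metas.get(pid)
            if meta is None:
                raise ValueError(f"patient {pid} in {path_t2} absent from {path_t1}")
            meta.trajectory_label = parse_missing(row.get("trajectory"))
            meta.probability_score = _parse_float(row.get("probability_score"))
            genes = {}
            for col, tp in (
                ("critical_genes_diagnosis", DIAGNOSIS),
                ("critical_genes_first_relapse", R1),
                ("critical_genes_second_relapse", R2),
            ):
                gs = _parse_genes(row.get(col))
                if gs:
                    genes[tp] = gs
            meta.critical_genes = genes
    return list(metas.values())


def read_reference(path) -> dict[str, str]:
    """Load a FASTA reference as a chrom -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reference(path, chroms: Mapping[str, str], width: int = 70):
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def fixture_table_paths() -> tuple[Path, Path]:
    """Paths of the cohort tables shipped with the package."""
    data = resources.files("clonokit") / "data"
    return Path(str(data / "table1.tsv")), Path(str(data / "table2.tsv"))


def load_cohort_fixture() -> list[SampleMeta]:
    """Parse the shipped 29-patient cohort tables."""
    t1, t2 = fixture_table_paths()
    return read_cohort_tables(t1, t2)
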