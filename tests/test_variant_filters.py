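import pytest

from clonokit import variant_filters as vf
from clonokit.core_model import (
    DIAGNOSIS,
    DEL,
    DUP,
    GenomicInterval,
    IntervalSet,
    SampleMeta,
    SomaticVariant,
    StructuralVariant,
)
from clonokit.synthetic_data import SimConfig, inject_artifacts, sample_clean_positions, substream


def snv(chrom="c", pos=10, ref="C", alt="A", depth=100, alt_n=40, gdp=30, sample="P_diagnosis"):
    return SomaticVariant(
        patient_id="P",
        sample_id=sample,
        timepoint=DIAGNOSIS,
        interval=GenomicInterval(chrom, pos, pos + 1),
        ref_allele=ref,
        alt_allele=alt,
        var_class="SNV",
        tumor_depth=depth,
        alt_count=alt_n,
        af=alt_n / depth,
        germline_depth=gdp,
    )


CFG = vf.FilterConfig()


class TestDepthAnomaly:
    profile = vf.ChromDepthProfile({"c": 30.0})

    def test_excess_depth_fails(self):
        assert not vf.filter_depth_anomaly(snv(gdp=95), self.profile, CFG)  # 95 > 90

    def test_boundary_passes(self):
        assert vf.filter_depth_anomaly(snv(gdp=90), self.profile, CFG)  # not strict excess

    def test_zero_depth_passes(self):
        assert vf.filter_depth_anomaly(snv(gdp=0), self.profile, CFG)

    def test_unknown_chrom_errors(self):
        with pytest.raises(KeyError):
            vf.filter_depth_anomaly(snv(chrom="zz", gdp=5), self.profile, CFG)


class TestLowAf:
    def test_below_default_fails(self):
        v = snv(depth=100, alt_n=4)  # af 0.04
        assert not vf.filter_low_af(v, SampleMeta(patient_id="P"), CFG)

    def test_bmt_raises_threshold(self):
        v = snv(depth=100, alt_n=7)  # af 0.07 < 0.10 flagged
        assert not vf.filter_low_af(v, SampleMeta(patient_id="P", bmt_flag=True), CFG)

    def test_boundary_af_passes(self):
        v = snv(depth=100, alt_n=5)  # af exactly 0.05
        assert vf.filter_low_af(v, SampleMeta(patient_id="P"), CFG)

    def test_dbsnp_overlap_flag(self):
        v = snv(depth=100, alt_n=7)
        meta = SampleMeta(patient_id="P", dbsnp_overlap_fraction=0.95)
        assert not vf.filter_low_af(v, meta, CFG)


class TestAnnotationOverlaps:
    reference = {"c": "ACGTC" + "A" * 7 + "CGTCGTACGATCGTACGT" + "G" * 6 + "ACGTACGT"}
    empty_repeats = IntervalSet([])
    empty_pop = vf.PopulationIndex()

    def run(self, v, indels=()):
        return vf.filter_annotation_overlaps(
            v, self.empty_repeats, self.empty_pop, list(indels), self.reference, CFG
        )

    def test_adjacent_to_seven_run_fails(self):
        # run of 7 A at positions 5..11; SNV at 4 is adjacent within 1 bp
        assert self.run(snv(pos=4)) == {vf.RULE_HOMOPOLYMER}
        assert self.run(snv(pos=12, ref="C")) == {vf.RULE_HOMOPOLYMER}

    def test_inside_run_fails(self):
        assert vf.RULE_HOMOPOLYMER in self.run(snv(pos=8, ref="A", alt="C"))

    def test_six_run_passes(self):
        # run of 6 G at positions 29..34 is below the 7 bp minimum
        assert self.run(snv(pos=29, ref="G", alt="T")) == set()
        assert self.run(snv(pos=28, ref="T", alt="C")) == set()

    def test_near_indel_boundary(self):
        indel = SomaticVariant(
            "P", "P_diagnosis", DIAGNOSIS, GenomicInterval("c", 20, 21),
            "TA", "T", "indel", 50, 10, 0.2,
        )
        assert self.run(snv(pos=15, ref="G", alt="A"), [indel]) == {vf.RULE_NEAR_INDEL}
        assert self.run(snv(pos=14, ref="C", alt="A"), [indel]) == set()  # 6 bp away

    def test_near_indel_other_sample_ignored(self):
        indel = SomaticVariant(
            "Q", "Q_diagnosis", DIAGNOSIS, GenomicInterval("c", 20, 21),
            "TA", "T", "indel", 50, 10, 0.2,
        )
        assert self.run(snv(pos=18, ref="A", alt="C"), [indel]) == set()

    def test_repeat_overlap(self):
        repeats = IntervalSet([GenomicInterval("c", 15, 25)])
        v = snv(pos=20, ref="T", alt="C")
        failed = vf.filter_annotation_overlaps(
            v, repeats, self.empty_pop, [], self.reference, CFG
        )
        assert failed == {vf.RULE_REPEAT}

    def test_population_allele_match(self):
        pop = vf.PopulationIndex(records=[("c", 16, "A", "C")])
        assert vf.filter_annotation_overlaps(
            snv(pos=16, ref="A", alt="C"), self.empty_repeats, pop, [], self.reference, CFG
        ) == {vf.RULE_POPULATION}
        # different alt allele is not a population match
        assert vf.filter_annotation_overlaps(
            snv(pos=16, ref="A", alt="T"), self.empty_repeats, pop, [], self.reference, CFG
        ) == set()


class TestCascade:
    def _bundle(self, toy_world, rates):
        reference, ann = toy_world
        cfg = SimConfig(seed=5, artifact_rates=rates)
        rng = substream(5, "cascade-test")
        clean = []
        for chrom, pos in sample_clean_positions(4, ann, rng):
            ref = reference[chrom][pos]
            alt = {"A": "T", "C": "A", "G": "C", "T": "G"}[ref]
            clean.append(snv(chrom=chrom, pos=pos, ref=ref, alt=alt))
        return inject_artifacts(clean, reference, ann, cfg, patient_id="P") + (reference, ann)

    def run_cascade(self, variants, reference, ann):
        return vf.run_cascade(
            variants,
            depth_profile=vf.ChromDepthProfile(ann.chrom_means),
            metas={"P_diagnosis": SampleMeta(patient_id="P")},
            repeats=ann.repeat_index(),
            population=ann.population,
            reference=reference,
        )

    def test_single_rule_violators(self, toy_world):
        rates = {r: 1 for r in vf.SNV_RULES}
        variants, truth, reference, ann = self._bundle(toy_world, rates)
        res = self.run_cascade(variants, reference, ann)
        for v in res.removed:
            assert truth[v.key] in v.filter_flags
        removed_keys = {v.key for v in res.removed}
        for key, label in truth.items():
            if label != "clean":
                assert key in removed_keys
        for v in res.survivors:
            assert truth[v.key] == "clean"
        assert len(res.survivors) + len(res.removed) == len(variants)

    def test_empty_input(self, toy_world):
        reference, ann = toy_world
        res = self.run_cascade([], reference, ann)
        assert res.survivors == [] and res.removed == []
        assert all(c == 0 for c in res.rule_counts.values())

    def test_clean_only_identity(self, toy_world):
        variants, truth, reference, ann = self._bundle(toy_world, {})
        res = self.run_cascade(variants, reference, ann)
        assert len(res.survivors) == len(variants)

    def test_order_independence(self, toy_world):
        rates = {r: 1 for r in vf.SNV_RULES}
        variants, truth, reference, ann = self._bundle(toy_world, rates)
        baseline = self.run_cascade(variants, reference, ann)
        shuffled = list(reversed(variants))
        res = self.run_cascade(shuffled, reference, ann)
        assert {v.key for v in res.survivors} == {v.key for v in baseline.survivors}
        assert res.rule_counts == baseline.rule_counts


def make_sv(sample, sv_type, chrom, start, end, genes=()):
    mid = (start + end) // 2
    return StructuralVariant(
        sample,
        sv_type,
        GenomicInterval(chrom, start, start + 1),
        GenomicInterval(chrom, end - 1, end),
        genes=frozenset(genes),
    )


class TestStructuralVariants:
    full_cov = {"c": [30.0] * 20}
    no_gaps = IntervalSet([])

    def test_reciprocal_overlap_removal(self):
        sv = make_sv("S", DEL, "c", 10_000, 20_000)
        pop = [make_sv("POP", DEL, "c", 14_000, 24_000)]  # 60% reciprocal
        survivors, reasons = vf.filter_structural_variants(
            [sv], pop, self.full_cov, self.no_gaps, set(), set()
        )
        assert survivors == [] and reasons[0] == {vf.SV_POPULATION}

    def test_reciprocal_overlap_requires_same_type(self):
        sv = make_sv("S", DEL, "c", 10_000, 20_000)
        pop = [make_sv("POP", DUP, "c", 10_000, 20_000)]
        survivors, _ = vf.filter_structural_variants(
            [sv], pop, self.full_cov, self.no_gaps, set(), set()
        )
        assert len(survivors) == 1

    def test_low_coverage_window(self):
        cov = {"c": [30.0] * 5 + [8.0] + [30.0] * 14}
        sv = make_sv("S", DEL, "c", 48_000, 62_000)  # spans window 5
        survivors, reasons = vf.filter_structural_variants(
            [sv], [], cov, self.no_gaps, set(), set()
        )
        assert survivors == [] and vf.SV_LOW_COVERAGE in reasons[0]

    def test_gap_overlap(self):
        gaps = IntervalSet([GenomicInterval("c", 15_000, 16_000)])
        sv = make_sv("S", DEL, "c", 10_000, 20_000)
        survivors, reasons = vf.filter_structural_variants(
            [sv], [], self.full_cov, gaps, set(), set()
        )
        assert survivors == [] and vf.SV_GAP in reasons[0]

    def test_del_dup_same_sample(self):
        dele = make_sv("S", DEL, "c", 10_000, 20_000)
        dup = make_sv("S", DUP, "c", 15_000, 30_000)
        survivors, reasons = vf.filter_structural_variants(
            [dele, dup], [], self.full_cov, self.no_gaps, set(), set()
        )
        assert dup in survivors
        assert vf.SV_DEL_DUP in reasons[0]

    def test_whitelisted_gene_keeps_sv(self):
        dele = make_sv("S", DEL, "c", 10_000, 20_000, genes={"ETV6"})
        dup = make_sv("S", DUP, "c", 15_000, 30_000)
        survivors, _ = vf.filter_structural_variants(
            [dele, dup], [], self.full_cov, self.no_gaps, set(), {"ETV6"}
        )
        assert dele in survivors

    def test_excluded_genes(self):
        sv = make_sv("S", DEL, "c", 10_000, 20_000, genes={"IGH"})
        survivors, reasons = vf.filter_structural_variants(
            [sv], [], self.full_cov, self.no_gaps, {"IGH"}, set()
        )
        assert survivors == [] and reasons[0] == {vf.SV_EXCLUDED_GENE}


class TestReplicateConcordance:
    def test_identical_triplicates(self):
        s = {("c", 1, "A", "T"), ("c", 2, "G", "C")}
        assert vf.replicate_concordance([set(s), set(s), set(s)]) == (1.0, 0.0, 0.0)

    def test_partial_overlap(self):
        # union {a,b,c}: a in all three sets, b and c in exactly one each
        a, b, c = "a", "b", "c"
        assert vf.replicate_concordance([{a, b}, {a, c}, {a}]) == pytest.approx(
            (1 / 3, 0.0, 2 / 3)
        )

    def test_exactly_two(self):
        fr = vf.replicate_concordance([{"a", "b"}, {"a", "b"}, {"a"}])
        assert fr == pytest.approx((1 / 2, 1 / 2, 0.0))

    def test_fractions_sum_to_one(self):
        fr = vf.replicate_concordance([{1, 2, 3}, {2, 3, 4}, {3, 5}])
        assert sum(fr) == pytest.approx(1.0)

    def test_wrong_count_errors(self):
        with pytest.raises(ValueError):
            vf.replicate_concordance([{1}, {1}])

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            vf.replicate_concordance([set(), set(), set()])
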