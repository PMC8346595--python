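# clonokit

Tools for relapse-oriented tumor/germline whole-genome cohort analysis:
somatic-variant filter cascades, mutational-signature extraction and
parsimonious reference-set selection, non-coding regulatory hotspot
detection, a driver-gene rule engine, clonal-evolution trajectory
classification, and cohort statistics — plus a synthetic-data generator
that produces every input the pipeline consumes.

## Modules

| module | what it does |
|---|---|
| `clonokit.core_model` | Domain types (variants, intervals, sample metadata), VCF/BED/FASTA/table readers and writers. Internal coordinates are 0-based half-open. |
| `clonokit.synthetic_data` | Seeded generators: signature-mixture 96-channel catalogs, clone trees with sum-rule-consistent prevalences, binomial read counts, artifact variants violating each filter rule, and a toy reference genome with planted features. |
| `clonokit.variant_filters` | The six-rule downstream SNV/indel filter cascade (depth anomaly, AF floor, repeats, homopolymers, indel proximity, population presence), structural-variant filters, replicate concordance. |
| `clonokit.signature_analysis` | 96-channel catalogs, de novo NMF with RSS-elbow rank selection, cosine matching against a reference signature set, staged parsimonious selection with paired t-test equivalence, NNLS refitting. |
| `clonokit.regulatory_hotspots` | Regulatory/population gating of non-coding SNVs and complete-linkage recurrence clustering under a strict 100 bp diameter rule. |
| `clonokit.driver_rules` | Five-criterion driver-gene calls with the known-driver shortcut; timepoint summaries; biallelic-hit detection. |
| `clonokit.clonal_trajectories` | Binomial-mixture VAF clustering over joint timepoints (BIC model selection), clone-tree enumeration under the pigeonhole sum rule with bootstrap consensus, and persistent / rising / founding / undetermined trajectory classification, including deep-resequencing reassignment and relapse-to-relapse intervals. |
| `clonokit.cohort_stats` | Exact two-sided Fisher test, cohort tallies over the shipped 29-patient tables, burden summaries, markdown report. |

The 29-patient clinical and trajectory tables ship as TSV fixtures in
`src/clonokit/data/` and load via `clonokit.core_model.load_cohort_fixture()`.

## CLI

```bash
clonokit simulate --seed 1 --out bundle/            # synthetic input bundle
clonokit filter-snv --vcf bundle/SIM_001.vcf --patient SIM_001 \
    --reference bundle/reference.fa --repeats bundle/repeats.bed \
    --population bundle/population.vcf --out filtered/
clonokit hotspots --vcf a.vcf --vcf b.vcf --regulatory reg.bed \
    --population pop.vcf --width 100 --min-patients 2 --out hotspots.tsv
clonokit signatures extract --catalog catalog.tsv --seed 1 --out sigs.tsv
clonokit signatures refit --catalog catalog.tsv --signatures sigs.tsv --out exposures.tsv
clonokit clonal --counts counts.tsv --purity diagnosis 0.8 --purity r1 0.7 --out clonal/
clonokit stats table-tallies
clonokit report --out report.md
```

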