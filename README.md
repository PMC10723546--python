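# tumourevo

Analysis toolkit for whole-genome-sequenced tumour cohorts: somatic-call
curation, non-coding driver recurrence testing, rearrangement hotspot
detection, molecular and chronological timing of copy-number events,
genome-instability metrics, and genetic immune-evasion classification —
plus a ground-truthed synthetic-cohort generator so the entire pipeline is
testable offline with no external data.

## Modules

| Module | What it does |
| --- | --- |
| `tumourevo.cohort_io` | Data model (variants, segments, SVs, samples); VCF/TSV/BEDPE readers and writers; indel proximity filtering against a germline panel; multi-caller SV consensus; TMB; 96-class trinucleotide contexts |
| `tumourevo.synthetic_cohort` | Cohort simulator with configurable clonal/subclonal structure, timed gains (2+1, 2+0, 2+2, WGD), purity-diluted read counts, hotspot-enriched SV landscapes and planted driver/HLA/APG alterations; writes standard formats plus a ground-truth JSON |
| `tumourevo.driver_recurrence` | Negative-binomial recurrence testing of genomic elements against a trinucleotide-context background; pairwise Fisher co-occurrence / mutual-exclusivity tests; pathogenic-fraction comparison |
| `tumourevo.sv_hotspot` | Breakpoint binning, covariate-adjusted Poisson background (GLM), exact piecewise-constant fitting by dynamic programming, FDR-controlled hotspot calling, fragile-site flagging/exclusion |
| `tumourevo.event_timing` | Mutation multiplicity assignment, molecular-time estimators for clonal gains and WGD with bootstrap CIs, a two-phase mutation-rate chronology (molecular time ↔ years before sampling), clonality odds ratios, Bradley–Terry event ordering |
| `tumourevo.genome_instability` | Weighted genome instability index, WGD calling, arm-level alteration matrix and binomial enrichment test |
| `tumourevo.immune_escape` | Segment-based HLA-LOH call, HLA mutation flag, antigen-presenting-gene inactivation, combined escape classification |

## Command line

The `tumourevo` entry point exposes the pipeline stages:

```bash
tumourevo simulate-cohort --n-samples 10 --seed 1 --out cohort/
tumourevo curate-indels somatic.vcf germline.vcf --window-bp 10 --out kept.vcf
tumourevo consensus-sv manta.bedpe lumpy.bedpe delly.bedpe \
    --callers manta,lumpy,delly --min-callers 2 --out consensus.bedpe
tumourevo tmb sample.vcf --callable-mb 3000
tumourevo sv-hotspots cohort.bedpe --genome genome.tsv --fdr 0.05 --out hotspots.tsv
tumourevo time-events sample.vcf segments.tsv --purity 0.8 --age 60 \
    --clock-rate 0.05 --acceleration 5 --initiation-lead 10
tumourevo cna-metrics segments.tsv --ploidy 2.1 --genome genome.tsv
tumourevo immune-escape sample.vcf segments.tsv --hla-locus chr6:29941260-29949572
tumourevo cooccurrence matrix.tsv --fdr 0.05
tumourevo test-noncoding counts.tsv --fdr 0.05
```

## Conventions

- VCF positions and copy-number segment bounds are 1-based inclusive;
  BED/BEDPE-style intervals and genome bins are 0-based half-open.
- All randomness flows through `numpy.random.default_rng` seeds; simulator
  outputs are byte-reproducible for a fixed seed.
- Segment tables use the columns
  `chrom  start  end  major_cn  minor_cn  clonal_fraction`.
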