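# myelopanel

Tumor-only variant interpretation for ultra-deep targeted myeloid gene-panel
sequencing.

Clinical AML cohorts are often sequenced on a 54-gene myeloid amplicon panel
at ~5000x from peripheral blood, **without a matched normal sample**. That
leaves three questions no caller answers by itself: which of the called
variants are somatic, which germline variants plausibly predispose to
disease, and how co-existing somatic mutations are organized into clones.
`myelopanel` is a tested, reusable pipeline for exactly this setting, aimed
at bioinformaticians analyzing tumor-only panel cohorts.

## The model

For a blood specimen whose tumor content is the circulating-blast fraction
*b*, a heterozygous somatic variant carried by a clone with cancer-cell
fraction *f* has expected variant allele fraction

```
E[VAF] = b · f / 2        (×2 at hemizygous X-linked sites in males)
```

while germline heterozygotes sit near 0.5 and homozygotes near 1.0. The
pipeline therefore:

1. filters calls by quality (`QUAL ≥ 50`, `DP ≥ 20`, `GQ ≥ 20`) and rarity
   (population AF < 1% in both gnomAD and 1000 Genomes; common variants are
   kept aside for pharmacogenomics);
2. classifies each rare call **somatic** iff `VAF < b/2` (strict), per case;
3. orders each case's co-existing non-silent somatic mutations into a
   founding clone and subclones by VAF gaps (join the founding clone when
   `max VAF − VAF ≤ 0.1`);
4. prioritizes germline variants through a multi-evidence cascade (ClinVar
   pathogenic, protein-truncating, splice-disrupting, frameshift, or
   SIFT-deleterious ∧ PolyPhen2-damaging missense, behind a GMAF < 1% gate;
   CADD ≥ 20 is reported as support, never as a gate);
5. computes cohort statistics: region/impact tables, nonsyn/syn ratio
   against a reference cohort, recurrence lists, a Kruskal–Wallis + Dunn
   per-case mutation-burden screen, somatic×germline co-occurrence, and a
   pharmacogenomic genotype table (bundled rule: TP53 rs1042522).

A synthetic cohort generator (`myelopanel.simulate`) emulates the whole
design — blast fractions, clone structure, binomial read noise at ~5000x,
hemizygous X sites, annotation fields — with a truth table, so every stage
is testable without access to patient data. See `docs/methods.md` for the
model details and its limitations.

## Worked example

```
$ myelopanel simulate --seed 7 --n-cases 26 --out demo/sim
wrote 26 cases, 2074 variants to demo/sim
$ myelopanel report --manifest demo/sim/manifest.tsv \
    --variants demo/sim/cohort.annotated.tsv --out demo/report
report written to demo/report (1965 QC-passing variants, 42 somatic)
```

`demo/report/report.txt` then contains (abridged):

```
Cases: 26
QC-passing variants: 1965
...
nonsyn/syn ratio: 1.18 (481/409)

Somatic mutations: 42 (39 SNVs, 3 indels; 1.62 mutation/case)
  non-silent: 13   silent: 29
...
Cases with any non-silent somatic or prioritized germline mutation: 23 (88.46%)
  both: 9  somatic only: 1  germline only: 13  neither: 3

Pharmacogenomics rs1042522 (TP53): 16 of 26 cases (62%) carry a risk genotype [C/G, G/G]
```

Reading this: of ~2000 QC-passing calls, most are germline panel
polymorphisms; 42 sit below their case's `b/2` cutoff and are called
somatic (1.62 per case); 23 of 26 cases carry at least one non-silent
somatic or prioritized germline event; and 16 cases carry a TP53 P72R
genotype associated with decreased chemotherapy response. The same numbers
are written machine-readably to `cohort_summary.json`, per-variant labels to
`classified_variants.tsv`, and the run configuration with input checksums to
`run_manifest.json`.

The library surface mirrors the CLI: `simulate_cohort`, `apply_qc_filter` /
`apply_popaf_filter`, `classify_origin` / `assign_clones`,
`prioritize_germline`, `burden_test`, `summarize_cohort`, `run_pipeline`.

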