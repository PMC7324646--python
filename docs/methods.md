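# Methods

## Problem and model

`myelopanel` interprets ultra-deep (~5000x) targeted amplicon-panel variant
calls from blood of acute myeloid leukemia (AML) cases sequenced **without a
matched normal** (tumor-only). The panel covers 54 genes recurrently mutated
in myeloid neoplasms. Given per-case calls and their functional annotations,
the pipeline must decide which variants are somatic, which germline variants
plausibly predispose to disease, how co-existing somatic mutations are
organized clonally, and what the cohort looks like in aggregate.

### Somatic/germline separation

In a blood specimen whose tumor content is the circulating-blast fraction
*b* (blast percent / 100), a heterozygous somatic variant carried by a clone
with cancer-cell fraction (CCF) *f* has expected variant allele fraction

    E[VAF] = b * f / 2          (doubled at hemizygous X-linked sites in males)

while autosomal germline heterozygotes sit near 0.5 and homozygous or
hemizygous germline variants near 1.0 regardless of *b*. A variant is
classified **somatic** when `VAF < b/2`, strictly; the boundary is germline.
The rule is deliberately stringent: a fully clonal heterozygous somatic
variant sits *at* the cutoff in expectation and can be missed, which is the
price of tumor-only analysis. Two caveat flags are attached rather than
silently ignored: `hemizygous_x_male` (X-linked site in a male, where a
somatic VAF is doubled and may be misrouted to germline) and
`untestable_low_blast` (the threshold falls below 3 alt reads at the site's
depth, i.e. below read-count resolution).

### Staged filtering

1. **QC**: remove calls with `QUAL < 50`, `DP < 20` or `GQ < 20`. Removal
   conditions are strict `<`, so equality at a threshold is retained.
2. **Rarity**: route to the *common* set any call with population allele
   frequency `>= 1%` in **either** gnomAD or 1000 Genomes; a missing
   frequency never makes a variant common (ultra-rare variants are often
   absent from both databases). The common set is not discarded: it skips
   somatic/germline interpretation but stays visible to the pharmacogenomic
   lookup, which must see common polymorphisms such as TP53 rs1042522.

### Clonal ordering

Within a case, co-existing non-silent somatic mutations are ordered by VAF.
The highest-VAF mutation anchors the founding clone; a mutation joins it
when its gap to the maximum VAF is at most `delta_threshold` (default 0.1),
otherwise it is a subclone. The default is the round midpoint of the gap
that separates observed same-clone pairs (ΔVAF <= 0.055) from
founding/subclone pairs (ΔVAF >= 0.134) in the cohort this pipeline was
designed around; any value in (0.055, 0.134) gives the same assignments
there. The reasoning is ordinal by design — no mixture model or CCF
estimation is attempted, matching the resolution the data support at one
specimen per case.

### Germline prioritization

A germline-classified variant is **prioritized** when it passes the global
minor-allele-frequency gate (all known population AFs `< gmaf_cutoff`,
default 0.01; missing passes) **and** carries at least one evidence class:

- ClinVar pathogenic or likely pathogenic;
- protein-truncating (stop-gain/stop-loss);
- splice-disrupting;
- frameshift insertion/deletion;
- missense called deleterious by SIFT **and** damaging by PolyPhen2
  (`possibly_damaging` counts by default; a switch restricts to
  `probably_damaging`).

CADD (`>= 20`) is reported as supporting evidence but never gates the
verdict: the cascade's hard evidence classes are the functional ones, and a
second missense meta-score would double-count. Missing SIFT/PolyPhen2 on a
missense variant yields a `missing-evidence` note, not an error.

### Cohort statistics

- **Recurrence**: somatic mutations grouped by (gene, protein change) for
  coding variants and by genomic identity otherwise; groups seen in >= 2
  distinct cases are reported, split non-silent/silent. Prioritized germline
  variants are grouped the same way, plus a "multi-hit gene" list (genes
  with >= 2 distinct prioritized variants — independent events rather than
  recurrence of one allele).
- **Burden test**: the replicate unit is the vector of per-gene somatic
  counts within a case (54 values per case) — a per-case scalar would admit
  no rank test at all. A Kruskal-Wallis omnibus test runs across cases; if
  it rejects at `alpha` (default 0.01), all pairwise Dunn post hoc tests are
  computed (pooled mid-ranks, tie-corrected variance
  `N(N+1)/12 - sum(t^3 - t)/(12(N-1))`, two-sided normal p) and corrected
  with Bonferroni (Benjamini-Hochberg available). A case is flagged when it
  beats a **majority** of the other cases at adjusted p < alpha with the
  higher mean rank; the majority rule makes the flag mean "this case's
  burden exceeds the cohort", not "one lucky pair".
- **Silence partition**: missense, stop-gain/loss, splice-site and
  frameshift events are non-silent; synonymous, UTR, intronic,
  up/downstream and in-frame (non-frameshift) indels are silent. In-frame
  indels do alter protein sequence; the default keeps them silent to match
  panel-reporting convention, and `nonframeshift_silent=False` moves them.
- **Conservation**: PhyloP `> 4` high, `1 <= PhyloP <= 4` moderate, `< 1`
  non-conserved, missing stays missing. The interval endpoints follow the
  only reading that tiles the line.
- **Pharmacogenomics**: per rule (rsID, risk genotypes, drug annotation),
  each case is genotyped from its QC-passing call — het -> ref/alt,
  hom-alt -> alt/alt, hemizygous -> single allele, no call -> hom-ref —
  and carriers of any risk genotype are counted. The bundled default rule is
  TP53 rs1042522 (G>C), whose G/G and G/C genotypes associate with decreased
  response to cisplatin, paclitaxel, capecitabine and oxaliplatin.
- **Rendering**: percentages use decimal round-half-up at report time; raw
  fractions are always kept in the JSON.

## Synthetic cohorts

The generator (`myelopanel.simulate`) emulates the study design so every
stage is testable with known truth:

- **Cases**: default 26, blast percent uniform on 20-90%, ~58% male.
- **Depth**: mean-preserving lognormal around 5000x (sigma 0.25), matching
  ultra-deep amplicon panels' heavy-tailed coverage; 1% of calls get a
  shallow depth (< 20) to exercise the DP filter, and 2% each get low QUAL
  or low GQ.
- **Counts**: per-case germline and somatic counts are Poisson (defaults 80
  and 1.5 per case) — the simplest count model at these rates.
- **Genotypes and VAFs**: germline het/hom-alt at 85/15; X-linked genes in
  males are hemizygous (expected VAF 1.0 germline, doubled somatic).
  Read support is `Binomial(depth, E[VAF])`.
- **Tumor content**: the specimen's tumor-DNA fraction is
  `specimen_purity x blast_fraction` with `specimen_purity = 0.85`: the
  morphological blast count overestimates the tumor fraction of extracted
  DNA because normal leukocytes dilute it. This keeps fully clonal somatic
  VAFs strictly below the `b/2` cutoff — consistent with observed tumor-only
  panels, where detected somatic VAFs sit clearly under half the blast
  fraction — and makes classifier recovery well-defined. `expected_vaf()`
  itself is purity-agnostic; the factor enters only through the tumor
  fraction the simulator passes it.
- **Clones**: one candidate subclone per case with CCF uniform on
  (0.1, 0.6); each somatic variant joins it with probability 0.3, else the
  founding clone (CCF 1).
- **Annotations**: region/impact categories drawn from a fixed mix (half
  non-coding, missense slightly above synonymous); ~60% of germline calls
  get a common population AF (>= 1%) and the rest are rare or absent, so
  both rarity branches are exercised; SIFT/PolyPhen2/CADD/PhyloP/ClinVar
  fields are drawn with realistic missingness. Positions are synthetic
  integers inside per-gene intervals on the genes' real chromosomes (chrX
  correctness matters); they are **not** genome coordinates.
- **PGx site**: TP53 rs1042522 genotypes in Hardy-Weinberg proportions at
  alt-allele frequency 0.52 (chosen from the worked example's genotype
  split: 7/26 C/C homozygotes).

What the generator does **not** model: sequencing error, mapping and PCR
artifacts, strand bias, copy-number alteration, contamination, related
individuals, or a real reference genome. Passing recovery tests therefore
demonstrates the statistical geometry of the classifier under binomial
noise, not robustness to artifact-heavy real panels.

## Problem sizes and numerical choices

- Classifier recovery runs on three default 26-case cohorts (~2000 calls
  each); the exact-tail check uses 3000 draws at depth 5000 and blast 100%,
  compared with `P(X < 2500 | Bin(5000, 0.5))` within Monte-Carlo error.
- Burden calibration uses 500 null replicates of a 26x54 Poisson(0.5) count
  table; the planted alternative doubles two cases to Poisson(3.0) means.
- Filter oracles use 1000 random records x 20 random threshold settings.
- Degenerate inputs: zero-depth calls are skipped with a warning at read
  time (VAF undefined); an all-identical burden table returns omnibus p = 1
  with no flags; zero synonymous count reports the nonsyn/syn ratio as
  undefined, never infinity; an rsID absent from the cohort reports zero
  alt carriers rather than erroring.

## Known limitations

- The worked-example tables carry two internal inconsistencies of the
  source material, kept verbatim rather than reconciled: the region view
  (exonic 146, total 293) and the coding-impact view (summing 147) differ
  by one variant (the splice pair straddles the views; the report folds
  splice-region counts into the rendered Exonic row and says so in a
  footer), and the headline silent-somatic count ("17") disagrees with its
  own category enumeration (15), which is what the totals (23 + 15 = 38)
  support.
- Tumor-only somatic calling by a VAF threshold cannot see copy-number
  context; hemizygous and CN-altered sites are flagged, not resolved.
- The burden test's replicate unit (per-gene counts) treats genes as
  exchangeable replicates within a case; panel genes differ in target size,
  so the test is a screen, not an estimate of mutation rate.
- The healthy-reference nonsyn/syn count table is consumed as input; the
  bundled example pair is a synthetic stand-in with ratio 0.88 and no
  population provenance.
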