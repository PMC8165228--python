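# Methods

`oncotriage` re-implements, as a reusable and fully testable pipeline, a
post-calling somatic-variant triage and interpretation workflow for small
tumor cell-line cohorts — the setting is a panel of eight canine
osteosarcoma cell lines plus one matched FFPE tumor/normal pair, profiled
by whole-exome sequencing (150 Mb capture design) and RNA-seq. The package
starts downstream of the variant caller and the read aligner: its inputs
are annotated variant tables (or minimal VCFs), gene catalogs, a
pathogenicity-oracle table, and a gene-level count matrix.

## The triage cascade

Annotated somatic calls pass through three tiers of increasing stringency.

**Level 1 — quality-filtered exonic variants.** A call survives when it is
exonic and has alternate-read count ≥ 2, alternate-allele fraction ≥ 0.05,
read depth strictly > 10, and is neither a catalogued SNP nor present in
the panel-of-normals blacklist. The depth cut-off is deliberately strict
(`> 10`, not `≥ 10`): a variant covered by exactly ten reads is excluded.
Synonymous variants are *retained* at this level — they count toward
mutational burden — and are tagged for downstream exclusion. Quality-passing
5′UTR and splice-site variants are not part of Level 1 (which is
exonic-only) but are held in a side channel for the Level-3 rescue; they
never enter TMB.

**Level 2 — protein-modifying subset.** Synonymous and unknown-consequence
variants are dropped (the treatment of "unknown" is configurable via
`keep_unknown`; excluded by default since missense, stop, and frameshift
classes are the protein-modifying ones). Each surviving variant is
annotated with (a) its sample-wise recurrence — the number of distinct
*cell-line* samples carrying the identical genomic key
`(chrom, pos, ref, alt)`; recurrence counts samples, never reads, and FFPE
samples are excluded by default — and (b) membership of its gene in the
disease-associated gene list. These are annotations consumed by the driver
catalog, never exclusion filters.

**Level 3 — cancer-census subset with non-coding rescue.** The union of
Level-2 variants whose gene is in the role-annotated cancer-gene census
and side-channel UTR5/splice variants of census genes (re-checked against
the Level-1 quality thresholds). Genes represented only by UTR5/splice
variants are flagged `noncoding_only`.

Variant identity throughout is the genomic key; HGVS strings are carried
as annotations only, which makes recurrence robust to annotation-dialect
differences.

## Hotspot cross-referencing

Protein changes are parsed from simple HGVS substitutions (one- or
three-letter, normalized to one-letter). A catalog entry carries a human
hotspot (gene, ref AA, position, alt AA) plus a per-gene
`species_codon_offset` = human position − query-species position; a match
requires identical gene and amino acids with
`query_position + offset == human_position`. The shipped catalog encodes
the TP53 cross-species hotspot (canine E273K ↔ human E285K, offset +12).
Non-substitution protein changes (frameshifts, indels) are skipped and
counted. Matching is performed on the protein change only — the cDNA
strings in the source driver table are internally inconsistent with the
protein notation (e.g. `c.818C>T` alongside p.E273K), so no cDNA
arithmetic is attempted.

## Landscape statistics

- **TMB** = per-sample Level-1 variant count (synonymous included) divided
  by the capture size in Mb (default 150, configurable). Mean, median,
  min, and max are reported over cell lines; FFPE samples are listed
  separately. Both mean and median are reported; no attempt is made to
  prefer one.
- **Mutation-type distribution**: counts and proportions per functional
  class, pooled and per sample; the per-sample average is the unweighted
  mean of per-sample proportions.
- **SNV spectrum**: single-base substitutions collapsed onto the six
  pyrimidine classes (G>A counted as C>T, etc.); indels are ignored but
  counted so totals are conserved; the dominant class breaks ties
  lexicographically.
- **Pathogenicity fractions**: the pathogenicity predictor is represented
  by a table-driven oracle file mapping (gene, protein change) to
  deleterious/neutral/unknown — the predictor's internals are out of scope
  and deliberately pluggable. Fractions are computed over SNVs of a chosen
  functional class; oracle calls of "unknown" are excluded from numerator
  and denominator by default (configurable to count as non-pathogenic).
  Percentages are reported to one decimal with half-up rounding.

## Driver cataloguing

Recurrence is reported at variant level and at gene level (union of
samples over the gene's variants, so a gene can be recurrent when none of
its variants is) — both statistics are computed and reported distinctly
because they answer different questions, and "recurrent variants collapsed
to genes" is a third, again distinct, count. Census roles partition genes
into oncogene / tumor-suppressor / fusion / dual-role / unannotated; the
dual role is its own class, never double-counted, so counts always sum to
the number of input genes. The oncoplot matrix is gene × cell-line with
cells holding the set of functional classes observed; rows are ordered by
incidence (descending, then symbol). No statistical driver-significance
testing (dN/dS-style background models) is performed: prioritization is by
catalog membership, matching the workflow this package reproduces.

## Expression integration

Counts are filtered (unnormalized CPM ≥ 1 in ≥ 2 samples by default) and
normalized with TMM re-implemented from the published algorithm: reference
sample = the one whose 75th-percentile count fraction is closest to the
cohort mean; per-sample log2 ratios against the reference trimmed 30%
(log-ratio) and 5% (abundance) on each side using average-tie ranks; the
precision-weighted mean of retained ratios (inverse asymptotic binomial
variances) gives the factor; factors are rescaled to geometric mean 1. The
30%/5% trims are the standard published values. The implementation is
verified in the test suite against factors computed independently with
edgeR's `calcNormFactors` on a frozen simulated matrix (agreement to
≈1e-8).

Fold-changes use `(CPM + 0.25) / (median baseline CPM + 0.25)` with the
baseline defaulting to the leave-one-out median over the other samples
(an explicit baseline set can be supplied); the pseudo-CPM keeps ratios
finite at zero baselines and is configurable. The upstream study states
fold directions but no baseline or pseudo-count convention, so these are
pipeline choices recorded in every profile.

Mechanism rules combine mutation status with fold-changes per sample:

- `tp53_hotspot_lof` — TP53 hotspot match present and MDM2 (a direct p53
  transcriptional target) at or below the under-expression cut-off
  (default 0.5×): mutant p53 no longer transactivates its own negative
  regulator.
- `tp53_mdm_overexpression` — no TP53 coding mutation, and MDM2 or MDM4
  at or above the over-expression cut-off (default 2×): p53 silenced by
  its inhibitors.
- `met_mapk_activation` — MET ≥ 2× and at least two of {MAPK1, MEK, MYC}
  ≥ 1.5×; no coding mutation in the downstream genes is required. "MEK"
  is resolved through an alias table (MAP2K1/MAP2K2/MEK1/MEK2).

The numeric cut-offs are pipeline defaults (the biology states directions,
not numbers); every comparison is recorded in the flag's evidence list, so
flags are reproducible functions of (matches, profiles, thresholds). A
sample may carry several flags; a sample with none gets an explicit
`none` record.

## Synthetic data

The generator produces cohorts with the statistical structure the analysis
assumes, so every stage is testable without sequence data:

- Eight cell lines (Penny, Wall, Sky, Desmond, Pedro, D17, D22, Lord) plus
  an optional FFPE tumor/normal pair; 1,444 quality-passing exonic
  variants per tumor sample by default, so eight cell lines at 150 Mb give
  a mean TMB of 9.6 mutations/Mb and a cohort Level-1 total of ≈11.5k.
- Mutation-type weights default to missense 0.387, frameshift insertion
  0.158, frameshift deletion 0.125, synonymous 0.196, with the remainder
  split across stop/non-frameshift/unknown classes; the spectrum defaults
  to C>T-dominant (0.45) with transitions outweighing transversions.
  Planted missense variants are debited from the multinomial fill so
  realized mixtures match the weights.
- Pass/fail status is **constructed, not sampled**: depths and alternate
  counts are assigned so each variant passes everything or fails exactly
  one named criterion (depth ≤ 10; alt count 1 at depth 11–19 so the
  fraction still passes; fraction ≤ 0.025 via 2 reads at depth ≥ 80;
  known-SNP or blacklist flags on otherwise-passing calls). The
  ground-truth record names the failing criterion per variant, making
  filter tests exact rather than probabilistic.
- 234 recurrent variant keys planted across 3–8 cell lines each; a TP53
  p.E273K driver planted in Wall and its FFPE twin; UTR5/splice variants
  split between census and non-census genes for the Level-3 rescue. The
  mechanism-panel genes never mutate unless explicitly planted, so
  wild-type status is controlled.
- The oracle labels each distinct missense (gene, protein change) pair
  deleterious at rate 0.505 (planted drivers always deleterious).
- Expression counts are negative-binomial (dispersion 0.005) with planted
  multiplicative folds — 9× MDM2, 5.5× MDM4, and 19× MET in D17/D22, MDM2
  depleted to 0.2× in Wall, TP53 and MAPK-pathway genes moderately
  elevated — on a high fixed baseline mean (2,000) for the panel genes so
  planted folds are recoverable within sampling noise, and log-normal
  baselines for background genes.

What the generator does **not** emulate: per-sample burden heterogeneity
(each tumor sample gets the same passing budget, so the generated TMB
range is degenerate at 9.6 while real panels spread widely),
trinucleotide-context spectra, realistic genome coordinates (positions are
collision-free within an arbitrary gene model), linkage between mutation
and expression beyond the explicitly planted configurations, and read-level
artifacts. Passing tests therefore demonstrate correctness of the
bookkeeping and recovery of planted structure under the stated noise
model — not calling accuracy on real sequencing data.

## Numerical choices and degenerate inputs

Percentages: half-up rounding to one decimal. Spectrum dominance: ties
break to the first class in C>A…T>G order. Empty variant sets yield
zero-count results flagged undefined rather than dividing by zero; a zero
denominator in a pathogenicity fraction is flagged, never divided. TMM
requires ≥ 2 samples and errors on an all-zero sample by name; a sample
pair with no co-expressed genes falls back to factor 1. Duplicate catalog
symbols keep the first entry with a warning; duplicate count-matrix gene
rows are summed, duplicate sample columns are an error. The driver-table
fixture preserves the source's cDNA strings verbatim (including apparent
typos such as reversed deletion coordinates, interpreted by absolute
span) and carries a protein change only where the source states one
(TP53 p.E273K), inventing no annotations.

## Problem sizes

The default test suite runs the full generator (≈16.6k variant calls,
2k-gene count matrices) in seconds; property suites use random cohorts of
≤ 1,000 variants; the acceptance script re-generates the full-scale
cohort and expression matrix from the supplied seed and completes in a few
seconds.
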