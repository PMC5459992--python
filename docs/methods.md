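# Methods

This package re-implements, at desk scale and on synthetic data, the two
bespoke computations of a rat cocaine self-administration / sperm methylome
study design: (1) classification of rats into addiction-like ("Addict") and
non-addiction-like ("Non-addict") groups from operant behaviour, and (2)
identification of sperm CpG-methylation differences between those groups
that are maintained from the exposed generation (F0) into their offspring
(F1), with downstream enrichment, profile and ordination summaries and an
overlap against offspring-brain differential expression. This note records
the models, the defaults and why, and what the synthetic experiments do and
do not demonstrate.

## Behaviour model and scoring

Animals acquire cocaine self-administration under fixed-ratio schedules
(FR1, FR3, FR5: 1/3/5 active-lever presses per infusion) and are then
probed with a progressive-ratio (PR) session in which the press requirement
for the i-th infusion is

    requirement(i) = floor(5 · e^(0.25 i) − 5),

so requirements run 1, 3, 5, 8, 12, 17, 23, 31, ... The **break point** is
the requirement of the last infusion earned and indexes motivation. The
notation of the source formula is `Int(·)`; we read `Int` as floor
(truncation for positive arguments). Progressive-ratio conventions differ
between labs, so the rounding mode is a switch on `PRSchedule`
(`floor` default, `nearest` available).

Each animal's mean FR5 active-lever pressing and its break point are
z-scored within the cohort,

    z_i = (x_i − x̄) / s,     combined_i = z_fr5,i + z_bp,i,

and the cohort is cut on the combined score: the top 25% of animals are
labelled Addict and the bottom 40% Non-addict (floor counts; ties broken by
score then animal id, so labelling is deterministic). `s` is the sample
standard deviation (n−1) by default, switchable to the population form via
`ddof` — the source description is ambiguous between the two; with cohorts
of n ≥ 100 the difference is negligible. Group break points are compared
with a Mann–Whitney rank-sum test: full enumeration of rank assignments
(midranks under ties) when n_a + n_b ≤ 12, otherwise the normal
approximation with tie and continuity corrections.

## Methylome model

Input is one bismark-style coverage table per sperm sample (chromosome,
position, % methylation, methylated count, unmethylated count) plus sample
metadata (generation F0/F1; phenotype Saline/Addict/Non-addict).
Coordinates are converted once at the I/O boundary (`coord_base=1` default)
and held 0-based internally; BED outputs are 0-based half-open.

Sites are filtered to those covered by ≥ 5 reads in more than 6 of the 16
samples (defaults `min_coverage=5`, `min_samples_detected=7`). Per
generation, read counts are pooled within the Addict and Non-addict groups
and each CpG is tested with a **two-sided Fisher exact test** on the 2×2
table (methylated/unmethylated × Addict/Non-addict), with
Benjamini–Hochberg correction across tested sites; `significant` means
q ≤ 0.05 by default (`use_fdr=False` thresholds raw p instead).
**Maintained differences** are CpGs significant in both F0 and F1 with the
same sign of the Addict−Non-addict level difference. Pooling across
samples is a deliberate simplification: it makes every p-value exactly
checkable against hypergeometric enumeration, but it ignores
between-animal variation, so when the observed between-sample variance of
methylation levels exceeds 3× the binomial expectation a warning is logged
(see Limitations).

Downstream summaries:

* **Element annotation** — promoter = closed window TSS ± 2,000 bp around
  the strand-aware TSS; precedence promoter > exon > intron > intergenic;
  a site in several promoters resolves to the nearest TSS. Gene models are
  read from BED12.
* **Hypomethylation flag** — true when the maximum per-sample methylation
  fraction at a site is ≤ 0.3 (inclusive); undefined (and excluded from
  enrichment denominators) when no sample covers the site.
* **Enrichment** — 2×2 odds ratio with a 95% Wald CI on the log scale,
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), with the Haldane–Anscombe +0.5
  correction when any cell is zero, plus the Fisher two-sided p.
* **Metagene profile** — per sample group, pooled site-level methylation
  averaged in bins over a fixed-width upstream flank (2,000 bp), the
  gene body rescaled to [0,1], and a downstream flank; 20 bins per zone by
  default; minus-strand genes are reversed; empty bins are reported as
  missing, never zero; genes shorter than one bin are skipped.
* **Ordination** — classical (Torgerson) multidimensional scaling of the
  per-sample methylation-fraction vectors on Euclidean distances,
  complete-case sites by default (site-mean imputation behind a flag);
  coordinates are centred, and each dimension's first nonzero loading is
  made positive so embeddings are reproducible.

## Expression overlap

The offspring-brain differential-expression table (gene, linear fold
change, p) is filtered at fold change ≥ 2 (inclusive) and p < 0.05
(exclusive); direction "up" means higher expression in Non-addict.
Maintained CpGs map to genes through promoter annotation only by default
(exonic/intronic CpGs behind `include_gene_body=True`). The overlap between
the maintained-promoter gene set and the DE gene set is scored with the
upper-tail hypergeometric probability over the universe of genes present in
both the gene model and the DE table.

## Synthetic data: what it emulates

The generator exists so every stage can be verified against planted truth.

*Behaviour*: each rat has a latent motivation m ~ N(0, 0.4) acting on the
log scale: FR5 session presses ~ NegBin(mean 150·e^(0.5 m), dispersion 8),
and the PR ladder is run against a capacity 60·e^(0.5 m) presses (the
session's one-hour stopping rule appears only as this capacity cutoff; the
scorer trusts the logged infusion count). Session structure: 5×FR1, 2×FR3,
5×FR5, 1×PR.

*Methylome*: 16 samples in 5 groups (3/3/3 Saline/Addict/Non-addict F0,
3/4 Addict/Non-addict F1). Baseline methylation per CpG is bimodal,
π ~ 0.6·Beta(0.5, 10) + 0.4·Beta(10, 0.5), clipped to [10⁻³, 1−10⁻³];
coverage ~ NegBin(mean 30, dispersion 5); methylated counts are
beta-binomial with intra-site correlation ρ = 0.05. Cocaine-exposed F0
groups (Addict-F0, Non-addict-F0) receive a global logit shift of −0.3
(drug-induced demethylation); Saline-F0 and both F1 groups receive none.
200 of 10,000 sites are planted as differential: Addict samples are
shifted ±1.5 logits (sign random per site, Non-addict stays at baseline) —
in F0 for all planted sites and in F1 for the maintained 80% subset. True
effect sizes in the source system are unknown; these values are
parameter-recovery placeholders, not estimates. One master seed feeds
named, independently derived substreams (behaviour, baselines, planted
structure, counts, positions, gene model, DE table), so enlarging one
component never perturbs another's draws.

A small random gene model (~120 non-overlapping multi-exon genes on two
synthetic chromosomes) supports annotation, profiles and placement control
(planted/background sites can be drawn from promoter windows with set
probabilities). A synthetic DE table, in which genes carrying maintained
promoter DMCs are DE with elevated probability, lets the end-to-end
`report` command exercise the integration stage; it is plumbing, not a
model of RNA-seq noise.

Not emulated: raw bisulfite reads, PCR duplicates, conversion failure,
litter/pedigree structure, chromatin context, or any spatial correlation
between neighbouring CpGs.

## Problem sizes used in tests

The shipped test suite and the reproduction script run the generator at its
default design — 10,000 CpGs, 16 samples, 10 replicate seeds for
recovery/null/structure checks, cohorts of 134–200 animals, 20 seeds for
classifier recovery — which the package treats as its standard desk-scale
experiment; a real RRBS study is two orders of magnitude larger in sites.

## Limitations

* **Pooled Fisher is anti-conservative under overdispersion.** With
  between-animal correlation ρ = 0.05, the pooled proportion's variance is
  ~2.5× the binomial value, so null per-generation discovery rates at
  q ≤ 0.05 run near 1% of sites rather than ~0, and an occasional null site
  survives the F0∩F1 intersection. The `dmc_test` log warning flags this
  regime; with binomially distributed counts (ρ = 0) the test is exactly
  calibrated (covered by a unit test). A beta-binomial regression per site
  would fix calibration at the cost of oracle-checkability.
* **Power is concentrated at intermediate baselines.** At ~90–120 pooled
  reads per group, a 1.5-logit shift at baselines below ~0.02 or above
  ~0.98 changes the methylation fraction too little to detect; under the
  bimodal baseline roughly half the planted sites sit there. Recovery of
  maintained sites at the default design is therefore partial (~10% at
  q ≤ 0.05), and passing tests demonstrate correctness of the machinery and
  directionality of recovery, not high sensitivity on real data.
* The generation axis in the synthetic ordination is an exposure axis:
  Saline-F0 samples receive no generation-specific signal and embed among
  F1 samples; separation claims are therefore made for the exposed F0
  groups.
* Real-data headline counts of the source study (e.g. about 1.57 million
  filtered CpGs) arise from its animals and sequencing depth and are not
  reproduced at this scale; the deposited accession (GSE72401) can be run
  through the same entry points by exporting bismark coverage files, but
  nothing in the build or tests requires it.
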