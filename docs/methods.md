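# Methods

`tumorfidelity` asks a single question of a matched trio — germline DNA,
primary tumor, and a derived pre-clinical model (neurosphere culture,
adherent culture, or mouse xenograft): *is the model genetically faithful to
the tumor it came from?* It answers at two levels: somatic point mutations
(are the same mutations present, at compatible allele frequencies?) and
copy-number aberrations (are the same chromosomal gains and losses called?).
Everything is driven from pileup allele counts and exome-probe coverage; no
raw read alignment is performed.

## Somatic calling

At each candidate site the germline and tumor allele counts form a 2x2
table. The somatic test is a right-tailed Fisher exact test: conditioned on
the margins, the tumor alt count follows a hypergeometric law, and
`fisher_right_tail` returns P(tumor alt >= observed). A site is somatic when

- the Fisher p-value is at most 0.05,
- the germline alt fraction is at most 5% (germline variants mis-called
  somatic are the dominant contaminant of naive somatic call sets),
- both samples reach the coverage floor (default 8x) and the tumor carries
  at least 2 alt reads.

Indels use stricter floors — 10x tumor coverage, 3 supporting reads,
germline alt fraction below 5% — reflecting their higher artifact rate.
The coverage/support floors for SNVs and the 20% heterozygous threshold for
germline calls are configurable defaults (`CallThresholds`); they stand in
for an upstream caller's internal defaults that are not part of this
package's contract. LOH is called at germline-heterozygous sites whose
tumor allele balance departs from 0.5 with a two-sided Fisher p <= 0.05;
this minimal rule is a design choice, since only the call itself (not the
rule) is externally specified.

## Base-quality mixture filter

False-positive calls concentrate at low mean alternate-allele base quality,
producing a bimodal quality distribution among novel variants while
database-known variants stay unimodal. `fit_quality_mixture` fits three
1-D Gaussian families by EM — one component, two components with tied
variance, two with free variances — from a quantile-split start with 10
jittered restarts (tolerance 1e-8 relative log-likelihood, max 500
iterations), and selects by BIC. When a two-component model wins, sites
assigned to the lower-mean component are discarded; known variants are
exempt by default because the artifact mode lives in the novel calls.
Fitting refuses fewer than 50 observations: below that, BIC cannot
meaningfully distinguish the families. The per-iteration log-likelihood
trace is kept on the fit object so monotonicity is testable.

## Xenograft host-read removal

Xenograft DNA is a human/mouse mixture; mouse fragments captured by
orthologous probes and aligned to the human reference masquerade as somatic
variation. Each read is summarized against both genomes and classified by a
cascade: (1) mapped to one genome only — that species; (2) both mapped —
the properly paired genome wins; (3) pairing tied — the strictly greater
match score M = matches − mismatches wins; (4) exact tie — ambiguous.
Human calls are kept; mouse and ambiguous calls are dropped. Reading
"better alignment" strictly (ties discarded) is deliberately conservative:
a read that aligns equally well to both genomes sits in an orthologous
region where the allele evidence cannot be trusted. A SAM adapter derives
matches as aligned M/=/X bases minus NM and mismatches as NM, the portable
edit-distance field.

## Primary-vs-model comparison

Every site called somatic in either tumor sample is tested for a frequency
change with a two-sided Fisher exact test on (primary ref/alt vs model
ref/alt). The significance threshold is set by permutation: under the null
the pooled reads at a site are exchangeable between samples, so each
permutation re-splits the pooled alt reads between the two depths by
hypergeometric resampling and recomputes p. The estimated FDR at threshold
t is the mean null count of p <= t over the observed count, and the chosen
threshold is the largest observed p with estimated FDR <= 0.05. This
plug-in estimate (E[null discoveries]/observed discoveries) is used rather
than Benjamini–Hochberg because the per-site hypergeometric null respects
the granularity of exact-test p-values at modest depth.

Sites are then classified: detected in both samples (>= 2 alt reads and
>= 5% MAF) and non-significant — *shared constant*; detected in both and
significant — *shared changing*; detected in one with a significant
difference — *unique* to that sample; detected in one without significance
— shared constant, since absence of evidence at ~60x is not evidence of
absence. The detection floor mirrors the somatic caller's floors.

**Contamination.** At a copy-neutral heterozygous somatic site, normal-DNA
contamination c of the primary scales its MAF by (1 − c) relative to a pure
model, so ĉ = 1 − median(primary MAF / model MAF) over shared sites
(restricted to copy-neutral segments when segmentation output is supplied),
clamped to [0, 1]. The median-ratio form is this package's own
construction from first principles (pure model, MAF dilution); it recovers
simulated contamination levels of 0.09–0.41 with |error| <= 0.05 at 150
sites and 60x. The MAF correlation between primary and model is Pearson's
r over sites covered by >= 30 reads in both samples, with Spearman
available as an option.

## Copy-number calling

Per-probe logR = log2 of library-size-normalized tumor/normal coverage.
GC bias is removed per sample by dividing each probe's coverage by the
median of its GC bin (width 0.01, bins under 10 probes merged) and
rescaling by the global median. Probes with normal coverage below 10 are
not callable (nc).

Segmentation is recursive binary splitting in the circular-binary-
segmentation style: within a chromosome, split at the probe maximizing the
two-sample t statistic of mean logR, accept when the permutation p (>= 1000
label permutations, seeded) is <= 0.01, and recurse; runs under 5 probes
are never split. This is a from-scratch implementation of the segmentation
idea, not a parity port of any exome CNV tool — the downstream calling
rules, not the segmentation internals, are the contract.

Segments are neutral when |mean logR| <= 0.2 (the `neutral_band`; "copy
neutral" has no external definition, so the band is configurable), else
amp/del by sign. High-confidence (HC) grading compares a segment's mean
logR against the 95th/5th percentile of the per-probe logR distribution
inside neutral segments. An arm is called amp/del when more than 20% of its
targeted base pairs lie in segments consistently called in one direction;
mixed directions are counted separately so an amp/del patchwork cannot fake
an arm event. A segment is flagged LOH when >= 10 germline-het sites fall
in it and their median tumor alt fraction departs from 0.5 by >= 0.2.

**Concordance and relatedness.** Primary/model concordance is scored over
targeted base pairs inside HC segments of either sample: the (primary call,
model call) bp contingency and the diagonal fraction (excluding nc).
Sample relatedness uses the union of HC segments as features, each sample's
mean probe logR within each feature as the value, Euclidean distance, and
average-linkage hierarchical clustering rendered as newick (lexicographic
sample order for determinism).

## Synthetic cohort generator

The generator emits matched cohorts with full ground truth so every stage
is testable by parameter recovery. Defaults describe a four-patient
glioblastoma-style cohort: 60x mean on-target depth, primary purities
(0.91, 0.89, 0.75, 0.59) against pure models, two xenografts with 30% and
60% murine read fractions, 150 somatic and 500 germline candidate sites per
patient, and a toy genome of 22 two-armed chromosomes (10 Mb each, 60
probes of 200 bp per chromosome) written in UCSC cytoBand format.

- **Allele counts.** The expected somatic MAF is
  f = m·CCF·p / (CN_t·p + 2(1 − p)) with m mutant copies, cancer-cell
  fraction CCF, purity p, and tumor copy number CN_t; observed alt counts
  are Binomial(depth, f) with depth ~ NegativeBinomial (size 5) whose mean
  follows a smooth quadratic GC bow peaking at GC 0.45. Subclonal
  architecture is not externally constrained; the default CCF set
  {1.0, 0.4} with weights {0.7, 0.3} is a free parameter documented as
  such.
- **Artifacts.** A configurable fraction of candidate sites are sequencing
  artifacts: alt counts ~ Binomial(depth, 0.08) in every sample and mean
  base qualities from the low mode N(12, 2²) instead of N(30, 2²), giving
  the mixture filter and the 5% germline cap real targets.
- **Probe coverage.** Probe "coverage" is a pooled fragment count (~4
  fragments per unit depth at 200 bp probes and 50 bp reads) drawn
  NegativeBinomial with size 300. The site-level size-5 overdispersion is
  deliberately *not* applied at the probe level: pooling fragments across a
  probe averages noise, and a size-5 probe model would produce per-probe
  logR noise near 0.9, under which percentile-based HC grading of arm-level
  events is mathematically impossible. Size 300 yields per-probe logR noise
  near 0.15, consistent with the segmentation operating regime. Tumor
  libraries get a stronger GC bow peaking at GC 0.57 (separate library
  batches), so logR carries a GC trend until corrected.
- **Copy-number truth.** All patients share the chr7 gain / chr10 loss
  pattern; each carries two or three private arm events and patient 0 a
  focal 400 kb deletion, echoing the arm-level landscape typical of this
  tumor type and giving clustering genuinely distinct profiles.
- **Xenograft reads.** Host reads align to mouse with ~0.5 expected
  mismatches and cross-map to human with ~4 (Poisson), with realistic
  pairing asymmetries — discriminative but imperfect, so a few percent of
  host reads survive the filter. Graft reads always map to their own
  genome (fully unmapped fragments never reach a pileup), and their mouse
  alignment, when present, always carries at least one extra cross-species
  mismatch: at 50 bp and ~85% human-mouse exon identity, a zero-mismatch
  cross-species alignment of a true human read is vanishingly unlikely.
  Consequently an uncontaminated read set passes the filter unchanged.
  Murine-ortholog artifact sites (model-sample alt fraction tracking the
  murine read fraction) mimic the spurious somatic calls that vanish after
  host-read removal.
- **Re-pileup stand-in.** Re-aligning and re-piling reads after filtering
  is out of scope, so the synthetic pipeline thins the murine-attributed
  alt support at each xenograft site binomially with the filter's measured
  per-species retention (which requires ground truth and therefore exists
  only in the synthetic workflow).

What the generator does **not** emulate: mappability and capture-efficiency
structure beyond GC, strand bias, indel realignment artifacts, multi-allelic
sites, clonal phylogenies deeper than one subclone level, and linked errors
between neighboring sites. Passing tests therefore demonstrate the
statistical machinery under the stated generative assumptions, not
performance on real libraries.

## Problem sizes and numerical choices

The default test/report problem sizes — 150 somatic sites, 1,320 probes,
300 FDR permutations, 200 segmentation permutations per split — were chosen
as the smallest sizes at which the Monte-Carlo error of each check is well
below its decision margin. Fisher p-values use scipy's hypergeometric
machinery; within the permutation FDR the per-site p-value table over the
hypergeometric support is precomputed once per site, making the null draws
a table lookup. Two-sided p-values include all tables whose point
probability does not exceed the observed one by more than one part in 1e7,
the standard floating-point tie guard. EM variances are floored at 1e-6;
degenerate inputs (empty chromosome, no neutral segments, zero
transversions, all-synonymous call sets) warn and return the documented
degenerate value rather than raising, except where the input is a contract
violation. All randomness flows from explicit integer seeds; fixed seeds
give byte-identical outputs, including serialized cohorts and reports.

## Known limitations

- The comparison assumes site-level independence; linked mutations (e.g.
  on one haplotype) violate the permutation null's exchangeability in ways
  the generator does not model.
- The contamination estimator is a reconstruction (see above) and assumes
  a pure model and copy-neutral context; aneuploid sites bias the median
  ratio if segmentation output is not supplied.
- HC grading needs at least one neutral segment; a genome-wide aneuploid
  sample degrades to ungraded calls with a warning.
- Segmentation p-values are permutation-based and therefore granular at
  small probe counts; chromosomes under 5 probes are never split.
- The CLI's multi-sample formats carry exactly three roles (germline,
  primary, model); multi-region or multi-model designs are out of scope.
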