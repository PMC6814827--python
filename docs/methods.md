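# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `clonotrace`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Somatic variant calling

The cascade operates on per-allele call records (one record per ALT allele;
multi-allelic VCF rows are split with depth carried to every allele, so VAF
is always `AD_alt / DP` for that allele).

Per-sample quality filter (all boundaries inclusive):
genotype quality ≥ 30, alt reads ≥ 3, VAF ≥ 0.05, depth ≥ 10. A record with
no GQ field is treated as GQ 0 and therefore fails the filter — the
conservative reading when a caller omits quality.

Somatic test against the matched normal: normal depth ≥ 10, normal
VAF ≤ 0.05, and a ratio rule relating normal to tumour VAF. The ratio rule
is stated ambiguously in the workflows this package generalises
("normal VAF < 2X of the tumour VAF"); the default here is the *stringent*
reading `normal_vaf < 0.5 × tumour_vaf` (tumour VAF must exceed twice the
normal VAF), because the literal reading `normal_vaf < 2 × tumour_vaf`
removes essentially nothing beyond the 0.05 cap. The literal reading is
selectable (`FilterThresholds.normal_vaf_rule = "twice_tumour"`).

Pooled panel of normals: a candidate is rejected when more than two pooled
normals show VAF ≥ 0.20 at the locus. The matched-normal and pooled filters
commute, so the retained set does not depend on their order.

Multi-caller merging is a union keyed by (chrom, pos, ref, alt), with the
caller set kept as provenance and numeric fields taken from the deepest
caller. Union (rather than intersection) is chosen because the downstream
filter cascade is the quality gate; requiring multi-caller support is a
stricter policy a user can impose on the `callers` field.

Consequences: an SNV inside a CDS is classified by substituting the base in
its codon and translating (silent / non_silent); coding indels are
non_silent; everything else, including UTR and splice region, is non_coding
by default. A variant overlapping several genes takes the worst consequence
(non_silent > silent > non_coding), conservative for burden counting.
TMB = non-silent somatic count / target size, default 51 Mb (the standard
whole-exome capture).

## Fusion calling

Evidence comes as an aligner-neutral junction table (read id, evidence type,
two coordinates) standing in for split-alignment and chimeric-tag BAM
records, which isolates the algorithm from aligner-specific conventions.
One read contributes at most one evidence record per gene pair.

Chain order (fixed and logged): group evidence by ordered gene pair →
remove normal-splicing reads between genes < 5 kb apart (gap measured
between nearest transcript ends, 0 for overlapping genes) → per-pair
breakpoint consensus (modal split junction, ties broken toward the 5'-most
junction) → frame check → ≥ 10 aa retained both sides → panel filters
(strictly > 1% non-cancer or > 10% cancer discards) → ≥ 5 total reads.
Each discarded candidate records the *first* failing reason, so decoy
classes map to deterministic reasons (proximity, frame, short_peptide,
panel, support).

Frame rule: with `off5` = coding bases retained from the 5' partner
(relative to its frame start) and `off3` = coding offset of the first
retained 3' base, the fusion is in frame iff `off5 ≡ off3 (mod 3)`.
Retained lengths are `aa5 = ⌊off5/3⌋` and `aa3 = ⌊(CDS3 − idx3)/3⌋`.
Stop codons created by the junction-spanning hybrid codon are **not**
scanned — the criterion is frame only; a documented limitation.

## Copy number and allelic imbalance

Gene status per platform: AMP iff CN ≥ 4 (inclusive), DEL iff CN < 0.5
(strict), else neutral. A call is *reliable* iff both platforms (SNP array
and exome) agree on the same non-neutral status; a missing platform value
means unreliable. The rule is symmetric in the platforms.

Allelic imbalance has no single canonical statistic; the operationalisation
here is windowed: heterozygous SNPs (het defined by the matched normal,
BAF in [0.3, 0.7], when a normal track is used; the synthetic tracks carry
an explicit het flag) are folded to deviations `d = |BAF − 0.5|`, scanned
in consecutive windows of 25 SNPs per chromosome. A window is imbalanced
when (i) its mean deviation reaches `dev_cut` = 0.05 and (ii) a one-sided
t-test rejects H0: mean deviation ≤ dev_cut at α = 0.01 (if the window has
zero variance, the mean alone decides). Adjacent imbalanced windows merge,
so segment boundaries are accurate to within one window of het SNPs.
Testing against `dev_cut` (rather than the noise floor) keeps the
false-segment rate per window below ~1e-4 at noise SD 0.05 while retaining
essentially full power at deviation 0.15 — the operating regime the tests
verify. Folding makes the whole procedure invariant under BAF → 1 − BAF.
Chromosomes with fewer than `min_snps` = 10 het SNPs are skipped.

Paired segment lists are matched by ≥ 50% reciprocal overlap:
baseline-only segments are *lost* (the clonal-replacement hallmark),
resistant-only *gained*, matched *shared*.

## Expression and signatures

Preprocessing: genes with < 10 counts in ≥ 80% of samples are removed (the
"at least 80%" reading; the alternative is switchable via `frac_samples`),
the matrix is quantile-normalised (every sample forced onto the mean of
sorted per-sample vectors; ties receive the average of the reference values
they span, which keeps the transform idempotent on tie-free data to 1e-9),
then log2(x + 1). The pseudocount of 1 on normalised counts is a
convention choice.

Combined Z: per-gene z-scores across samples (mean 0, sd 1, ddof = 1), then
`Z = Σ sign(g)·z_g / √|S∩matrix|`. Genes missing from the matrix are
dropped with a warning; an empty intersection is an error. Scores are
invariant to per-gene affine rescaling and ≈ N(0,1) on null data, which the
suite checks by KS test. Batch effects are *not* modelled (the mixed-model
batch correction used in cohort studies is out of scope); the synthetic
generator can plant batch-like shifts and per-batch median-centering is the
only, explicitly non-equivalent, mitigation offered.

Clustering of score matrices uses Euclidean distance with average linkage
(configurable); inputs are label-sorted first so the dendrogram does not
depend on input order.

Infiltration scores are combined-Z surrogates over user-supplied immune and
stromal sets — they are *not* the ESTIMATE algorithm, whose ssGSEA-based
internals are out of scope, but they reproduce the directional
paired-sample comparisons the package needs. EMT shifts are per-gene
Δlog2(resistant − baseline); |Δlog2| > 2 (i.e. > 4-fold) flags a gene, and
the summary is mean mesenchymal shift minus mean epithelial shift.

## Clonal dynamics

"VAF = 0" means *not called somatic in that sample*: a variant below the
0.05 detection threshold plots on the axis even if a few supporting reads
exist. Each biopsy is called independently and the sets joined by variant
key; baseline-private → lost, resistant-private → gained. Fractions are
reported overall and per consequence class.

The clonal-replacement score is the mean of (fraction lost, fraction
gained, fraction of baseline imbalance segments lost), with a verdict
threshold of 0.5. Both the averaging and the threshold are this package's
operationalisation of a qualitative conclusion, not literature constants;
with the BAF component missing the score runs over two components and is
flagged.

Response categories: best response CR/PR → intrinsically sensitive, SD/PD →
intrinsically resistant; a sensitive patient progressing during treatment
or within 2 months of completing it is additionally categorised
acquired-resistant.

## Synthetic cohorts (the stated world)

The generators emulate the input streams of the paired-biopsy design with
fixed, documented defaults:

- depth Poisson around 100× (negative binomial if overdispersion > 0),
  matching a standard exome; read counts binomial given depth;
- clonal somatic variants at tumour VAF 0.40 — a typical clonal fraction in
  an impure biopsy; tumour purity is deliberately not a separate knob;
- the resistant subclone at VAF 0.02 at baseline, below the 0.05 detection
  threshold. *Undetectability is enforced*: emitted alt counts of
  sub-threshold clones are capped strictly below the detection VAF, because
  a raw binomial tail would otherwise surface ~5% of subclone variants at
  depth 100 and contradict the stated premise that the resistant clone is
  invisible before treatment;
- germline variants at VAF 0.5 or 1.0 in tumour and normal; artifacts at
  VAF 0.35 in tumour with ≥ 3 pooled normals ≥ 0.20;
- re-biopsy under replacement fraction f: each baseline clonal variant lost
  independently with probability f; each subclone-private variant surfaces
  at clonal VAF with probability f; germline and artifacts persist;
- fusion evidence with exact junction coordinates and four decoy classes
  (read-through < 5 kb, panel-frequent, out-of-frame, < 10 aa);
- expression as negative binomial (dispersion 20) around log-normal
  baseline means, with log2-scale shifts planted per (sample, set);
- BAF tracks with het fraction 0.6, Gaussian noise (SD 0.02–0.05), planted
  mirrored deviations ±delta, and per-segment fates lost/shared/gained;
- toy genomes of two-exon, phase-0, stop-free coding genes on a few
  chromosomes, with some neighbouring pairs 2 kb apart to exercise the
  read-through rule. Silent/non-silent truth is planted *by construction*
  from the codon table (a synonymous or non-synonymous substitution is
  chosen at generation time), so truth never reuses the classifier.

What the generators do **not** emulate — and hence what a green test does
not establish: mapping and alignment artefacts, CNV-driven VAF distortion,
tumour purity distinct from clonal fraction, realistic mutational
signatures, fusion breakpoint micro-homology, batch-confounded library
sizes. All generators are bit-reproducible for a fixed seed.

## Determinism and numerics

Every random routine takes an explicit seed and uses `numpy`'s Generator;
the pipeline derives per-stage child seeds from one base seed in a fixed
order, so a rerun with the same config is byte-identical. Floats written to
reports are rounded (TMB to 4 decimals, scores to 6) to keep text outputs
stable. Quantile normalisation tolerances are 1e-9; BAF statistics use
exact t quantiles from scipy.
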