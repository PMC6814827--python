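# clonotrace

A tested, reusable implementation of the computational analyses used in
paired-biopsy studies of anti-EGFR therapy resistance in colorectal cancer:
tumours are profiled before treatment and again at acquired resistance, and
the question is whether resistance arose by *clonal replacement* — the
outgrowth of a minor subclone that was undetectable at baseline.

The package is aimed at computational biologists who want the individual
analysis stages (somatic filtering, fusion calling, allelic-imbalance
segmentation, signature scoring) as testable library functions rather than
one-off scripts, and who need synthetic cohorts with known truth to validate
each stage.

## What it computes

**Somatic variant cascade.** Multi-caller VCFs are union-merged, filtered at
genotype quality ≥ 30, ≥ 3 alt reads, VAF ≥ 0.05 and depth ≥ 10, then tested
against the matched normal (depth ≥ 10, normal VAF ≤ 0.05, normal VAF below
half the tumour VAF) and a pooled panel of normals (at most two pooled
normals with VAF ≥ 0.20). Tumour mutation burden is

    TMB = (# non-silent somatic mutations) / 51 Mb

with consequences assigned by codon retranslation against a gene model.

**Fusion calling.** Split-read and spanning-pair evidence from an
aligner-neutral junction table is grouped by gene pair; normal-splicing reads
between genes < 5 kb apart are dropped as read-through; the consensus
junction must join the two CDSs in frame with ≥ 10 amino acids retained on
both sides; pairs above 1% in a non-cancer panel or 10% in a cancer panel
are discarded, and ≥ 5 total supporting reads are required.

**Copy number and BAF.** Gene-level status AMP (CN ≥ 4) / DEL (CN < 0.5) is
called per platform; a call is reliable only when the SNP-array and exome
platforms agree. Allelic imbalance is segmented from folded B-allele
frequency deviations |BAF − 0.5| of heterozygous SNPs in 25-SNP windows, and
paired baseline/resistant segment lists are classified lost/gained/shared.

**Signature scoring.** Counts are filtered (< 10 counts in ≥ 80% of
samples), quantile-normalised and log2-transformed; a gene set's activation
in a sample is the combined Z score

    Z(sample, S) = Σ_{g∈S} sign(g) · z_g(sample) / √|S|

which is ≈ N(0,1) on null data. Immune/stromal infiltration scores and
per-gene EMT fold changes (> 4-fold flagged) are built on the same machinery.

**Clonal dynamics.** Paired somatic call sets are joined per variant;
baseline-private variants are *lost*, resistant-private *gained*, and the
clonal-replacement score averages the fraction of variants lost, the
fraction gained, and the fraction of baseline imbalance segments lost.

## Worked example

```python
from clonotrace import somatic, clonal, synthetic

cfg = synthetic.CohortConfig(seed=5, n_clonal=1000, n_subclonal=400,
                             n_germline=50, n_artifact=5)
ps = synthetic.simulate_paired_variants(cfg)
res_calls, _, _ = synthetic.simulate_resistant_rebiopsy(ps, replacement_fraction=0.7,
                                                        seed=99, config=cfg)
som_b = somatic.call_somatic(somatic.filter_variant_calls(ps.tumour_calls),
                             ps.normal_calls, ps.pooled_vafs)
som_r = somatic.call_somatic(somatic.filter_variant_calls(res_calls),
                             ps.normal_calls, ps.pooled_vafs)
records, summary = clonal.vaf_shift(som_b, som_r)
print(f"lost {summary.n_lost}/{summary.n_baseline} = {summary.fraction_lost:.3f}")
print(f"gained {summary.n_gained}/{summary.n_resistant} = {summary.fraction_gained:.3f}")
print(clonal.clonal_replacement_score(summary)["verdict"])
```

prints

```
lost 675/1000 = 0.675
gained 288/613 = 0.470
clonal_replacement
```

i.e. with 70% clonal replacement planted, 675 of the 1000 baseline clonal
variants are no longer called at resistance, 288 formerly sub-threshold
subclone variants surface at clonal frequency, and the combined verdict is
clonal replacement (score averages the lost and gained fractions; the BAF
component is omitted here, so the result is flagged as VAF-only).

A full cohort run (variants, fusions, copy number, signatures, paired
analysis, landscape table) is one command:

```bash
clonotrace pipeline run --config config.yaml
```

with a YAML config holding `seed`, `output_dir`, and optional threshold
overrides (deviations from the canonical defaults are warned about).
Single-stage commands (`clonotrace somatic call`, `clonotrace fusions call`,
`clonotrace cnv baf-segments`, `clonotrace expr score`,
`clonotrace clonal shift`) operate on files in standard formats
(VCF/GTF/TSV/GMT/BED).

## Acceptance script

`scripts/acceptance.py` re-runs the complete synthetic-cohort pipeline from
scratch (simulation, somatic calling, fusion calling, copy-number consensus,
signature scoring, paired clonal analysis, landscape assembly) for a given
seed and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/clonotrace/io_formats.py` — VCF/GTF/FASTA/TSV readers & writers, core types
- `src/clonotrace/synthetic.py` — cohort generators with machine-readable truth
- `src/clonotrace/somatic.py` — filter cascade, merging, somatic test, TMB
- `src/clonotrace/fusions.py` — junction evidence, frame check, panel filters
- `src/clonotrace/copynumber.py` — CN status/consensus, BAF segmentation
- `src/clonotrace/signatures.py` — preprocessing, combined-Z, clustering, EMT
- `src/clonotrace/clonal.py` — VAF shift, response categories, replacement score
- `src/clonotrace/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
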