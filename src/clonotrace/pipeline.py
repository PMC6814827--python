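"""End-to-end orchestration over a synthetic cohort.

``run_pipeline`` wires the stages together — simulate a cohort, call
somatic variants per patient, call fusions, assign copy-number status,
score expression signatures, and run the paired baseline/resistant clonal
analysis — and writes a run directory containing per-patient artifacts, a
cohort landscape table (per-gene MUT/FUS/AMP cells plus mutation burden and
response category per patient) and a MANIFEST with the config echo and
seed. Outputs are deterministic: the same config and seed produce
byte-identical files.

File-based single-stage analyses (a VCF pair, a junction table, a BAF
track) are exposed through the module functions and the command-line
interface; the pipeline itself runs on the synthetic cohort, which is the
only input whose truth is known end to end.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import clonal, copynumber, fusions, signatures, somatic, synthetic
from .io_formats import ValidationError, write_gene_models, write_genome_fasta, write_variant_calls

# canonical thresholds; deviations are reported by validate_config
PAPER_DEFAULTS = {
    "min_gq": 30.0,
    "min_alt_reads": 3,
    "min_vaf": 0.05,
    "min_depth": 10,
    "min_normal_depth": 10,
    "max_normal_vaf": 0.05,
    "max_pooled_hits": 2,
    "pooled_vaf_cut": 0.20,
    "target_mb": 51.0,
    "fusion_min_total_reads": 5,
    "fusion_min_aa": 10,
    "fusion_max_dist": 5000,
    "fusion_max_noncancer": 0.01,
    "fusion_max_cancer": 0.10,
    "cn_amp_cut": 4.0,
    "cn_del_cut": 0.5,
    "expr_min_count": 10,
    "expr_frac_samples": 0.80,
    "emt_fold_cut": 4.0,
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    thresholds: somatic.FilterThresholds = field(default_factory=somatic.FilterThresholds)
    target_mb: float = 51.0
    cn_amp_cut: float = 4.0
    cn_del_cut: float = 0.5
    fusion_min_total_reads: int = 5
    fusion_min_aa: int = 10
    fusion_max_dist: int = 5000
    n_patients: int = 6
    n_resistant_pairs: int = 2
    n_genes: int = 24
    panel_genes: list[str] | None = None  # None -> every annotated gene
    cohort: synthetic.CohortConfig | None = None


def validate_config(raw: dict) -> tuple[PipelineConfig, list[str], list[str]]:
    """Build a PipelineConfig from a plain dict (YAML-loaded).

    Returns (config, errors, warnings); warnings name every threshold that
    deviates from its canonical default so deviations are auditable per run.
    """
    errors: list[str] = []
    warnings: list[str] = []
    if "seed" not in raw:
        errors.append("missing field: seed")
    if "output_dir" not in raw:
        errors.append("missing field: output_dir")
    thr_kwargs = {}
    for name in ("min_gq", "min_alt_reads", "min_vaf", "min_depth",
                 "min_normal_depth", "max_normal_vaf", "normal_vaf_rule",
                 "max_pooled_hits", "pooled_vaf_cut"):
        if name in raw:
            thr_kwargs[name] = raw[name]
    try:
        thresholds = somatic.FilterThresholds(**thr_kwargs)
    except ValidationError as exc:
        errors.append(str(exc))
        thresholds = somatic.FilterThresholds()
    for name, default in PAPER_DEFAULTS.items():
        value = raw.get(name, getattr(thresholds, name, None))
        if value is not None and name in raw and value != default:
            warnings.append(f"{name}={value} deviates from canonical default {default}")
    if errors:
        return None, errors, warnings  # type: ignore[return-value]
    cfg = PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw["output_dir"]),
        thresholds=thresholds,
        target_mb=float(raw.get("target_mb", 51.0)),
        cn_amp_cut=float(raw.get("cn_amp_cut", 4.0)),
        cn_del_cut=float(raw.get("cn_del_cut", 0.5)),
        fusion_min_total_reads=int(raw.get("fusion_min_total_reads", 5)),
        fusion_min_aa=int(raw.get("fusion_min_aa", 10)),
        fusion_max_dist=int(raw.get("fusion_max_dist", 5000)),
        n_patients=int(raw.get("n_patients", 6)),
        n_resistant_pairs=int(raw.get("n_resistant_pairs", 2)),
        n_genes=int(raw.get("n_genes", 24)),
        panel_genes=raw.get("panel_genes"),
    )
    return cfg, errors, warnings


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def _write_json(path: str, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the in-memory report.

    The report carries the landscape table, per-patient results and the
    complete truth bundle, so callers (and tests) can re-derive every cell
    of the landscape from the planted truth alone.
    """
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    patients_dir = os.path.join(out_dir, "patients")
    os.makedirs(patients_dir, exist_ok=True)
    seed_rng = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(seed_rng.integers(2**31))

    genome_seed = child_seed()
    genome, gene_models = synthetic.make_toy_genome(n_genes=config.n_genes, seed=genome_seed)
    gene_ids = sorted(g.gene_id for g in gene_models)
    panel = config.panel_genes or gene_ids
    write_gene_models(os.path.join(out_dir, "annotation.gtf"), gene_models)
    write_genome_fasta(os.path.join(out_dir, "genome.fa"), genome)

    clinical = synthetic.simulate_clinical_table(
        config.n_patients, config.n_resistant_pairs, seed=child_seed()
    )
    clinical.to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t", index=False)

    cohort_cfg = config.cohort or synthetic.CohortConfig(
        seed=config.seed,
        n_patients=config.n_patients,
        n_resistant_pairs=config.n_resistant_pairs,
        n_clonal=60,
        n_subclonal=20,
        n_germline=120,
        n_artifact=8,
    )

    truth_bundle: dict = {"patients": {}, "genome_seed": genome_seed}
    patient_reports: dict = {}
    landscape_rows = []

    by_gene_id = {g.gene_id: g for g in gene_models}
    fusion_hosts = clinical["patient_id"].tolist()

    for i, row in enumerate(clinical.itertuples(index=False)):
        pid = row.patient_id
        pt_seed = child_seed()
        paired = synthetic.simulate_paired_variants(
            cohort_cfg, gene_models=gene_models, genome=genome,
            sample_id=pid, seed=pt_seed,
        )
        category = clonal.classify_response(pid, row.best_response, bool(row.progressed_within_2mo))

        filtered = somatic.filter_variant_calls(paired.tumour_calls, config.thresholds)
        som = somatic.call_somatic(
            filtered, paired.normal_calls, paired.pooled_vafs, config.thresholds
        )
        somatic.annotate_consequences(som, gene_models, genome)
        tmb = somatic.compute_tmb(som, config.target_mb)
        write_variant_calls(os.path.join(patients_dir, f"{pid}_somatic.vcf"),
                            [v.call for v in som], sample_id=pid)

        # fusions: every third patient hosts one planted in-frame fusion
        fusion_calls = []
        fusion_truth = None
        if i % 3 == 0:
            f_seed = child_seed()
            f_rng = np.random.default_rng(f_seed)
            g5, g3 = f_rng.choice(
                [g for g in gene_models if g.cds_length >= 120], size=2, replace=False
            )
            planted_fusion = synthetic.PlantedFusion(g5.gene_id, g3.gene_id)
            table, fusion_truth, noncancer, cancer = synthetic.simulate_chimeric_evidence(
                gene_models, [planted_fusion], seed=f_seed,
                decoys={"readthrough": 1, "frame": 1},
            )
            fusion_calls = fusions.call_fusions(
                table, gene_models, noncancer, cancer,
                min_total_reads=config.fusion_min_total_reads,
                min_aa=config.fusion_min_aa,
                max_dist=config.fusion_max_dist,
            )
        else:
            child_seed()  # keep the seed stream aligned across patients

        # copy number: every fourth patient gets one reliable amplification
        cn_seed = child_seed()
        cn_rng = np.random.default_rng(cn_seed)
        planted_cn = {}
        if i % 4 == 1:
            amp_gene = gene_ids[int(cn_rng.integers(len(gene_ids)))]
            planted_cn[amp_gene] = (float(4 + cn_rng.integers(0, 4)), float(4 + cn_rng.integers(0, 4)))
        cn_table = synthetic.simulate_cn_tables(gene_ids, planted_cn, seed=cn_seed)
        cn_calls = copynumber.call_gene_cn_status(
            cn_table, census_genes=set(panel),
            amp_cut=config.cn_amp_cut, del_cut=config.cn_del_cut,
        )

        # paired analysis for re-biopsied patients
        pair_report = None
        if bool(row.has_rebiopsy):
            rb_seed = child_seed()
            resistant_calls, _, fates = synthetic.simulate_resistant_rebiopsy(
                paired, cohort_cfg.replacement_fraction, rb_seed, cohort_cfg,
                sample_id=f"{pid}_RT",
            )
            filtered_rt = somatic.filter_variant_calls(resistant_calls, config.thresholds)
            som_rt = somatic.call_somatic(
                filtered_rt, paired.normal_calls, paired.pooled_vafs, config.thresholds
            )
            somatic.annotate_consequences(som_rt, gene_models, genome)
            records, summary = clonal.vaf_shift(som, som_rt)
            baf_seed = child_seed()
            segs = [
                synthetic.PlantedImbalance("chr10", 2_000_000, 8_000_000, 0.15, fate="lost"),
                synthetic.PlantedImbalance("chr2", 1_000_000, 5_000_000, 0.15, fate="shared"),
            ]
            chrom_lengths = {f"chr{c}": 10_000_000 for c in (2, 10)}
            base_track, res_track, baf_truth = synthetic.simulate_baf_tracks(
                chrom_lengths, segs, n_snps=4000, noise_sd=0.03,
                seed=baf_seed, sample_id=pid,
            )
            seg_b = copynumber.detect_allelic_imbalance(base_track)
            seg_r = copynumber.detect_allelic_imbalance(res_track)
            classes = copynumber.compare_imbalance(seg_b, seg_r)
            score = clonal.clonal_replacement_score(summary, classes)
            clonal.shift_records_frame(records).to_csv(
                os.path.join(patients_dir, f"{pid}_vaf_shift.tsv"), sep="\t", index=False
            )
            copynumber.write_segments_bed(
                os.path.join(patients_dir, f"{pid}_baseline_segments.bed"), seg_b
            )
            pair_report = {
                "n_lost": summary.n_lost,
                "n_gained": summary.n_gained,
                "fraction_lost": summary.fraction_lost,
                "fraction_gained": summary.fraction_gained,
                "replacement": score,
                "baf_classes": [(s.chrom, s.start, s.end, c) for s, c in classes],
            }
            truth_bundle["patients"].setdefault(pid, {})["rebiopsy_fates"] = {
                str(k): v for k, v in fates.items()
            }
            truth_bundle["patients"][pid]["baf_segments"] = [asdict(s) for s in segs]
        else:
            child_seed(); child_seed()  # rb + baf slots, keep stream aligned

        retained_fusions = [c for c in fusion_calls if c.status == "retained"]
        mut_genes = sorted({v.gene_id for v in som if v.consequence == "non_silent" and v.gene_id})
        fus_genes = sorted({g for c in retained_fusions for g in (c.gene5, c.gene3)})
        amp_genes = sorted(
            c.gene_id for c in cn_calls
            if c.reliable and c.status == "AMP" and c.in_census
        )
        cells = {}
        for g in panel:
            kinds = []
            if g in mut_genes:
                kinds.append("MUT")
            if g in fus_genes:
                kinds.append("FUS")
            if g in amp_genes:
                kinds.append("AMP")
            cells[g] = "+".join(kinds) if kinds else "none"
        landscape_rows.append(
            {"patient_id": pid, "category": category.category,
             "tmb": round(tmb, 4), **cells}
        )

        patient_reports[pid] = {
            "category": category.category,
            "tmb": tmb,
            "n_somatic": len(som),
            "n_non_silent": sum(1 for v in som if v.consequence == "non_silent"),
            "fusions_retained": [
                {"gene5": c.gene5, "gene3": c.gene3, "total_reads": c.total_reads,
                 "aa5": c.aa5, "aa3": c.aa3}
                for c in retained_fusions
            ],
            "amp_genes": amp_genes,
            "paired": pair_report,
        }
        _write_json(os.path.join(patients_dir, f"{pid}.json"), patient_reports[pid])

        truth_bundle["patients"].setdefault(pid, {}).update(
            {
                "variant_labels": {str(k): t.label for k, t in paired.truth.items()},
                "non_silent_genes": sorted(
                    {t.gene_id for t in paired.truth.values()
                     if t.label == "clonal_somatic" and t.consequence == "non_silent" and t.gene_id}
                ),
                "planted_fusion": fusion_truth.planted if fusion_truth else [],
                "planted_amp": sorted(planted_cn),
            }
        )

    # cohort expression + signatures
    expr_seed = child_seed()
    samples = [f"{p}_T" for p in clinical["patient_id"]] + [
        f"{p}_RT" for p in clinical.loc[clinical["has_rebiopsy"], "patient_id"]
    ] if len(clinical) else []
    sig_sets = {
        "EMT_MES": [f"G{i:05d}" for i in range(0, 25)],
        "EMT_EPI": [f"G{i:05d}" for i in range(25, 50)],
        "IMMUNE": [f"G{i:05d}" for i in range(50, 75)],
        "STROMAL": [f"G{i:05d}" for i in range(75, 100)],
    }
    effects = {}
    rebiopsied = clinical.loc[clinical["has_rebiopsy"], "patient_id"].tolist()
    if rebiopsied:
        star = rebiopsied[0]
        effects = {
            (f"{star}_RT", "EMT_MES"): 2.0,
            (f"{star}_RT", "IMMUNE"): -2.0,
        }
    if samples:
        counts, expr_truth = synthetic.simulate_expression(
            n_genes=400, samples=samples, signature_sets=sig_sets,
            effects=effects, seed=expr_seed, n_low_genes=20,
        )
        log2 = signatures.preprocess_counts(counts)
        gene_sets = [signatures.GeneSet(name, tuple(g)) for name, g in sig_sets.items()]
        scores = signatures.score_matrix(log2, gene_sets)
        scores.round(6).to_csv(os.path.join(out_dir, "signature_scores.tsv"), sep="\t")
        truth_bundle["expression"] = {
            "low_count_genes": expr_truth.low_count_genes,
            "effects": {f"{s}|{n}": v for (s, n), v in expr_truth.effects.items()},
        }
    else:
        scores = pd.DataFrame()
        truth_bundle["expression"] = {"low_count_genes": [], "effects": {}}

    if landscape_rows:
        landscape = pd.DataFrame(landscape_rows).set_index("patient_id")
    else:
        landscape = pd.DataFrame(columns=["category", "tmb"])
        landscape.index.name = "patient_id"
    landscape.to_csv(os.path.join(out_dir, "landscape.tsv"), sep="\t")
    _write_json(os.path.join(out_dir, "truth.json"), truth_bundle)

    config_echo = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_resistant_pairs": config.n_resistant_pairs,
        "n_genes": config.n_genes,
        "thresholds": asdict(config.thresholds),
        "target_mb": config.target_mb,
    }
    manifest = {
        "config": config_echo,
        "config_hash": hashlib.sha256(
            json.dumps(config_echo, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": sorted(
            os.path.relpath(os.path.join(root, f), out_dir)
            for root, _dirs, files in os.walk(out_dir)
            for f in files
            if f != "MANIFEST.json"
        ),
    }
    _write_json(os.path.join(out_dir, "MANIFEST.json"), manifest)

    return {
        "landscape": landscape,
        "patients": patient_reports,
        "truth": truth_bundle,
        "scores": scores,
        "clinical": clinical,
        "panel": panel,
    }
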