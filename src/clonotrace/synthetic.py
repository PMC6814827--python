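"""Synthetic cohorts with machine-readable truth sets.

Every generator emulates one input stream of the paired-biopsy resistance
analysis — tumour/normal variant calls with planted clonal structure,
chimeric read evidence over toy gene models, expression matrices with
planted signature shifts, and paired BAF tracks with imbalance segments
that disappear at resistance — and returns, alongside the data, the truth
labels needed to score any downstream stage.

Conventions of the stated world:

* clonal somatic variants sit at tumour VAF 0.4 (a typical clonal fraction
  in an impure biopsy) with read counts binomial given depth;
* the resistant subclone is planted at VAF 0.02 at baseline, below the 0.05
  somatic detection threshold, i.e. undetectable before treatment;
* sequencing depth is Poisson around 100x (negative binomial when
  overdispersion is requested), matching a standard exome;
* pooled-normal artifacts recur in at least three pooled normals at
  VAF >= 0.20, so the at-most-two-pooled-hits rule removes them;
* the capture target is 51 Mb, the standard whole-exome capture size.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .copynumber import BafTrack
from .io_formats import (
    JUNCTION_COLUMNS,
    GeneModel,
    GenomicInterval,
    ValidationError,
    VariantCall,
)

SOMATIC_DETECTION_VAF = 0.05
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS = [c for c in ("".join(p) for p in itertools.product(_BASES, repeat=3)) if c not in _STOPS]


def _substitutions(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """Single-base substitutions of ``codon`` with the requested effect,
    never creating a stop codon."""
    aa = str(Seq(codon).translate())
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutated = codon[:pos] + b + codon[pos + 1 :]
            if mutated in _STOPS:
                continue
            if (str(Seq(mutated).translate()) == aa) == synonymous:
                out.append((pos, b))
    return out


@dataclass
class CohortConfig:
    """The stated world for one synthetic cohort."""

    seed: int
    n_patients: int = 8
    n_resistant_pairs: int = 3
    depth_mean: float = 100.0
    depth_overdispersion: float = 0.0  # 0 -> Poisson depth
    clonal_vaf: float = 0.40
    subclone_fraction_baseline: float = 0.02
    target_mb: float = 51.0
    n_clonal: int = 150
    n_subclonal: int = 40
    n_germline: int = 400
    n_artifact: int = 15
    n_pooled_normals: int = 10
    coding_fraction: float = 0.8
    silent_fraction: float = 0.35
    error_rate: float = 0.001
    replacement_fraction: float = 0.7
    fusion_truth: list = field(default_factory=list)  # PlantedFusion entries
    signature_effects: dict = field(default_factory=dict)  # (sample, set) -> log2 shift
    baf_segments: list = field(default_factory=list)  # PlantedImbalance entries

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if not 0 < self.subclone_fraction_baseline <= SOMATIC_DETECTION_VAF:
            raise ValidationError(
                "subclone_fraction_baseline must be in (0, 0.05] so the planted "
                "resistant clone is undetectable at baseline"
            )


@dataclass
class VariantTruth:
    """Truth labels for one planted variant."""

    key: tuple[str, int, str, str]
    label: str  # clonal_somatic | subclonal_somatic | germline | artifact
    consequence: str  # silent | non_silent | non_coding
    true_vaf: float
    gene_id: str | None = None


@dataclass
class PairedVariantSet:
    tumour_calls: list[VariantCall]
    normal_calls: list[VariantCall]
    pooled_vafs: pd.DataFrame
    truth: dict[tuple, VariantTruth]

    def keys_with_label(self, label: str) -> set[tuple]:
        return {k for k, t in self.truth.items() if t.label == label}


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


def make_toy_genome(
    n_genes: int = 24,
    seed: int = 0,
    codons_per_gene: tuple[int, int] = (60, 160),
    intron_len: int = 300,
    gap_len: int = 20000,
    n_close_pairs: int = 2,
    close_gap: int = 2000,
    minus_fraction: float = 0.3,
    genes_per_chrom: int = 8,
) -> tuple[dict[str, str], list[GeneModel]]:
    """A toy genome of two-exon coding genes with stop-free CDS.

    ``n_close_pairs`` consecutive gene pairs are placed ``close_gap`` bp
    apart (default 2 kb) to provide read-through decoys for the 5 kb fusion
    proximity rule; all other neighbours sit ``gap_len`` apart.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, list[str]] = {}
    genes: list[GeneModel] = []
    cursor = 1000
    chrom_i = 1
    chrom = f"chr{chrom_i}"
    seqs: dict[str, str] = {}
    chrom_genes = 0
    close_remaining = n_close_pairs
    for gi in range(n_genes):
        n_codons = int(rng.integers(codons_per_gene[0], codons_per_gene[1] + 1))
        cds_len = 3 * n_codons
        exon1_len = 3 * (n_codons // 2)
        exon2_len = cds_len - exon1_len
        strand = "-" if rng.random() < minus_fraction else "+"
        e1 = GenomicInterval(chrom, cursor, cursor + exon1_len - 1, strand)
        e2_start = e1.end + intron_len + 1
        e2 = GenomicInterval(chrom, e2_start, e2_start + exon2_len - 1, strand)
        exons = [e1, e2] if strand == "+" else [e2, e1]
        gene = GeneModel(
            gene_id=f"GENE{gi:04d}",
            gene_name=f"TG{gi:04d}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=list(exons),
            coding_start_phase=0,
        )
        genes.append(gene)
        # layout: occasionally place the next gene close to form a
        # read-through pair
        if close_remaining > 0 and gi % 5 == 1:
            cursor = e2.end + close_gap + 1
            close_remaining -= 1
        else:
            cursor = e2.end + gap_len + 1
        chrom_genes += 1
        if chrom_genes >= genes_per_chrom and gi != n_genes - 1:
            chrom_i += 1
            chrom = f"chr{chrom_i}"
            cursor = 1000
            chrom_genes = 0
    # build sequences: random background, stop-free CDS overwritten
    for chrom_name in {g.chrom for g in genes}:
        length = max(g.end for g in genes if g.chrom == chrom_name) + 1000
        seq = rng.choice(list(_BASES), size=length)
        seqs[chrom_name] = seq
    for g in genes:
        n_codons = g.cds_length // 3
        mrna = "".join(rng.choice(_CODONS) for _ in range(n_codons))
        for i in range(g.cds_length):
            pos = g.genomic_position(i)
            base = mrna[i]
            if g.strand == "-":
                base = str(Seq(base).complement())
            seqs[g.chrom][pos - 1] = base
    genome = {name: "".join(seq) for name, seq in seqs.items()}
    for g in genes:
        g.validate()
    return genome, genes


# ---------------------------------------------------------------------------
# Paired tumour/normal variants
# ---------------------------------------------------------------------------


def _draw_depth(rng: np.random.Generator, mean: float, overdispersion: float, size: int) -> np.ndarray:
    if overdispersion <= 0:
        d = rng.poisson(mean, size=size)
    else:
        # NB with variance mean * (1 + overdispersion)
        r = mean / overdispersion
        p = r / (r + mean)
        d = rng.negative_binomial(r, p, size=size)
    return np.maximum(d, 1)


def _plant_coding_variant(
    rng: np.random.Generator,
    genes: list[GeneModel],
    genome: dict[str, str],
    used: set[tuple[str, int]],
    silent: bool,
) -> tuple[tuple[str, int, str, str], str]:
    """Choose a CDS position and substitution with the requested effect.

    Truth is by construction: the substitution is selected from the codon
    table as synonymous or non-synonymous, so no classifier logic is reused.
    """
    for _ in range(200):
        gene = genes[rng.integers(len(genes))]
        n_codons = gene.cds_length // 3
        ci = int(rng.integers(n_codons))
        cds_seq = gene.spliced_cds(genome)
        codon = cds_seq[ci * 3 : ci * 3 + 3]
        subs = _substitutions(codon, synonymous=silent)
        if not subs:
            continue
        pos_in_codon, alt_mrna = subs[rng.integers(len(subs))]
        idx = ci * 3 + pos_in_codon
        gpos = gene.genomic_position(idx)
        if (gene.chrom, gpos) in used:
            continue
        used.add((gene.chrom, gpos))
        ref = genome[gene.chrom][gpos - 1]
        alt = alt_mrna if gene.strand == "+" else str(Seq(alt_mrna).complement())
        return (gene.chrom, gpos, ref, alt), gene.gene_id
    raise ValidationError("could not place coding variant; gene models too small")


def _plant_noncoding_variant(
    rng: np.random.Generator,
    genome: dict[str, str],
    genes: list[GeneModel],
    used: set[tuple[str, int]],
) -> tuple[str, int, str, str]:
    chroms = sorted(genome)
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in genes:
        spans[g.chrom].append((g.start, g.end))
    for _ in range(500):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, len(genome[chrom]) + 1))
        if any(s <= pos <= e for s, e in spans[chrom]):
            continue
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome[chrom][pos - 1]
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
        return (chrom, pos, ref, alt)
    raise ValidationError("could not place non-coding variant")


def simulate_paired_variants(
    config: CohortConfig,
    gene_models: list[GeneModel] | None = None,
    genome: dict[str, str] | None = None,
    sample_id: str = "P1",
    seed: int | None = None,
) -> PairedVariantSet:
    """One patient's tumour/normal call pair plus the pooled-normal panel.

    Without gene models, loci are placed on an abstract chromosome and all
    consequences are non_coding; with models, coding variants are planted
    with by-construction silent/non-silent truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    used: set[tuple[str, int]] = set()
    truth: dict[tuple, VariantTruth] = {}

    def place(silent_request: bool | None) -> tuple[tuple, str, str | None]:
        """Returns (key, consequence, gene_id)."""
        if gene_models is None or genome is None or silent_request is None:
            if genome is not None and gene_models is not None:
                key = _plant_noncoding_variant(rng, genome, gene_models, used)
            else:
                pos = int(rng.integers(1, 50_000_000))
                while ("chr1", pos) in used:
                    pos = int(rng.integers(1, 50_000_000))
                used.add(("chr1", pos))
                ref = _BASES[int(rng.integers(4))]
                alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
                key = ("chr1", pos, ref, alt)
            return key, "non_coding", None
        key, gene_id = _plant_coding_variant(rng, gene_models, genome, used, silent_request)
        return key, ("silent" if silent_request else "non_silent"), gene_id

    def plan(n: int, label: str, true_vaf_fn) -> None:
        for _ in range(n):
            if label in ("clonal_somatic", "subclonal_somatic") and gene_models is not None:
                if rng.random() < config.coding_fraction:
                    silent_request = bool(rng.random() < config.silent_fraction)
                else:
                    silent_request = None
            else:
                silent_request = None
            key, cons, gene_id = place(silent_request)
            truth[key] = VariantTruth(
                key=key, label=label, consequence=cons, true_vaf=true_vaf_fn(), gene_id=gene_id
            )

    plan(config.n_clonal, "clonal_somatic", lambda: config.clonal_vaf)
    plan(config.n_subclonal, "subclonal_somatic", lambda: config.subclone_fraction_baseline)
    plan(
        config.n_germline,
        "germline",
        lambda: 1.0 if rng.random() < 1 / 3 else 0.5,
    )
    plan(config.n_artifact, "artifact", lambda: 0.35)

    tumour_calls, normal_calls = _emit_pair(rng, config, truth, sample_id)
    pooled = _emit_pooled_panel(rng, config, truth, sample_id)
    return PairedVariantSet(
        tumour_calls=tumour_calls,
        normal_calls=normal_calls,
        pooled_vafs=pooled,
        truth=truth,
    )


def _emit_pair(
    rng: np.random.Generator,
    config: CohortConfig,
    truth: dict[tuple, VariantTruth],
    sample_id: str,
    vaf_override: dict[tuple, float] | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    keys = sorted(truth)
    n = len(keys)
    t_depth = _draw_depth(rng, config.depth_mean, config.depth_overdispersion, n)
    n_depth = _draw_depth(rng, config.depth_mean, config.depth_overdispersion, n)
    tumour, normal = [], []
    for i, key in enumerate(keys):
        t = truth[key]
        p_t = vaf_override.get(key, t.true_vaf) if vaf_override is not None else t.true_vaf
        p_n = t.true_vaf if t.label == "germline" else config.error_rate
        alt_t = int(rng.binomial(t_depth[i], min(p_t, 1.0))) if p_t > 0 else int(
            rng.binomial(t_depth[i], config.error_rate)
        )
        if 0 < p_t < SOMATIC_DETECTION_VAF:
            # sub-threshold clones are undetectable by construction: cap the
            # emitted support strictly below the detection VAF so a binomial
            # tail draw cannot surface the planted subclone
            cap = int(np.ceil(SOMATIC_DETECTION_VAF * int(t_depth[i]))) - 1
            alt_t = min(alt_t, max(cap, 0))
        alt_n = int(rng.binomial(n_depth[i], min(p_n, 1.0)))
        chrom, pos, ref, alt = key
        locus = GenomicInterval(chrom, pos, pos + len(ref) - 1)
        if alt_t >= 1:
            tumour.append(
                VariantCall(
                    sample_id=sample_id + "_T",
                    locus=locus,
                    ref=ref,
                    alt=alt,
                    depth=int(t_depth[i]),
                    alt_reads=alt_t,
                    vaf=alt_t / int(t_depth[i]),
                    genotype_quality=99,
                    callers=frozenset({"callerA", "callerB", "callerC"}),
                )
            )
        normal.append(
            VariantCall(
                sample_id=sample_id + "_N",
                locus=locus,
                ref=ref,
                alt=alt,
                depth=int(n_depth[i]),
                alt_reads=alt_n,
                vaf=alt_n / int(n_depth[i]),
                genotype_quality=99,
                callers=frozenset({"callerA", "callerB", "callerC"}),
            )
        )
    return tumour, normal


def _emit_pooled_panel(
    rng: np.random.Generator,
    config: CohortConfig,
    truth: dict[tuple, VariantTruth],
    sample_id: str,
) -> pd.DataFrame:
    keys = sorted(truth)
    cols = [f"POOLN{i:02d}" for i in range(config.n_pooled_normals)]
    data = rng.uniform(0.0, 0.01, size=(len(keys), len(cols)))
    for i, key in enumerate(keys):
        t = truth[key]
        if t.label == "artifact":
            n_hits = int(rng.integers(3, min(6, config.n_pooled_normals) + 1))
            hit_cols = rng.choice(len(cols), size=n_hits, replace=False)
            data[i, hit_cols] = rng.uniform(0.20, 0.45, size=n_hits)
        elif t.label == "germline":
            # the patient's own normal is part of the pool
            data[i, 0] = t.true_vaf
    index = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos", "ref", "alt"])
    return pd.DataFrame(data, index=index, columns=cols)


def simulate_resistant_rebiopsy(
    baseline: PairedVariantSet,
    replacement_fraction: float,
    seed: int,
    config: CohortConfig,
    sample_id: str = "P1_RT",
) -> tuple[list[VariantCall], dict[tuple, VariantTruth], dict[tuple, str]]:
    """Re-biopsy at acquired resistance under partial clonal replacement.

    Each baseline clonal variant is independently lost (VAF -> 0) with
    probability ``replacement_fraction``; each planted subclone-private
    variant independently rises to clonal VAF with the same probability.
    Germline variants and recurrent artifacts persist. Returns the resistant
    tumour calls, the updated truth, and the per-variant fate
    (lost / gained / persistent).
    """
    if not 0.0 <= replacement_fraction <= 1.0:
        raise ValidationError("replacement_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    vaf_override: dict[tuple, float] = {}
    fates: dict[tuple, str] = {}
    new_truth: dict[tuple, VariantTruth] = {}
    for key, t in baseline.truth.items():
        if t.label == "clonal_somatic":
            lost = rng.random() < replacement_fraction
            vaf_override[key] = 0.0 if lost else config.clonal_vaf
            fates[key] = "lost" if lost else "persistent"
        elif t.label == "subclonal_somatic":
            gained = rng.random() < replacement_fraction
            vaf_override[key] = config.clonal_vaf if gained else config.subclone_fraction_baseline
            fates[key] = "gained" if gained else "persistent"
        else:
            vaf_override[key] = t.true_vaf
            fates[key] = "persistent"
        new_truth[key] = VariantTruth(
            key=key,
            label=t.label,
            consequence=t.consequence,
            true_vaf=vaf_override[key],
            gene_id=t.gene_id,
        )
    tumour, _ = _emit_pair(rng, config, baseline.truth, sample_id, vaf_override=vaf_override)
    return tumour, new_truth, fates


# ---------------------------------------------------------------------------
# Chimeric (fusion) evidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedFusion:
    gene5: str
    gene3: str
    n_split: int = 6
    n_pairs: int = 4


@dataclass
class FusionTruth:
    planted: list[dict]
    decoys: list[dict]  # each with gene pair and expected discard reason


def _pick_junctions(
    rng: np.random.Generator,
    g5: GeneModel,
    g3: GeneModel,
    frame_shift: int = 0,
    min_aa: int = 10,
    short_side: str | None = None,
) -> tuple[int, int]:
    """Junction coordinates for a planted fusion.

    ``frame_shift`` offsets the 3' breakpoint within its codon (0 keeps the
    fusion in frame). ``short_side`` forces < 10 retained aa on one side.
    """
    n5, n3 = g5.cds_length // 3, g3.cds_length // 3
    lo5 = 2 if short_side == "5" else min_aa + 1
    hi5 = min_aa - 2 if short_side == "5" else n5 - 2
    a = int(rng.integers(lo5, max(lo5 + 1, hi5)))
    j5 = g5.genomic_position(3 * a - 1)  # last base of codon a
    lo3 = n3 - min_aa + 2 if short_side == "3" else 1
    hi3 = n3 - 2 if short_side == "3" else n3 - min_aa - 1
    b = int(rng.integers(lo3, max(lo3 + 1, hi3)))
    j3 = g3.genomic_position(3 * b + frame_shift)  # first base of codon b (+shift)
    return j5, j3


def simulate_chimeric_evidence(
    gene_models: list[GeneModel],
    fusion_truth: list[PlantedFusion],
    seed: int,
    decoys: dict[str, int] | None = None,
    noncancer_panel_freq: float = 0.02,
) -> tuple[pd.DataFrame, FusionTruth, dict[tuple, float], dict[tuple, float]]:
    """Junction-table evidence for planted fusions plus four decoy classes.

    Decoy classes (all with enough read support to survive the support
    filter, so each is discarded for exactly its own reason):

    a. ``readthrough`` — splice-type split reads between neighbouring genes
       < 5 kb apart;
    b. ``panel`` — an otherwise valid in-frame fusion whose gene pair is
       listed above 1% in the non-cancer panel;
    c. ``frame`` — chimeric junction joining the CDSs out of frame;
    d. ``short_peptide`` — in-frame junction retaining < 10 aa on one side.

    Returns (junction table, truth, non-cancer panel, cancer panel).
    """
    by_id = {g.gene_id: g for g in gene_models}
    for f in fusion_truth:
        if not (by_id[f.gene5].coding and by_id[f.gene3].coding):
            raise ValidationError(
                f"fusion {f.gene5}-{f.gene3}: partners must be coding (frame undefined)"
            )
    rng = np.random.default_rng(seed)
    decoys = decoys or {}
    rows: list[dict] = []
    read_counter = itertools.count()

    def emit(gene5: GeneModel, gene3: GeneModel, j5: int, j3: int, ev_type: str, n: int) -> None:
        for _ in range(n):
            rid = f"read{next(read_counter):06d}"
            if ev_type == "spanning_pair":
                p5 = int(rng.integers(gene5.exons[0].start, gene5.exons[0].end + 1))
                p3 = int(rng.integers(gene3.exons[0].start, gene3.exons[0].end + 1))
            else:
                p5, p3 = j5, j3
            rows.append(
                {
                    "read_id": rid,
                    "evidence_type": ev_type,
                    "chrom5": gene5.chrom,
                    "pos5": p5,
                    "strand5": gene5.strand,
                    "chrom3": gene3.chrom,
                    "pos3": p3,
                    "strand3": gene3.strand,
                }
            )

    planted_records = []
    used_pairs = set()
    for f in fusion_truth:
        g5, g3 = by_id[f.gene5], by_id[f.gene3]
        j5, j3 = _pick_junctions(rng, g5, g3)
        emit(g5, g3, j5, j3, "split_chimeric", f.n_split)
        emit(g5, g3, j5, j3, "spanning_pair", f.n_pairs)
        used_pairs.add((f.gene5, f.gene3))
        planted_records.append(
            {"gene5": f.gene5, "gene3": f.gene3, "junction5": j5, "junction3": j3,
             "n_split": f.n_split, "n_pairs": f.n_pairs}
        )

    noncancer: dict[tuple, float] = {}
    cancer: dict[tuple, float] = {}
    decoy_records = []

    def free_pair(coding_only: bool = True, same_chrom: bool = False) -> tuple[GeneModel, GeneModel]:
        for _ in range(500):
            g5, g3 = rng.choice(gene_models, size=2, replace=False)
            if (g5.gene_id, g3.gene_id) in used_pairs:
                continue
            if coding_only and not (g5.coding and g3.coding):
                continue
            if same_chrom and g5.chrom != g3.chrom:
                continue
            used_pairs.add((g5.gene_id, g3.gene_id))
            return g5, g3
        raise ValidationError("not enough genes for decoys")

    # (a) read-through: splice evidence between close neighbours
    close_pairs = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(gene_models, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        for a, b in zip(glist, glist[1:]):
            if b.start - a.end - 1 < 5000:
                close_pairs.append((a, b))
    for i in range(decoys.get("readthrough", 0)):
        if not close_pairs:
            raise ValidationError("no gene pairs < 5 kb apart for read-through decoys")
        a, b = close_pairs[i % len(close_pairs)]
        if (a.gene_id, b.gene_id) in used_pairs:
            continue
        used_pairs.add((a.gene_id, b.gene_id))
        # splice junction: end of upstream gene to start of downstream gene
        emit(a, b, a.exons[-1].end if a.strand == "+" else a.exons[-1].start, b.start, "split_splice", 6)
        decoy_records.append({"gene5": a.gene_id, "gene3": b.gene_id, "reason": "proximity"})

    # (b) panel-frequent: valid fusion, high non-cancer panel frequency
    for _ in range(decoys.get("panel", 0)):
        g5, g3 = free_pair()
        j5, j3 = _pick_junctions(rng, g5, g3)
        emit(g5, g3, j5, j3, "split_chimeric", 5)
        emit(g5, g3, j5, j3, "spanning_pair", 2)
        noncancer[(g5.gene_id, g3.gene_id)] = noncancer_panel_freq
        decoy_records.append({"gene5": g5.gene_id, "gene3": g3.gene_id, "reason": "panel"})

    # (c) out-of-frame junction
    for _ in range(decoys.get("frame", 0)):
        g5, g3 = free_pair()
        j5, j3 = _pick_junctions(rng, g5, g3, frame_shift=1)
        emit(g5, g3, j5, j3, "split_chimeric", 6)
        decoy_records.append({"gene5": g5.gene_id, "gene3": g3.gene_id, "reason": "frame"})

    # (d) short retained peptide
    for i in range(decoys.get("short_peptide", 0)):
        g5, g3 = free_pair()
        j5, j3 = _pick_junctions(rng, g5, g3, short_side="5" if i % 2 == 0 else "3")
        emit(g5, g3, j5, j3, "split_chimeric", 6)
        decoy_records.append({"gene5": g5.gene_id, "gene3": g3.gene_id, "reason": "short_peptide"})

    table = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    truth = FusionTruth(planted=planted_records, decoys=decoy_records)
    return table, truth, noncancer, cancer


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    low_count_genes: list[str]
    set_genes: dict[str, list[str]]
    effects: dict[tuple[str, str], float]  # (sample, set) -> log2 shift


def simulate_expression(
    n_genes: int,
    samples: list[str],
    signature_sets: dict[str, list[str]],
    effects: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    n_low_genes: int = 0,
    base_mean: float = 300.0,
    dispersion: float = 20.0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Negative-binomial counts with planted signature shifts.

    ``effects`` maps (sample, set name) to a log2-scale shift added to every
    gene of the set in that sample. ``n_low_genes`` extra genes are planted
    at near-zero expression to exercise the low-count filter. Signature
    genes must exist among the generated gene ids.
    """
    effects = effects or {}
    for (_s, set_name) in effects:
        if set_name not in signature_sets:
            raise ValidationError(f"effect on unknown gene set {set_name!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    known = set(gene_ids)
    for set_name, members in signature_sets.items():
        missing = set(members) - known
        if missing:
            raise ValidationError(f"gene set {set_name!r} references unknown genes")
    low_ids = [f"LOW{i:04d}" for i in range(n_low_genes)]
    all_ids = gene_ids + low_ids
    base = np.exp(rng.normal(np.log(base_mean), 0.7, size=len(all_ids)))
    base[len(gene_ids):] = 0.5  # low-count plants
    mu = np.tile(base[:, None], (1, len(samples)))
    gene_index = {g: i for i, g in enumerate(all_ids)}
    sample_index = {s: j for j, s in enumerate(samples)}
    for (sample, set_name), shift in effects.items():
        for g in signature_sets[set_name]:
            mu[gene_index[g], sample_index[sample]] *= 2.0 ** shift
    r = dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=pd.Index(all_ids, name="gene_id"), columns=samples)
    truth = ExpressionTruth(
        low_count_genes=low_ids,
        set_genes={k: list(v) for k, v in signature_sets.items()},
        effects=dict(effects),
    )
    return df, truth


# ---------------------------------------------------------------------------
# BAF tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedImbalance:
    chrom: str
    start: int
    end: int
    delta: float
    fate: str = "shared"  # shared | lost | gained

    def __post_init__(self) -> None:
        if not 0 < self.delta < 0.5:
            raise ValidationError("imbalance delta must be in (0, 0.5)")
        if self.fate not in ("shared", "lost", "gained"):
            raise ValidationError(f"unknown segment fate {self.fate!r}")


@dataclass
class BafTruth:
    segments: list[PlantedImbalance]
    het_fraction: float
    noise_sd: float


def simulate_baf_tracks(
    chrom_lengths: dict[str, int],
    imbalance_segments: list[PlantedImbalance],
    n_snps: int,
    noise_sd: float = 0.02,
    seed: int = 0,
    het_fraction: float = 0.6,
    sample_id: str = "P1",
) -> tuple[BafTrack, BafTrack, BafTruth]:
    """Paired baseline/resistant BAF tracks with planted imbalance.

    Heterozygous SNPs inside a baseline segment sit at 0.5 +/- delta with the
    sign mirrored at random per SNP; segments with fate ``lost`` revert to
    balance in the resistant track (the clonal-replacement pattern), fate
    ``gained`` appear only at resistance, ``shared`` persist. Homozygous
    SNPs sit at 0 or 1 in both tracks.
    """
    by_chrom: dict[str, list[PlantedImbalance]] = {}
    for seg in imbalance_segments:
        if seg.chrom not in chrom_lengths:
            raise ValidationError(f"segment on unknown chromosome {seg.chrom}")
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValidationError(f"overlapping segments on {chrom}")
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    frames = {"baseline": [], "resistant": []}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        k = max(1, round(n_snps * length / total))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(k, length), replace=False))
        het = rng.random(len(pos)) < het_fraction
        hom_allele = rng.random(len(pos)) < 0.5
        noise_b = rng.normal(0.0, noise_sd, size=len(pos))
        noise_r = rng.normal(0.0, noise_sd, size=len(pos))
        mirror = np.where(rng.random(len(pos)) < 0.5, 1.0, -1.0)
        for label, noise in (("baseline", noise_b), ("resistant", noise_r)):
            baf = np.where(het, 0.5, np.where(hom_allele, 1.0, 0.0)) + noise
            for seg in by_chrom.get(chrom, []):
                active = (seg.fate == "shared") or (
                    seg.fate == "lost" and label == "baseline"
                ) or (seg.fate == "gained" and label == "resistant")
                if not active:
                    continue
                inside = het & (pos >= seg.start) & (pos <= seg.end)
                baf = np.where(inside, 0.5 + mirror * seg.delta + noise, baf)
            baf = np.clip(baf, 0.0, 1.0)
            frames[label].append(
                pd.DataFrame({"chrom": chrom, "pos": pos, "baf": baf, "het": het})
            )
    baseline = BafTrack(
        sample_id=f"{sample_id}_T",
        snps=pd.concat(frames["baseline"], ignore_index=True),
    )
    resistant = BafTrack(
        sample_id=f"{sample_id}_RT",
        snps=pd.concat(frames["resistant"], ignore_index=True),
    )
    truth = BafTruth(segments=list(imbalance_segments), het_fraction=het_fraction, noise_sd=noise_sd)
    return baseline, resistant, truth


# ---------------------------------------------------------------------------
# Copy-number tables and clinical annotations
# ---------------------------------------------------------------------------


def simulate_cn_tables(
    gene_ids: list[str],
    planted: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-platform gene CN table; unplanted genes are diploid with jitter."""
    rng = np.random.default_rng(seed)
    planted = planted or {}
    rows = []
    for g in gene_ids:
        if g in planted:
            cn_a, cn_e = planted[g]
        else:
            cn_a = float(np.round(2.0 + rng.normal(0, 0.1), 3))
            cn_e = float(np.round(2.0 + rng.normal(0, 0.1), 3))
        rows.append({"gene_id": g, "cn_array": cn_a, "cn_exome": cn_e})
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_clinical_table(
    n_patients: int, n_resistant_pairs: int, seed: int = 0
) -> pd.DataFrame:
    """Per-patient best response and progression flags.

    The first ``n_resistant_pairs`` patients are responders who later
    progress (acquired resistance with a re-biopsy pair); the remainder
    split between intrinsically sensitive and intrinsically resistant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        if i < n_resistant_pairs:
            best, progressed, rebiopsy = "PR", True, True
        elif rng.random() < 0.5:
            best, progressed, rebiopsy = ("CR" if rng.random() < 0.2 else "PR"), False, False
        else:
            best, progressed, rebiopsy = ("SD" if rng.random() < 0.5 else "PD"), False, False
        rows.append(
            {
                "patient_id": pid,
                "best_response": best,
                "progressed_within_2mo": progressed,
                "has_rebiopsy": rebiopsy,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "best_response", "progressed_within_2mo", "has_rebiopsy"],
    )
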