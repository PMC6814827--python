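"""Somatic small-variant calling from multi-caller tumour/normal call sets.

The cascade mirrors a conventional matched tumour/normal exome workflow:

1. per-sample quality filter (genotype quality >= 30, >= 3 alt reads,
   VAF >= 0.05, depth >= 10, all boundaries inclusive);
2. union merge of up to three callers with provenance;
3. somatic test against the matched normal (depth >= 10, normal VAF <= 0.05,
   normal-vs-tumour VAF ratio rule) and a pooled panel of normals (at most
   two pooled normals with VAF >= 0.20 at the locus);
4. consequence classification by codon retranslation against a gene model
   and genome sequence;
5. tumour mutation burden as non-silent somatic mutations per megabase of
   captured target (51 Mb default, the standard whole-exome capture size).

The normal-vs-tumour ratio clause is ambiguous in prose descriptions of this
cascade ("normal VAF < 2X of the tumour VAF"); the default here is the
stringent reading, normal_vaf < 0.5 * tumour_vaf, with the literal reading
selectable via ``FilterThresholds.normal_vaf_rule``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel, ValidationError, VariantCall

logger = logging.getLogger(__name__)

CONSEQUENCES = ("silent", "non_silent", "non_coding")
# worst-first ordering used when a variant overlaps several genes
_SEVERITY = {"non_silent": 2, "silent": 1, "non_coding": 0}


@dataclass(frozen=True)
class FilterThresholds:
    """Quality and somatic-evidence thresholds for the filter cascade."""

    min_gq: float = 30.0
    min_alt_reads: int = 3
    min_vaf: float = 0.05
    min_depth: int = 10
    min_normal_depth: int = 10
    max_normal_vaf: float = 0.05
    normal_vaf_rule: str = "half_tumour"  # or "twice_tumour" (literal reading)
    max_pooled_hits: int = 2
    pooled_vaf_cut: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_gq", "min_alt_reads", "min_depth", "min_normal_depth", "max_pooled_hits"):
            if getattr(self, name) < 0:
                raise ValidationError(f"threshold {name} must be non-negative")
        for name in ("min_vaf", "max_normal_vaf", "pooled_vaf_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"threshold {name} must be in [0,1]")
        if self.normal_vaf_rule not in ("half_tumour", "twice_tumour"):
            raise ValidationError(f"unknown normal_vaf_rule {self.normal_vaf_rule!r}")


@dataclass
class SomaticVariant:
    """A tumour variant that passed the full somatic cascade."""

    call: VariantCall
    normal_depth: int
    normal_vaf: float
    pooled_hit_count: int
    consequence: str = "non_coding"
    gene_id: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.call.key


def filter_variant_calls(
    calls: list[VariantCall], thresholds: FilterThresholds | None = None
) -> list[VariantCall]:
    """Apply the per-sample quality filter; every boundary is inclusive."""
    t = thresholds or FilterThresholds()
    return [
        c
        for c in calls
        if c.genotype_quality >= t.min_gq
        and c.alt_reads >= t.min_alt_reads
        and c.vaf >= t.min_vaf
        and c.depth >= t.min_depth
    ]


def merge_caller_sets(caller_sets: dict[str, list[VariantCall]]) -> list[VariantCall]:
    """Union-merge per-caller call lists keyed by (chrom, pos, ref, alt).

    The merged record takes numeric fields from the supporting caller with
    the highest depth; the ``callers`` field accumulates provenance.
    """
    merged: dict[tuple, VariantCall] = {}
    provenance: dict[tuple, set[str]] = {}
    ref_seen: dict[tuple, str] = {}
    for caller, calls in caller_sets.items():
        for c in calls:
            key = c.key
            allele_key = (c.locus.chrom, c.locus.start, c.alt)
            prev_ref = ref_seen.setdefault(allele_key, c.ref)
            if prev_ref != c.ref:
                raise ValidationError(
                    f"conflicting REF alleles at {allele_key[:2]}: {prev_ref} vs {c.ref}"
                )
            provenance.setdefault(key, set()).add(caller)
            if key not in merged or c.depth > merged[key].depth:
                merged[key] = c
    out = []
    for key, c in merged.items():
        out.append(
            VariantCall(
                sample_id=c.sample_id,
                locus=c.locus,
                ref=c.ref,
                alt=c.alt,
                depth=c.depth,
                alt_reads=c.alt_reads,
                vaf=c.vaf,
                genotype_quality=c.genotype_quality,
                callers=frozenset(provenance[key]),
            )
        )
    out.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.ref, c.alt))
    return out


def _normal_vaf_ok(normal_vaf: float, tumour_vaf: float, rule: str) -> bool:
    if rule == "half_tumour":
        return normal_vaf < 0.5 * tumour_vaf
    return normal_vaf < 2.0 * tumour_vaf


def call_somatic(
    tumour_calls: list[VariantCall],
    normal_calls: list[VariantCall],
    pooled_normal_vafs: pd.DataFrame | None,
    thresholds: FilterThresholds | None = None,
) -> list[SomaticVariant]:
    """Somatic test of quality-filtered tumour calls against the matched and
    pooled normals.

    A locus absent from the matched-normal call set but with recorded normal
    coverage would need a coverage table; here the normal evidence comes from
    ``normal_calls`` (depth and VAF at matching loci). Loci with no matched
    normal record are treated as normal depth 0 and rejected (logged), the
    conservative choice when coverage is unknown.
    """
    t = thresholds or FilterThresholds()
    pooled_hit_counts: dict[tuple, int] = {}
    if pooled_normal_vafs is not None and len(pooled_normal_vafs):
        counts = (pooled_normal_vafs >= t.pooled_vaf_cut).sum(axis=1)
        pooled_hit_counts = {k: int(v) for k, v in counts.items()}
    normal_by_key: dict[tuple, VariantCall] = {}
    normal_by_pos: dict[tuple, VariantCall] = {}
    for n in normal_calls:
        normal_by_key[n.key] = n
        normal_by_pos.setdefault((n.locus.chrom, n.locus.start), n)
    out: list[SomaticVariant] = []
    n_missing = 0
    for c in tumour_calls:
        n = normal_by_key.get(c.key) or normal_by_pos.get((c.locus.chrom, c.locus.start))
        if n is None:
            n_missing += 1
            continue
        # normal VAF for this allele: 0 when the matched record is a pure
        # reference observation at the locus (alt mismatch)
        normal_vaf = n.vaf if n.key == c.key or n.alt == c.alt else 0.0
        if n.depth < t.min_normal_depth:
            continue
        if normal_vaf > t.max_normal_vaf:
            continue
        if not _normal_vaf_ok(normal_vaf, c.vaf, t.normal_vaf_rule):
            continue
        pooled_hits = pooled_hit_counts.get(c.key, 0)
        if pooled_hits > t.max_pooled_hits:
            continue
        out.append(
            SomaticVariant(
                call=c,
                normal_depth=n.depth,
                normal_vaf=normal_vaf,
                pooled_hit_count=pooled_hits,
            )
        )
    if n_missing:
        logger.info("call_somatic: %d tumour loci without matched-normal coverage rejected", n_missing)
    return out


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------


def _classify_in_gene(
    call: VariantCall, gene: GeneModel, genome: dict[str, str]
) -> str:
    """Consequence of a variant against one gene model."""
    if not gene.coding:
        return "non_coding"
    pos = call.locus.start
    idx = gene.coding_index(pos)
    if not call.is_snv():
        # any indel touching CDS is protein-altering
        touches_cds = any(
            c.start <= call.locus.end and call.locus.start <= c.end for c in gene.cds
        )
        return "non_silent" if touches_cds else "non_coding"
    if idx is None:
        return "non_coding"
    frame_off = idx - gene.coding_start_phase
    if frame_off < 0:
        return "non_coding"  # within the phase-skipped leading bases
    cds_seq = gene.spliced_cds(genome)
    codon_i = frame_off // 3
    codon_start = gene.coding_start_phase + codon_i * 3
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        return "non_coding"  # trailing partial codon
    alt_base = call.alt if gene.strand == "+" else str(Seq(call.alt).reverse_complement())
    ref_base = call.ref if gene.strand == "+" else str(Seq(call.ref).reverse_complement())
    within = idx - codon_start
    if codon[within] != ref_base:
        logger.warning(
            "gene %s pos %d: reference base %s disagrees with genome %s",
            gene.gene_id, pos, ref_base, codon[within],
        )
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "silent" if aa_ref == aa_alt else "non_silent"


def classify_consequence(
    call: VariantCall, gene_models: list[GeneModel], genome: dict[str, str]
) -> tuple[str, str | None]:
    """Classify one variant as silent / non_silent / non_coding.

    When the variant overlaps several genes it is classified against each and
    the worst consequence wins (non_silent > silent > non_coding), which is
    conservative for mutation-burden counting.
    """
    hits = [g for g in gene_models if g.contains(call.locus.chrom, call.locus.start)]
    if not hits:
        return "non_coding", None
    if len(hits) > 1:
        logger.info(
            "variant %s overlaps %d genes; taking worst consequence",
            call.key, len(hits),
        )
    best = ("non_coding", hits[0].gene_id)
    for g in hits:
        cons = _classify_in_gene(call, g, genome)
        if _SEVERITY[cons] > _SEVERITY[best[0]]:
            best = (cons, g.gene_id)
    return best


def annotate_consequences(
    variants: list[SomaticVariant],
    gene_models: list[GeneModel],
    genome: dict[str, str],
) -> list[SomaticVariant]:
    """Assign consequence and gene to each somatic variant in place."""
    for v in variants:
        cons, gene_id = classify_consequence(v.call, gene_models, genome)
        v.consequence = cons
        v.gene_id = gene_id
    return variants


def compute_tmb(somatic_variants: list[SomaticVariant], target_mb: float = 51.0) -> float:
    """Tumour mutation burden: non-silent somatic mutations per Mb of target."""
    if target_mb <= 0:
        raise ValidationError("target_mb must be positive")
    n = sum(1 for v in somatic_variants if v.consequence == "non_silent")
    return n / target_mb
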