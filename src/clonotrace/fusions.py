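"""RNA-seq gene-fusion calling from split-read and spanning-pair evidence.

The caller consumes an aligner-neutral junction table (one row per read with
split or spanning-pair evidence) rather than raw BAM, so the algorithm is
isolated from any particular aligner's tag conventions. The chain is:

1. assign read evidence to ordered (5', 3') gene pairs by coordinate overlap;
2. discard normal-splicing (``split_splice``) evidence between genes less
   than 5 kb apart — read-through transcription, not fusion;
3. per gene pair, take the modal split-read junction as breakpoint consensus;
4. verify that the junction joins the two CDSs in frame and retains at least
   10 amino acids from both partners;
5. discard pairs seen in >1% of a non-cancer panel or >10% of a cancer panel;
6. require >= 5 total supporting reads (split + spanning pairs).

Frame is checked by CDS phase arithmetic only; stop codons created by the
junction-spanning hybrid codon are not scanned (documented limitation).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneModel, ValidationError

logger = logging.getLogger(__name__)

DISCARD_REASONS = (
    "proximity",      # only read-through splice evidence, removed by the 5 kb rule
    "no_junction",    # no split evidence to place a breakpoint
    "frame",          # CDS junction out of frame (or non-CDS breakpoint)
    "short_peptide",  # fewer than 10 aa retained on one side
    "panel",          # frequent in the non-cancer or cancer panel
    "support",        # fewer than 5 total reads
)


@dataclass(frozen=True)
class JunctionEvidence:
    """One read's chimeric evidence between two genes."""

    read_id: str
    evidence_type: str
    gene5: str
    pos5: int
    gene3: str
    pos3: int


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    junction5: int | None
    junction3: int | None
    in_frame: bool
    aa5: int
    aa3: int
    split_reads: int
    spanning_pairs: int
    freq_noncancer_panel: float
    freq_cancer_panel: float
    status: str  # "retained" or "discarded"
    reason: str | None = None

    @property
    def total_reads(self) -> int:
        return self.split_reads + self.spanning_pairs


def _locate_gene(gene_models: list[GeneModel], chrom: str, pos: int) -> GeneModel | None:
    for g in gene_models:
        if g.contains(chrom, pos):
            return g
    return None


def collect_junction_evidence(
    junction_table: pd.DataFrame, gene_models: list[GeneModel]
) -> dict[tuple[str, str], list[JunctionEvidence]]:
    """Group read evidence by ordered (5' gene, 3' gene) pair.

    Reads whose two sides do not fall in two distinct genes are dropped
    (counted in the log). One read_id contributes at most one evidence
    record per gene pair.
    """
    groups: dict[tuple[str, str], list[JunctionEvidence]] = {}
    seen: set[tuple[str, str, str]] = set()
    n_dropped = 0
    for row in junction_table.itertuples(index=False):
        g5 = _locate_gene(gene_models, row.chrom5, int(row.pos5))
        g3 = _locate_gene(gene_models, row.chrom3, int(row.pos3))
        if g5 is None or g3 is None or g5.gene_id == g3.gene_id:
            n_dropped += 1
            continue
        key = (g5.gene_id, g3.gene_id)
        dedup = (row.read_id, *key)
        if dedup in seen:
            continue
        seen.add(dedup)
        groups.setdefault(key, []).append(
            JunctionEvidence(
                read_id=row.read_id,
                evidence_type=row.evidence_type,
                gene5=g5.gene_id,
                pos5=int(row.pos5),
                gene3=g3.gene_id,
                pos3=int(row.pos3),
            )
        )
    if n_dropped:
        logger.info("collect_junction_evidence: dropped %d single-gene/unassigned reads", n_dropped)
    return groups


def gene_gap(a: GeneModel, b: GeneModel) -> float:
    """Genomic gap between the nearest transcript ends of two genes.

    0 for overlapping genes; +inf for genes on different chromosomes.
    """
    if a.chrom != b.chrom:
        return float("inf")
    if a.start <= b.end and b.start <= a.end:
        return 0.0
    return float(max(a.start, b.start) - min(a.end, b.end) - 1)


def apply_proximity_filter(
    groups: dict[tuple[str, str], list[JunctionEvidence]],
    gene_models: list[GeneModel],
    max_dist: int = 5000,
) -> dict[tuple[str, str], list[JunctionEvidence]]:
    """Remove normal-splicing evidence between genes < ``max_dist`` bp apart.

    Only ``split_splice`` records are affected: chimeric-tag splits and
    spanning pairs survive regardless of proximity.
    """
    by_id = {g.gene_id: g for g in gene_models}
    out: dict[tuple[str, str], list[JunctionEvidence]] = {}
    for (g5, g3), evs in groups.items():
        close = gene_gap(by_id[g5], by_id[g3]) < max_dist
        kept = [e for e in evs if not (close and e.evidence_type == "split_splice")]
        out[(g5, g3)] = kept
    return out


def check_reading_frame(
    gene5: GeneModel, junction5: int, gene3: GeneModel, junction3: int
) -> tuple[bool, int, int, str | None]:
    """Frame compatibility and retained peptide lengths at a fusion junction.

    ``junction5`` is the genomic position of the last retained base of the 5'
    partner; ``junction3`` the first retained base of the 3' partner. Both
    must lie inside CDS. The fused transcript is in frame when the 3'
    fragment starts at the same within-codon offset it occupies in its
    native transcript, so translation reads through without frameshift.
    Returns (in_frame, aa5, aa3, failure_reason).
    """
    if not (gene5.coding and gene3.coding):
        return False, 0, 0, "non-CDS junction"
    idx5 = gene5.coding_index(junction5)
    idx3 = gene3.coding_index(junction3)
    if idx5 is None or idx3 is None:
        return False, 0, 0, "non-CDS junction"
    n5 = idx5 + 1  # coding bases retained from the 5' gene
    off5 = n5 - gene5.coding_start_phase
    off3 = idx3 - gene3.coding_start_phase
    if off5 < 0 or off3 < 0:
        return False, 0, 0, "non-CDS junction"
    aa5 = off5 // 3
    aa3 = (gene3.cds_length - idx3) // 3
    in_frame = (off5 % 3) == (off3 % 3)
    return in_frame, aa5, aa3, None


def apply_panel_filters(
    candidates: list[FusionCandidate],
    noncancer_freqs: dict[tuple[str, str], float] | None,
    cancer_freqs: dict[tuple[str, str], float] | None,
    max_noncancer: float = 0.01,
    max_cancer: float = 0.10,
) -> list[FusionCandidate]:
    """Discard recurrent-artifact pairs: >1% non-cancer or >10% cancer panel.

    Both comparisons are strict, so a pair at exactly the panel threshold is
    retained. Pairs absent from a panel have frequency 0.
    """
    noncancer_freqs = noncancer_freqs or {}
    cancer_freqs = cancer_freqs or {}
    for c in candidates:
        if c.status == "discarded":
            continue
        pair = (c.gene5, c.gene3)
        c.freq_noncancer_panel = float(noncancer_freqs.get(pair, 0.0))
        c.freq_cancer_panel = float(cancer_freqs.get(pair, 0.0))
        if c.freq_noncancer_panel > max_noncancer or c.freq_cancer_panel > max_cancer:
            c.status = "discarded"
            c.reason = "panel"
    return candidates


def _breakpoint_consensus(split_evs: list[JunctionEvidence]) -> tuple[int, int]:
    """Modal (junction5, junction3); ties broken by the 5'-most junction5."""
    counts = Counter((e.pos5, e.pos3) for e in split_evs)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
    return best[0]


def call_fusions(
    junction_table: pd.DataFrame,
    gene_models: list[GeneModel],
    noncancer_freqs: dict[tuple[str, str], float] | None = None,
    cancer_freqs: dict[tuple[str, str], float] | None = None,
    min_total_reads: int = 5,
    min_aa: int = 10,
    max_dist: int = 5000,
) -> list[FusionCandidate]:
    """Run the full fusion-calling chain; see module docstring for the order.

    Every discarded candidate carries the first reason that failed. Retained
    candidates are sorted by total read support, descending.
    """
    by_id = {g.gene_id: g for g in gene_models}
    groups_raw = collect_junction_evidence(junction_table, gene_models)
    groups = apply_proximity_filter(groups_raw, gene_models, max_dist=max_dist)
    candidates: list[FusionCandidate] = []
    for (g5_id, g3_id), evs in sorted(groups.items()):
        split_evs = [e for e in evs if e.evidence_type in ("split_splice", "split_chimeric")]
        pairs = [e for e in evs if e.evidence_type == "spanning_pair"]
        cand = FusionCandidate(
            gene5=g5_id,
            gene3=g3_id,
            junction5=None,
            junction3=None,
            in_frame=False,
            aa5=0,
            aa3=0,
            split_reads=len(split_evs),
            spanning_pairs=len(pairs),
            freq_noncancer_panel=0.0,
            freq_cancer_panel=0.0,
            status="retained",
        )
        if not split_evs:
            # distinguish read-through (splice reads removed by the 5 kb
            # rule) from pairs-only groups that never had a placeable junction
            lost_to_proximity = len(evs) < len(groups_raw[(g5_id, g3_id)])
            cand.status = "discarded"
            cand.reason = "proximity" if lost_to_proximity else "no_junction"
            candidates.append(cand)
            continue
        j5, j3 = _breakpoint_consensus(split_evs)
        cand.junction5, cand.junction3 = j5, j3
        in_frame, aa5, aa3, why = check_reading_frame(by_id[g5_id], j5, by_id[g3_id], j3)
        cand.in_frame, cand.aa5, cand.aa3 = in_frame, aa5, aa3
        if not in_frame:
            cand.status = "discarded"
            cand.reason = "frame"
        elif aa5 < min_aa or aa3 < min_aa:
            cand.status = "discarded"
            cand.reason = "short_peptide"
        candidates.append(cand)
    apply_panel_filters(candidates, noncancer_freqs, cancer_freqs)
    for c in candidates:
        if c.status == "retained" and c.total_reads < min_total_reads:
            c.status = "discarded"
            c.reason = "support"
    retained = [c for c in candidates if c.status == "retained"]
    discarded = [c for c in candidates if c.status == "discarded"]
    retained.sort(key=lambda c: (-c.total_reads, c.gene5, c.gene3))
    return retained + discarded


def quantify_partner_expression(
    counts: pd.DataFrame,
    gene: str,
    tumour_sample: str,
    normal_sample: str,
    pseudocount: float = 0.5,
) -> float:
    """Fold overexpression of a fusion partner in tumour vs matched normal.

    Both samples are scaled to reads per million; the fold difference is
    (RPM_tumour + pc) / (RPM_normal + pc) with pseudocount pc = 0.5.
    """
    if gene not in counts.index:
        raise ValidationError(f"gene {gene!r} absent from counts matrix")
    for s in (tumour_sample, normal_sample):
        if s not in counts.columns:
            raise ValidationError(f"sample {s!r} absent from counts matrix")
    totals = counts.sum(axis=0)
    rpm_t = counts.at[gene, tumour_sample] * 1e6 / totals[tumour_sample]
    rpm_n = counts.at[gene, normal_sample] * 1e6 / totals[normal_sample]
    return (rpm_t + pseudocount) / (rpm_n + pseudocount)
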