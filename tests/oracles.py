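"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: consequence labels come
from full-protein retranslation, fusion frames from concatenating and
translating the two CDS fragments, and quantile normalisation from a naive
per-column loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from clonotrace.io_formats import GeneModel, VariantCall


def _translate_full(cds: str, phase: int) -> str:
    coding = cds[phase:]
    coding = coding[: len(coding) // 3 * 3]
    return str(Seq(coding).translate())


def consequence_by_retranslation(
    call: VariantCall, gene: GeneModel, genome: dict[str, str]
) -> str:
    """Full-CDS retranslation: translate the whole protein before and after
    the substitution and compare."""
    if not gene.coding:
        return "non_coding"
    if not call.is_snv():
        touches = any(
            c.start <= call.locus.end and call.locus.start <= c.end for c in gene.cds
        )
        return "non_silent" if touches else "non_coding"
    idx = gene.coding_index(call.locus.start)
    if idx is None:
        return "non_coding"
    if idx < gene.coding_start_phase:
        return "non_coding"
    tail = gene.cds_length - gene.coding_start_phase
    if idx - gene.coding_start_phase >= tail // 3 * 3:
        return "non_coding"  # trailing partial codon
    cds = gene.spliced_cds(genome)
    alt = call.alt if gene.strand == "+" else str(Seq(call.alt).complement())
    mutated = cds[:idx] + alt + cds[idx + 1 :]
    before = _translate_full(cds, gene.coding_start_phase)
    after = _translate_full(mutated, gene.coding_start_phase)
    return "silent" if before == after else "non_silent"


def frame_by_concatenation(
    gene5: GeneModel, j5: int, gene3: GeneModel, j3: int, genome: dict[str, str]
) -> bool | None:
    """Concatenate-and-translate frame oracle.

    Builds the hybrid coding sequence (5' fragment up to and including j5,
    3' fragment from j3 on), translates it, and declares the fusion in
    frame iff the hybrid protein ends with the 3' partner's native peptide
    downstream of the junction. Returns None when the downstream peptide is
    too short to be informative.
    """
    i5 = gene5.coding_index(j5)
    i3 = gene3.coding_index(j3)
    if i5 is None or i3 is None:
        return None
    cds5 = gene5.spliced_cds(genome)
    cds3 = gene3.spliced_cds(genome)
    hybrid = cds5[gene5.coding_start_phase : i5 + 1] + cds3[i3:]
    prot_h = _translate_full(hybrid, 0)
    prot3 = _translate_full(cds3, gene3.coding_start_phase)
    off3 = i3 - gene3.coding_start_phase
    first_full_codon = (off3 + 2) // 3
    tail = prot3[first_full_codon:]
    if len(tail) < 5:
        return None
    return prot_h.endswith(tail)


def naive_quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-sorted-vectors quantile normalisation, one column at a time."""
    x = df.to_numpy(dtype=float)
    reference = np.mean(np.sort(x, axis=0), axis=1)
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        for i in range(len(col)):
            tied = np.flatnonzero(col == col[i])
            # positions this tie group occupies in the sorted column
            n_below = int((col < col[i]).sum())
            span = range(n_below, n_below + len(tied))
            out[i, j] = float(np.mean(reference[list(span)]))
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def somatic_row_check(call, normal_depth, normal_vaf, pooled_hits, t) -> bool:
    """Single-pass independent re-check of all somatic predicates."""
    return (
        call.genotype_quality >= t.min_gq
        and call.alt_reads >= t.min_alt_reads
        and call.vaf >= t.min_vaf
        and call.depth >= t.min_depth
        and normal_depth >= t.min_normal_depth
        and normal_vaf <= t.max_normal_vaf
        and (
            normal_vaf < 0.5 * call.vaf
            if t.normal_vaf_rule == "half_tumour"
            else normal_vaf < 2 * call.vaf
        )
        and pooled_hits <= t.max_pooled_hits
    )
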