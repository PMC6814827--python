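"""Gene-level copy-number status with cross-platform consensus, and
B-allele-frequency allelic-imbalance segmentation for paired biopsies.

Copy-number status uses the conventional cutoffs AMP: CN >= 4 (inclusive)
and DEL: CN < 0.5 (strict). A call is *reliable* only when the SNP-array and
exome-derived copy numbers agree on a non-neutral status; a missing platform
makes the call unreliable.

Allelic imbalance is detected on folded BAF deviations |BAF - 0.5| of
heterozygous SNPs in consecutive windows. A window is imbalanced when its
mean folded deviation reaches ``dev_cut`` *and* a one-sided t-test rejects
the hypothesis that the mean folded deviation is at most ``dev_cut`` at
alpha = 0.01. Folding makes the statistic symmetric under BAF -> 1 - BAF,
so mirrored imbalance (60/40 vs 40/60) is treated identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

AMP_CUT = 4.0
DEL_CUT = 0.5


@dataclass
class CnCall:
    gene_id: str
    cn_array: float | None
    cn_exome: float | None
    status: str = "neutral"  # status of the array platform (primary)
    reliable: bool = False
    in_census: bool = False


@dataclass
class BafTrack:
    """Per-SNP B-allele fractions for one sample."""

    sample_id: str
    snps: pd.DataFrame  # columns chrom, pos, baf, het

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "baf", "het"}
        missing = required - set(self.snps.columns)
        if missing:
            raise ValidationError(f"BAF track missing columns {sorted(missing)}")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValidationError(
                    f"BAF positions not strictly increasing on {chrom}"
                )
        if ((self.snps["baf"] < 0) | (self.snps["baf"] > 1)).any():
            raise ValidationError("BAF outside [0,1]")


@dataclass
class ImbalanceSegment:
    chrom: str
    start: int
    end: int
    n_het_snps: int
    mean_dev: float
    imbalanced: bool = True


def _cn_status(cn: float | None, amp_cut: float, del_cut: float) -> str | None:
    if cn is None or (isinstance(cn, float) and math.isnan(cn)):
        return None
    if cn < 0:
        raise ValidationError(f"negative copy number {cn}")
    if cn >= amp_cut:
        return "AMP"
    if cn < del_cut:
        return "DEL"
    return "neutral"


def call_gene_cn_status(
    cn_table: pd.DataFrame,
    census_genes: set[str] | None = None,
    amp_cut: float = AMP_CUT,
    del_cut: float = DEL_CUT,
) -> list[CnCall]:
    """Status per gene from a TSV-derived table with cn_array / cn_exome.

    The reported status follows the array platform; the exome value feeds the
    consensus rule. Census membership is flagged so reporting can restrict to
    a cancer-gene census list.
    """
    census_genes = census_genes or set()
    calls = []
    for row in cn_table.itertuples():
        gene_id = row.Index if cn_table.index.name == "gene_id" else row.gene_id
        cn_a = getattr(row, "cn_array", None)
        cn_e = getattr(row, "cn_exome", None)
        status_a = _cn_status(cn_a, amp_cut, del_cut)
        call = CnCall(
            gene_id=str(gene_id),
            cn_array=cn_a,
            cn_exome=cn_e,
            status=status_a or "neutral",
            in_census=str(gene_id) in census_genes,
        )
        calls.append(call)
    return consensus_cn(calls, amp_cut=amp_cut, del_cut=del_cut)


def consensus_cn(
    calls: list[CnCall], amp_cut: float = AMP_CUT, del_cut: float = DEL_CUT
) -> list[CnCall]:
    """Flag calls reliable when both platforms agree on a non-neutral status.

    Symmetric in the two platforms; a missing platform value (None/NaN)
    makes the call unreliable.
    """
    for c in calls:
        s_a = _cn_status(c.cn_array, amp_cut, del_cut)
        s_e = _cn_status(c.cn_exome, amp_cut, del_cut)
        c.reliable = s_a is not None and s_a == s_e and s_a != "neutral"
    return calls


def detect_allelic_imbalance(
    track: BafTrack,
    window_snps: int = 25,
    dev_cut: float = 0.05,
    min_snps: int = 10,
    alpha: float = 0.01,
) -> list[ImbalanceSegment]:
    """Windowed detection of allelic imbalance on heterozygous SNPs.

    Consecutive windows of ``window_snps`` het SNPs are tested per
    chromosome; adjacent imbalanced windows merge into one segment, so
    segment boundaries are accurate to within one window of het SNPs.
    Chromosomes with fewer than ``min_snps`` het SNPs are skipped (logged).
    """
    segments: list[ImbalanceSegment] = []
    het = track.snps[track.snps["het"].astype(bool)]
    for chrom, grp in het.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        dev = np.abs(grp["baf"].to_numpy() - 0.5)
        if len(pos) < min_snps:
            logger.info("chromosome %s: only %d het SNPs, skipped", chrom, len(pos))
            continue
        flags = []
        bounds = []
        for w0 in range(0, len(pos) - window_snps + 1, window_snps):
            w = slice(w0, w0 + window_snps)
            d = dev[w]
            mean_dev = float(d.mean())
            sd = float(d.std(ddof=1))
            if mean_dev < dev_cut:
                reject = False
            elif sd == 0.0:
                reject = mean_dev > dev_cut
            else:
                tstat = (mean_dev - dev_cut) / (sd / math.sqrt(len(d)))
                reject = stats.t.sf(tstat, df=len(d) - 1) < alpha
            flags.append(reject)
            bounds.append((int(pos[w0]), int(pos[w0 + window_snps - 1]), mean_dev, len(d)))
        i = 0
        while i < len(flags):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            devs = [bounds[k][2] * bounds[k][3] for k in range(i, j + 1)]
            n = sum(bounds[k][3] for k in range(i, j + 1))
            segments.append(
                ImbalanceSegment(
                    chrom=str(chrom),
                    start=bounds[i][0],
                    end=bounds[j][1],
                    n_het_snps=n,
                    mean_dev=sum(devs) / n,
                )
            )
            i = j + 1
    return segments


def _reciprocal_overlap(a: ImbalanceSegment, b: ImbalanceSegment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start + 1), inter / (b.end - b.start + 1))


def compare_imbalance(
    baseline: list[ImbalanceSegment],
    resistant: list[ImbalanceSegment],
    min_reciprocal: float = 0.5,
) -> list[tuple[ImbalanceSegment, str]]:
    """Classify imbalance segments as lost / gained / shared between biopsies.

    Segments match when their reciprocal overlap is at least 50%. A
    baseline-only segment is *lost* at resistance (the hallmark of clonal
    replacement), a resistant-only segment is *gained*.
    """
    out: list[tuple[ImbalanceSegment, str]] = []
    matched_resistant: set[int] = set()
    for seg in baseline:
        hit = None
        for i, r in enumerate(resistant):
            if i in matched_resistant:
                continue
            if _reciprocal_overlap(seg, r) >= min_reciprocal:
                hit = i
                break
        if hit is None:
            out.append((seg, "lost"))
        else:
            matched_resistant.add(hit)
            out.append((seg, "shared"))
    for i, r in enumerate(resistant):
        if i not in matched_resistant:
            out.append((r, "gained"))
    return out


# ---------------------------------------------------------------------------
# TSV / BED IO for BAF tracks and segments
# ---------------------------------------------------------------------------


def read_baf_track(path: str, sample_id: str | None = None) -> BafTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return BafTrack(sample_id=sample_id or path, snps=df)


def write_baf_track(path: str, track: BafTrack) -> None:
    track.snps.to_csv(path, sep="\t", index=False)


def read_cn_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: missing gene_id column")
    return df.set_index("gene_id")


def write_cn_table(path: str, table: pd.DataFrame) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def write_segments_bed(path: str, segments: list[ImbalanceSegment]) -> None:
    """Segments as BED (0-based half-open) with mean deviation as score."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.mean_dev:.4f}\n")


def read_segments_bed(path: str) -> list[ImbalanceSegment]:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, score = line.split("\t")[:4]
            segs.append(
                ImbalanceSegment(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    n_het_snps=0,
                    mean_dev=float(score),
                )
            )
    return segs
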