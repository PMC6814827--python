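"""Readers/writers for the external file formats and the canonical in-memory types.

External files use the community conventions: VCF v4.2 for small variants
(parsed with :mod:`pysam`), GTF for gene models (parsed with :mod:`gffutils`),
FASTA for toy genomes (via Biopython), and plain TSV for count matrices,
pooled-normal allele-fraction tables and chimeric-junction evidence.

Coordinates are 1-based inclusive throughout, matching VCF/GTF. Gene models
store exons and CDS intervals in *transcription* order, i.e. ascending genomic
position on the ``+`` strand and descending on ``-``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomicInterval",
    "GeneModel",
    "VariantCall",
    "read_variant_calls",
    "write_variant_calls",
    "read_gene_models",
    "write_gene_models",
    "read_counts_matrix",
    "write_counts_matrix",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_pooled_vaf_table",
    "write_pooled_vaf_table",
    "read_junction_table",
    "write_junction_table",
]

JUNCTION_COLUMNS = [
    "read_id",
    "evidence_type",
    "chrom5",
    "pos5",
    "strand5",
    "chrom3",
    "pos3",
    "strand3",
]

EVIDENCE_TYPES = {"split_splice", "split_chimeric", "spanning_pair"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GeneModel:
    """A gene with exon structure and (optionally) a CDS.

    ``exons`` and ``cds`` are kept in transcription order. ``coding_start_phase``
    is the GTF frame of the first CDS interval: the number of bases to skip
    before the first complete codon.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    coding_start_phase: int = 0

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def validate(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end >= b.start:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        expected = by_start if self.strand == "+" else by_start[::-1]
        if self.exons != expected:
            raise ValidationError(
                f"gene {self.gene_id}: exons not in transcription order"
            )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValidationError(
                    f"gene {self.gene_id}: CDS {c.start}-{c.end} outside exons"
                )
        if self.cds and self.cds_length < 3:
            raise ValidationError(f"gene {self.gene_id}: CDS shorter than one codon")
        if not 0 <= self.coding_start_phase <= 2:
            raise ValidationError(f"gene {self.gene_id}: bad phase")

    # --- CDS coordinate helpers -------------------------------------------

    def coding_index(self, pos: int) -> int | None:
        """0-based index of genomic position ``pos`` within the spliced CDS.

        Indexing follows transcription order; returns None when ``pos`` does
        not fall in any CDS interval.
        """
        offset = 0
        for c in self.cds:
            if c.start <= pos <= c.end:
                if self.strand == "+":
                    return offset + (pos - c.start)
                return offset + (c.end - pos)
            offset += len(c)
        return None

    def genomic_position(self, idx: int) -> int:
        """Genomic position of the 0-based spliced-CDS index ``idx``."""
        offset = 0
        for c in self.cds:
            if idx < offset + len(c):
                within = idx - offset
                return c.start + within if self.strand == "+" else c.end - within
            offset += len(c)
        raise ValidationError(f"gene {self.gene_id}: CDS index {idx} out of range")

    def spliced_cds(self, genome: dict[str, str]) -> str:
        """The CDS nucleotide sequence in transcription order (5'->3' mRNA)."""
        seq = genome[self.chrom]
        parts = []
        for c in self.cds:
            piece = seq[c.start - 1 : c.end]
            if self.strand == "-":
                piece = str(Seq(piece).reverse_complement())
            parts.append(piece)
        return "".join(parts)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class VariantCall:
    """One ALT-allele observation in one sample."""

    sample_id: str
    locus: GenomicInterval
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    genotype_quality: float
    callers: frozenset = frozenset({"callerA"})

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"{self.key}: alt_reads {self.alt_reads} > depth {self.depth}"
            )
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.01:
            raise ValidationError(f"{self.key}: VAF inconsistent with AD/DP")
        if not self.callers:
            raise ValidationError(f"{self.key}: empty caller set")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.locus.chrom, self.locus.start, self.ref, self.alt)

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting variant callers">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def read_variant_calls(path: str, sample_id: str | None = None) -> list[VariantCall]:
    """Read a VCF into VariantCall records, one per ALT allele.

    Multi-allelic records are split; DP is carried to every split allele and
    VAF is computed as AD[alt]/DP. A missing GQ is treated as 0 (it then
    fails any genotype-quality filter, the conservative choice). An empty
    file yields an empty list.
    """
    if os.path.getsize(path) == 0:
        return []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if sample_id is None:
            if not samples:
                raise FormatError(f"{path}: VCF has no sample columns")
            sample_id = samples[0]
        elif sample_id not in samples:
            raise FormatError(f"{path}: sample {sample_id!r} not in VCF")
        header_lines = str(vcf.header).count("\n")
        calls: list[VariantCall] = []
        for i, rec in enumerate(vcf):
            line_no = header_lines + i + 1
            fmt = rec.samples[sample_id]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            if ad is None or all(a is None for a in ad):
                raise FormatError(f"{path} line {line_no}: missing AD field")
            if dp is None:
                raise FormatError(f"{path} line {line_no}: missing DP field")
            gq = fmt.get("GQ")
            gq = 0 if gq is None else gq
            try:
                callers = rec.info.get("CALLERS")
            except (KeyError, ValueError):  # tag not declared in header
                callers = None
            if isinstance(callers, str):
                callers = (callers,)
            caller_set = (
                frozenset(callers) if callers else frozenset({"callerA"})
            )
            for j, alt in enumerate(rec.alts or ()):
                alt_reads = ad[j + 1] if ad[j + 1] is not None else 0
                vaf = alt_reads / dp if dp > 0 else 0.0
                locus = GenomicInterval(
                    rec.chrom, rec.pos, rec.pos + len(rec.ref) - 1
                )
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        locus=locus,
                        ref=rec.ref,
                        alt=alt,
                        depth=dp,
                        alt_reads=alt_reads,
                        vaf=vaf,
                        genotype_quality=gq,
                        callers=caller_set,
                    )
                )
    return calls


def write_variant_calls(path: str, calls: list[VariantCall], sample_id: str | None = None) -> None:
    """Write VariantCalls as a biallelic VCF v4.2.

    VAF is normalised to AD/DP on output, so write->read round-trips are
    exact for calls whose VAF already equals alt_reads/depth.
    """
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "SAMPLE"
    lines = [_VCF_HEADER + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}"]
    for c in sorted(calls, key=lambda c: (c.locus.chrom, c.locus.start, c.ref, c.alt)):
        gt = "1/1" if c.depth > 0 and c.vaf > 0.9 else "0/1"
        info = "CALLERS=" + ",".join(sorted(c.callers))
        lines.append(
            f"{c.locus.chrom}\t{c.locus.start}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\t"
            f"GT:AD:DP:GQ\t{gt}:{c.depth - c.alt_reads},{c.alt_reads}:{c.depth}:{int(c.genotype_quality)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str) -> list[GeneModel]:
    """Parse a GTF into GeneModel records.

    Requires gene/exon/CDS features carrying ``gene_id``. The CDS frame
    column of the transcription-wise first CDS becomes ``coding_start_phase``.
    Genes without CDS features are returned as non-coding models.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["gene_id"][0]
        gene_name = g.attributes.get("gene_name", [gene_id])[0]
        exons = []
        cds = []
        for f in db.children(g, featuretype="exon"):
            exons.append(GenomicInterval(f.seqid, f.start, f.end, g.strand))
        phases: dict[tuple[int, int], int] = {}
        for f in db.children(g, featuretype="CDS"):
            cds.append(GenomicInterval(f.seqid, f.start, f.end, g.strand))
            phases[(f.start, f.end)] = int(f.frame) if f.frame in "012" else 0
        reverse = g.strand == "-"
        exons.sort(key=lambda e: e.start, reverse=reverse)
        cds.sort(key=lambda c: c.start, reverse=reverse)
        phase = phases[(cds[0].start, cds[0].end)] if cds else 0
        model = GeneModel(
            gene_id=gene_id,
            gene_name=gene_name,
            chrom=g.seqid,
            strand=g.strand,
            exons=exons,
            cds=cds,
            coding_start_phase=phase,
        )
        model.validate()
        genes.append(model)
    return genes


def write_gene_models(path: str, genes: list[GeneModel], source: str = "clonotrace") -> None:
    """Write GeneModels as GTF with gene/transcript/exon/CDS features."""
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
        tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_name "{g.gene_name}";'
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{g.chrom}\t{source}\ttranscript\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}"
        )
        for e in g.exons:
            lines.append(
                f"{g.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t{tattrs}"
            )
        consumed = 0
        for c in g.cds:
            frame = (3 - ((consumed - g.coding_start_phase) % 3)) % 3 if consumed else g.coding_start_phase
            lines.append(
                f"{g.chrom}\t{source}\tCDS\t{c.start}\t{c.end}\t.\t{g.strand}\t{frame}\t{tattrs}"
            )
            consumed += len(c)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------


def read_counts_matrix(path: str) -> pd.DataFrame:
    """Read a genes x samples TSV of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    try:
        values = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric counts") from exc
    if (values.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    values.index.name = df.index.name or "gene_id"
    return values


def write_counts_matrix(path: str, counts: pd.DataFrame) -> None:
    out = counts.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genome_fasta(path: str, genome: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_pooled_vaf_table(path: str) -> pd.DataFrame:
    """Locus x pooled-normal VAF table, indexed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.set_index(required)
    if ((df.values < 0) | (df.values > 1)).any():
        raise FormatError(f"{path}: VAF outside [0,1]")
    return df


def write_pooled_vaf_table(path: str, table: pd.DataFrame) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def read_junction_table(path: str) -> pd.DataFrame:
    """Read the aligner-neutral chimeric-junction evidence table.

    This TSV stands in for split ('N'-CIGAR / chimeric-tag) and spanning-pair
    records that a fusion-aware aligner would emit in BAM.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom5": str, "chrom3": str})
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = set(df["evidence_type"]) - EVIDENCE_TYPES
    if bad:
        raise FormatError(f"{path}: unknown evidence types {sorted(bad)}")
    return df[JUNCTION_COLUMNS]


def write_junction_table(path: str, table: pd.DataFrame) -> None:
    table[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)
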