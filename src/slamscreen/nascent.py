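"""Nascent-read calling from T>C conversions.

Metabolic labeling with 4sU followed by chemical conversion makes uridines
incorporated during the labeling window read as cytosines.  After alignment,
a read from a newly made molecule therefore shows T>C mismatches in
transcript orientation (genomic T>C for plus-strand genes, genomic A>G for
minus-strand genes).  A read is called nascent when, among its
quality-filtered mismatches that survive SNP masking, the fraction of
conversion-consistent mismatches exceeds 30%; reads without eligible
mismatches are pre-existing.

Base-quality note: the default threshold keeps mismatches with Phred quality
strictly above 45.  Several platforms cap reported qualities at 40-41, in
which case the threshold must be lowered in the configuration or every
mismatch (including real conversions) is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam


@dataclass
class Mismatch:
    ref_pos: int  # 0-based reference coordinate
    ref_base: str
    read_base: str
    base_quality: int
    cigar_op: str = "M"


@dataclass
class ReadAlignment:
    """One aligned read with barcode/UMI metadata and its mismatch list."""

    read_id: str
    cell_barcode: str
    umi: str
    contig: str
    start: int  # 0-based leftmost reference position
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    mapq: int
    mismatches: list[Mismatch] = field(default_factory=list)

    @property
    def five_prime(self) -> int:
        """5' alignment coordinate used for UMI deduplication."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class NascentCall:
    read_id: str
    label: str  # "nascent" | "preexisting"
    n_tc: int
    n_mismatch: int


@dataclass
class SnpBackground:
    """Genomic positions masked as background variation, not conversions."""

    masked_sites: dict[tuple[str, int], tuple[str, str]] = field(
        default_factory=dict
    )

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.masked_sites

    def __len__(self) -> int:
        return len(self.masked_sites)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (contig, pos), (ref, alt) in sorted(self.masked_sites.items()):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{ref}>{alt}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "SnpBackground":
        sites: dict[tuple[str, int], tuple[str, str]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                contig, start = fields[0], int(fields[1])
                ref, alt = "N", "N"
                if len(fields) > 3 and ">" in fields[3]:
                    ref, alt = fields[3].split(">", 1)
                sites[(contig, start)] = (ref, alt)
        return cls(sites)


def _parse_read_name(name: str) -> tuple[str, str]:
    """Extract (cell_barcode, umi) from a ``cb|umi|serial`` read name."""
    parts = name.split("|")
    if len(parts) >= 2:
        return parts[0], parts[1]
    return "", ""


def read_alignments(
    path: str | Path,
    mapq_min: int = 30,
    contig: Optional[str] = None,
) -> Iterator[ReadAlignment]:
    """Stream alignments from SAM/BAM with mismatches taken from the MD tag.

    Cell barcode and UMI come from ``CB``/``UB`` tags when present, else from
    a ``cb|umi|serial`` read name.  Unmapped, secondary and supplementary
    records and reads below ``mapq_min`` are skipped.  Only aligned (CIGAR M)
    columns yield mismatch entries.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        records = fh.fetch(contig) if contig else fh
        for rec in records:
            aln = _to_read_alignment(rec, mapq_min)
            if aln is not None:
                yield aln


def _to_read_alignment(
    rec: pysam.AlignedSegment, mapq_min: int
) -> Optional[ReadAlignment]:
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return None
    if rec.mapping_quality < mapq_min:
        return None
    if rec.has_tag("CB") and rec.has_tag("UB"):
        cb, umi = str(rec.get_tag("CB")), str(rec.get_tag("UB"))
    else:
        cb, umi = _parse_read_name(rec.query_name or "")
    quals = rec.query_qualities
    seq = rec.query_sequence or ""
    mismatches: list[Mismatch] = []
    # with_seq requires an MD tag; lowercase reference base marks a mismatch
    for qpos, rpos, ref_base in rec.get_aligned_pairs(
        matches_only=True, with_seq=True
    ):
        if ref_base is None or not ref_base.islower():
            continue
        mismatches.append(
            Mismatch(
                ref_pos=int(rpos),
                ref_base=ref_base.upper(),
                read_base=seq[qpos].upper(),
                base_quality=int(quals[qpos]) if quals is not None else 0,
                cigar_op="M",
            )
        )
    return ReadAlignment(
        read_id=rec.query_name or "",
        cell_barcode=cb,
        umi=umi,
        contig=rec.reference_name or "",
        start=int(rec.reference_start),
        end=int(rec.reference_end),
        strand="-" if rec.is_reverse else "+",
        mapq=int(rec.mapping_quality),
        mismatches=mismatches,
    )


def build_snp_background(
    control_alignments: Iterable[ReadAlignment],
    min_coverage: int = 10,
    min_alt_fraction: float = 0.5,
) -> SnpBackground:
    """Identify background SNPs from an unlabeled control sample.

    A site is masked when its coverage reaches ``min_coverage`` and a single
    alternate base accounts for at least ``min_alt_fraction`` of the covering
    reads.  With no control reads the background is empty (nothing masked).
    """
    coverage: dict[tuple[str, int], int] = {}
    alt_counts: dict[tuple[str, int, str, str], int] = {}
    n_reads = 0
    for aln in control_alignments:
        n_reads += 1
        for pos in range(aln.start, aln.end):
            key = (aln.contig, pos)
            coverage[key] = coverage.get(key, 0) + 1
        for mm in aln.mismatches:
            key4 = (aln.contig, mm.ref_pos, mm.ref_base, mm.read_base)
            alt_counts[key4] = alt_counts.get(key4, 0) + 1
    if n_reads == 0:
        import warnings

        warnings.warn("empty control stream: SNP background is empty")
    masked: dict[tuple[str, int], tuple[str, str]] = {}
    for (contig, pos, ref, alt), n_alt in alt_counts.items():
        cov = coverage.get((contig, pos), 0)
        if cov >= min_coverage and n_alt / cov >= min_alt_fraction:
            masked[(contig, pos)] = (ref, alt)
    return SnpBackground(masked)


def classify_read(
    read: ReadAlignment,
    background: SnpBackground,
    gene_strand: str,
    min_base_quality: int = 45,
    min_tc_fraction: float = 0.30,
) -> NascentCall:
    """Label one read nascent/pre-existing from its filtered mismatches.

    Eligible mismatches are aligned (CIGAR M) columns with base quality
    strictly above ``min_base_quality`` whose site is not SNP-masked.  A
    conversion is an eligible mismatch reading T>C in transcript orientation.
    The read is nascent iff eligible mismatches exist and the conversion
    fraction strictly exceeds ``min_tc_fraction`` (zero eligible mismatches
    is treated as fraction 0, i.e. pre-existing).
    """
    if gene_strand == "+":
        conv = ("T", "C")
    else:
        conv = ("A", "G")
    n_elig = 0
    n_tc = 0
    for mm in read.mismatches:
        if mm.cigar_op != "M":
            continue
        if mm.base_quality <= min_base_quality:
            continue
        if (read.contig, mm.ref_pos) in background:
            continue
        n_elig += 1
        if mm.ref_base == conv[0] and mm.read_base == conv[1]:
            n_tc += 1
    nascent = n_elig > 0 and n_tc / n_elig > min_tc_fraction
    return NascentCall(
        read_id=read.read_id,
        label="nascent" if nascent else "preexisting",
        n_tc=n_tc,
        n_mismatch=n_elig,
    )


def call_nascent(
    alignments: Iterable[ReadAlignment],
    background: SnpBackground,
    gene_index=None,
    min_base_quality: int = 45,
    min_tc_fraction: float = 0.30,
) -> pd.DataFrame:
    """Label a deduplicated read stream; one row per read.

    ``gene_index`` (see :mod:`slamscreen.matrices`) supplies the transcript
    strand and gene assignment; reads overlapping no unique gene fall back to
    their alignment strand and are flagged ``strand_fallback``.
    """
    rows = []
    for aln in alignments:
        gene_id, exonic = (None, False)
        if gene_index is not None:
            gene_id, exonic = gene_index.assign(aln)
        if gene_id is not None:
            strand = gene_index.strand_of(gene_id)
            fallback = False
        else:
            strand = aln.strand
            fallback = True
        call = classify_read(
            aln,
            background,
            strand,
            min_base_quality=min_base_quality,
            min_tc_fraction=min_tc_fraction,
        )
        rows.append(
            {
                "read_id": aln.read_id,
                "cell_barcode": aln.cell_barcode,
                "umi": aln.umi,
                "contig": aln.contig,
                "start": aln.start,
                "strand": aln.strand,
                "gene_id": gene_id,
                "exonic": exonic,
                "label": call.label,
                "n_tc": call.n_tc,
                "n_mismatch": call.n_mismatch,
                "strand_fallback": fallback,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "cell_barcode",
            "umi",
            "contig",
            "start",
            "strand",
            "gene_id",
            "exonic",
            "label",
            "n_tc",
            "n_mismatch",
            "strand_fallback",
        ],
    )
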