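"""Gene models, breakpoints, and fusion-transcript construction.

Genes are represented as ordered exon chains (single canonical transcript
per gene). A chromosomal translocation is described by two breakpoints, one
in each partner gene; mapping a breakpoint onto the exon chain yields the
set of exons retained on the derivative allele. For a 5' partner the fusion
retains a contiguous prefix of exons (promoter side); for a 3' partner a
contiguous suffix. This reproduces the exon architectures of the PAX
fusions seen in fusion-positive rhabdomyosarcoma, e.g. PAX3 exons 1-7
joined to FOXO1 exons 2-3.

Coordinates are 0-based, half-open throughout. GTF input (1-based,
inclusive) is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gffutils

Strand = Literal["+", "-"]

FIVE_PRIME = "five_prime_partner"
THREE_PRIME = "three_prime_partner"


class GeneModelError(ValueError):
    """Invalid gene structure or breakpoint."""


class ExonicBreakpointError(GeneModelError):
    """Breakpoint falls inside an exon and no override was given."""


class GtfParseError(ValueError):
    """Malformed GTF record; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GeneModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene as an ordered exon chain.

    ``exons`` are stored in transcription order: exon 1 first. For a
    reverse-strand gene exon 1 therefore sits at the highest genomic
    coordinates.
    """

    gene_id: str
    strand: Strand
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError(f"gene {self.gene_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise GeneModelError(f"gene {self.gene_id} spans chromosomes {chroms}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise GeneModelError(f"gene {self.gene_id} has overlapping exons")
            genomic_ok = a.end <= b.start if self.strand == "+" else b.end <= a.start
            if not genomic_ok:
                raise GeneModelError(
                    f"gene {self.gene_id}: exon order inconsistent with strand"
                )

    @classmethod
    def from_intervals(
        cls, gene_id: str, strand: Strand, intervals: Iterable[GenomicInterval]
    ) -> "GeneModel":
        """Build from unordered genomic intervals, sorting into transcription order."""
        ivs = sorted(intervals, key=lambda e: e.start, reverse=(strand == "-"))
        return cls(gene_id=gene_id, strand=strand, exons=ivs)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def exon(self, index: int) -> GenomicInterval:
        """1-based exon lookup in transcription order."""
        if not 1 <= index <= self.n_exons:
            raise GeneModelError(f"exon index {index} out of range for {self.gene_id}")
        return self.exons[index - 1]


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    position: int
    gene_id: str
    role: str  # FIVE_PRIME or THREE_PRIME

    def __post_init__(self) -> None:
        if self.role not in (FIVE_PRIME, THREE_PRIME):
            raise GeneModelError(f"unknown breakpoint role {self.role!r}")


@dataclass(frozen=True)
class FusionTranscript:
    """Exon architecture of a fusion transcript.

    ``retained_5p_exons`` is always a contiguous prefix 1..k of the 5'
    gene's exons and ``retained_3p_exons`` a contiguous suffix m..N of the
    3' gene's exons (1-based transcription-order indices).
    """

    five_prime_gene: str
    retained_5p_exons: tuple[int, ...]
    three_prime_gene: str
    retained_3p_exons: tuple[int, ...]

    def __post_init__(self) -> None:
        r5 = self.retained_5p_exons
        if list(r5) != list(range(1, len(r5) + 1)):
            raise GeneModelError("retained 5' exons must be a prefix 1..k")
        r3 = self.retained_3p_exons
        if r3 and list(r3) != list(range(r3[0], r3[0] + len(r3))):
            raise GeneModelError("retained 3' exons must be contiguous")

    @property
    def n_exons(self) -> int:
        return len(self.retained_5p_exons) + len(self.retained_3p_exons)

    @property
    def name(self) -> str:
        return f"{self.five_prime_gene}-{self.three_prime_gene}"


def _validate_gtf_lines(path: Path) -> None:
    """Cheap structural pre-check so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise GtfParseError(f"line {lineno}: end < start ({end} < {start})")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"line {lineno}: bad strand {fields[6]!r}")


def load_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read exon records from a GTF/GFF file into GeneModels.

    1-based inclusive GTF coordinates are converted to the internal 0-based
    half-open convention. Exons are grouped by ``gene_id`` and ordered in
    transcription order.
    """
    path = Path(path)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise GtfParseError(f"exon at {feat.seqid}:{feat.start} lacks gene_id")
        gid = gene_ids[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        by_gene.setdefault(gid, []).append(iv)
        strands[gid] = feat.strand
    if not by_gene:
        raise GtfParseError(f"{path}: no exon features found")
    return {
        gid: GeneModel.from_intervals(gid, strands[gid], ivs)
        for gid, ivs in by_gene.items()
    }


def map_breakpoint_to_exons(
    gene: GeneModel, bp: Breakpoint, allow_exonic: bool = False
) -> tuple[list[int], list[int]]:
    """Classify exons as retained or lost by the fusion breakpoint.

    Returns 1-based exon indices ``(retained, lost)`` in transcription
    order. For a 5' partner, retained exons are those transcriptionally
    upstream of the breakpoint; for a 3' partner, downstream. A breakpoint
    inside an exon is an error unless ``allow_exonic`` is set, in which
    case the containing (truncated) exon counts as retained.
    """
    if bp.gene_id != gene.gene_id:
        raise GeneModelError(
            f"breakpoint gene {bp.gene_id} does not match model {gene.gene_id}"
        )
    if bp.chrom != gene.chrom:
        raise GeneModelError(
            f"breakpoint chromosome {bp.chrom} does not match gene on {gene.chrom}"
        )
    containing = [i for i in range(1, gene.n_exons + 1) if gene.exon(i).contains(bp.position)]
    if containing and not allow_exonic:
        raise ExonicBreakpointError(
            f"exonic breakpoint: position {bp.position} inside exon "
            f"{containing[0]} of {gene.gene_id} (pass allow_exonic to truncate)"
        )

    def upstream(i: int) -> bool:
        # Transcriptionally upstream of the break (exonic breaks handled above).
        e = gene.exon(i)
        if e.contains(bp.position):
            return True  # truncated exon kept on whichever side retains it
        if gene.strand == "+":
            return e.end <= bp.position
        return e.start >= bp.position

    if bp.role == FIVE_PRIME:
        retained = [i for i in range(1, gene.n_exons + 1) if upstream(i)]
    else:
        retained = [i for i in range(1, gene.n_exons + 1) if not upstream(i)]
        if containing:  # truncated exon belongs to the retained 3' suffix
            retained = sorted(set(retained) | {containing[0]})
    lost = [i for i in range(1, gene.n_exons + 1) if i not in retained]
    return retained, lost


def build_fusion_transcript(
    five_prime: tuple[GeneModel, Breakpoint],
    three_prime: tuple[GeneModel, Breakpoint],
    allow_exonic: bool = False,
) -> FusionTranscript:
    """Join the retained 5' prefix and 3' suffix into a fusion transcript."""
    gene5, bp5 = five_prime
    gene3, bp3 = three_prime
    if bp5.role != FIVE_PRIME or bp3.role != THREE_PRIME:
        raise GeneModelError("breakpoint roles must be five_prime/three_prime partners")
    ret5, _ = map_breakpoint_to_exons(gene5, bp5, allow_exonic=allow_exonic)
    ret3, _ = map_breakpoint_to_exons(gene3, bp3, allow_exonic=allow_exonic)
    if not ret5:
        warnings.warn(
            f"promoterless fusion: no 5' exons of {gene5.gene_id} retained",
            stacklevel=2,
        )
    return FusionTranscript(
        five_prime_gene=gene5.gene_id,
        retained_5p_exons=tuple(ret5),
        three_prime_gene=gene3.gene_id,
        retained_3p_exons=tuple(ret3),
    )


def fusion_report(
    fusion: FusionTranscript,
    genes: dict[str, GeneModel],
) -> "list[dict]":
    """Per-exon retained/lost table for a fusion, ready for TSV export."""
    rows = []
    for gid, retained in (
        (fusion.five_prime_gene, set(fusion.retained_5p_exons)),
        (fusion.three_prime_gene, set(fusion.retained_3p_exons)),
    ):
        gene = genes[gid]
        for i in range(1, gene.n_exons + 1):
            e = gene.exon(i)
            rows.append(
                {
                    "gene_id": gid,
                    "exon_index": i,
                    "retained": i in retained,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "strand": e.strand,
                }
            )
    return rows
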