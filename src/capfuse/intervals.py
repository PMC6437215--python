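"""Genomic interval model, capture-panel index, and annotation handling.

All coordinates are 0-based half-open internally.  BED input is taken as-is;
GTF (1-based inclusive) is converted on read and back on write.  Chromosome
names are used verbatim — no "chr" normalisation — unless an alias map is
supplied explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )


def overlaps(
    a: GenomicInterval,
    b: GenomicInterval,
    min_fraction_of_b: float = 0.0,
    stranded: bool = False,
) -> bool:
    """True iff ``a`` overlaps ``b`` by >= 1 bp and >= min_fraction_of_b * len(b).

    ``min_fraction_of_b=1.0`` requires full containment of ``b``;
    ``min_fraction_of_b=0.0`` degenerates to "any overlap of >= 1 bp".
    With ``stranded`` the strands must match exactly.
    """
    if not 0.0 <= min_fraction_of_b <= 1.0:
        raise ValueError("min_fraction_of_b must be in [0, 1]")
    if stranded and a.strand != b.strand:
        return False
    ov = a.overlap_length(b)
    return ov >= 1 and ov >= min_fraction_of_b * len(b)


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each an ordered exon list.

    Exons within a transcript are sorted by start, non-overlapping, and share
    the gene's chromosome and strand.
    """

    gene_id: str
    gene_name: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def chrom(self) -> str:
        for exons in self.transcripts.values():
            if exons:
                return exons[0].chrom
        raise ValueError(f"gene {self.gene_id} has no exons")

    def span(self) -> GenomicInterval:
        starts = [e.start for exs in self.transcripts.values() for e in exs]
        ends = [e.end for exs in self.transcripts.values() for e in exs]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def validate(self) -> None:
        for tid, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tid} has no exons")
            for prev, cur in zip(exons, exons[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"transcript {tid}: exons overlap or unsorted at "
                        f"{cur.chrom}:{cur.start}"
                    )
            chroms = {e.chrom for e in exons}
            if len(chroms) != 1:
                raise ValueError(f"transcript {tid} spans chromosomes {chroms}")

    def main_transcript(self) -> str:
        """Longest transcript by summed exonic length; ties -> lowest id."""
        return min(
            self.transcripts,
            key=lambda t: (-sum(len(e) for e in self.transcripts[t]), t),
        )


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, per transcript, deduplicated.

    Introns carry the gene strand.  Single-exon transcripts contribute none.
    Order is deterministic (by coordinate).
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[GenomicInterval] = []
    for exons in gene.transcripts.values():
        for left, right in zip(exons, exons[1:]):
            key = (left.chrom, left.end, right.start, gene.strand)
            if key not in seen:
                seen.add(key)
                out.append(
                    GenomicInterval(left.chrom, left.end, right.start, gene.strand)
                )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


class CapturePanel:
    """A capture panel: named interval set with an interval index and gene map."""

    def __init__(
        self,
        name: str,
        intervals: Sequence[GenomicInterval],
        gene_ids: Sequence[str] | None = None,
    ) -> None:
        self.name = name
        if gene_ids is None:
            gene_ids = [""] * len(intervals)
        if len(gene_ids) != len(intervals):
            raise ValueError("gene_ids must parallel intervals")
        order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
        self.intervals: list[GenomicInterval] = [intervals[i] for i in order]
        self._gene_ids: list[str] = [gene_ids[i] for i in order]
        self.gene_index: dict[str, list[GenomicInterval]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for iv, gid in zip(self.intervals, self._gene_ids):
            if gid:
                self.gene_index.setdefault(gid, []).append(iv)
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, gid
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, iv: GenomicInterval) -> bool:
        """Strand-agnostic: capture probes hybridise to either orientation."""
        tree = self._trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start, iv.end))

    def genes_hit(self, iv: GenomicInterval) -> set[str]:
        """Gene ids whose panel intervals overlap ``iv`` by >= 1 bp."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end) if hit.data}


def genes_hit(panel: CapturePanel, iv: GenomicInterval) -> set[str]:
    return panel.genes_hit(iv)


# ---------------------------------------------------------------------------
# BED / GTF / FASTA I/O
# ---------------------------------------------------------------------------


def read_panel_bed(path: str, name: str = "panel") -> CapturePanel:
    """Read a BED3/BED6 file into a CapturePanel.

    BED is already 0-based half-open, so coordinates pass through unchanged.
    Malformed lines raise with the 1-based line number; an empty file yields
    an empty panel with a warning.
    """
    intervals: list[GenomicInterval] = []
    gene_ids: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {s!r}/{e!r}"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
            gene_ids.append(fields[3] if len(fields) >= 4 else "")
    if not intervals:
        logger.warning("panel BED %s is empty", path)
    return CapturePanel(name, intervals, gene_ids)


def write_panel_bed(panel: CapturePanel, path: str) -> None:
    with open(path, "w") as fh:
        for iv, gid in zip(panel.intervals, panel._gene_ids):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}\t0\t{iv.strand}\n")


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Read exon features of a GTF2.2 file into GeneModel objects.

    ``gene_id`` and ``transcript_id`` attributes are required.  GTF 1-based
    inclusive coordinates become 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [None])[0]
        tid = feat.attributes.get("transcript_id", [None])[0]
        if gid is None or tid is None:
            raise ValueError(
                f"{path}: exon at {feat.seqid}:{feat.start} lacks "
                "gene_id/transcript_id"
            )
        gname = feat.attributes.get("gene_name", [gid])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        gene = genes.setdefault(gid, GeneModel(gid, gname, feat.strand))
        gene.transcripts.setdefault(tid, []).append(iv)
    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort(key=lambda e: e.start)
        gene.validate()
    return genes


def write_gtf(genes: Mapping[str, GeneModel], path: str, source: str = "capfuse") -> None:
    """Write exon features; converts back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gid in sorted(genes):
            gene = genes[gid]
            for tid in sorted(gene.transcripts):
                for exon in gene.transcripts[tid]:
                    attrs = (
                        f'gene_id "{gid}"; transcript_id "{tid}"; '
                        f'gene_name "{gene.gene_name}";'
                    )
                    fh.write(
                        f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t"
                        f"{exon.end}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


def read_fasta(path: str) -> dict[str, str]:
    """Load a genome FASTA into memory (small references only)."""
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(path).items()}
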