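"""Novel-exon discovery from assembled transcripts.

Exons of assembled multi-exon transcripts are compared against a reference
exon annotation: an exon is novel when it has no genomic overlap with any
reference exon (any-overlap exclusion, strand-agnostic).  Novel exons are
classified by position within their transcript (5', internal, 3'), internal
exons by reading-frame impact (length mod 3), and candidate acceptors are
profiled for polypyrimidine tracts and the canonical AG 3' splice-site
motif as evidence of genuine splicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class AssembledTranscript:
    """A multi-exon assembled transcript; exons sorted genomically."""

    transcript_id: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError("analysis is limited to multi-exon transcripts")
        self.exons = sorted(self.exons, key=lambda e: e.start)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class ExonClassification:
    transcript_id: str
    exon: GenomicInterval
    novel: bool
    position_class: str  # five_prime | internal | three_prime
    frame_modifying: bool | None  # None for terminal exons (not applicable)
    strand: str


def classify_position(exon: GenomicInterval, transcript: AssembledTranscript) -> str:
    """5'/internal/3' position of an exon within its transcript.

    The first exon in transcript orientation (leftmost on +, rightmost
    on -) is five_prime; the last is three_prime; the rest internal.
    """
    try:
        idx = transcript.exons.index(exon)
    except ValueError as exc:
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} not in transcript "
            f"{transcript.transcript_id}"
        ) from exc
    first, last = 0, len(transcript.exons) - 1
    if transcript.strand == "-":
        first, last = last, first
    if idx == first:
        return "five_prime"
    if idx == last:
        return "three_prime"
    return "internal"


def frame_impact(exon: GenomicInterval, position_class: str = "internal") -> bool:
    """True when an internal exon's length would shift the reading frame."""
    if position_class != "internal":
        raise ValueError("frame impact is defined for internal exons only")
    return len(exon) % 3 != 0


def find_novel_exons(
    assembled: Sequence[AssembledTranscript],
    reference_exons: Sequence[GenomicInterval],
    panel_gene_spans: Sequence[GenomicInterval],
) -> list[ExonClassification]:
    """Classify exons of assembled transcripts against the reference.

    Only transcripts overlapping a targeted gene's span (>= 1 bp) are
    considered.  An exon is novel iff it overlaps zero reference exons by
    even 1 bp, strand-agnostic.  Every exon of a considered transcript is
    returned, novel or not, with its position class; frame impact is
    reported for internal exons only.
    """
    if not reference_exons:
        raise ValueError("reference exon set is empty")
    ref_trees: dict[str, IntervalTree] = {}
    for ex in reference_exons:
        ref_trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end)
    panel_trees: dict[str, IntervalTree] = {}
    for iv in panel_gene_spans:
        panel_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    out: list[ExonClassification] = []
    for tx in assembled:
        span = tx.span()
        ptree = panel_trees.get(span.chrom)
        if not (ptree and ptree.overlap(span.start, span.end)):
            continue
        for exon in tx.exons:
            rtree = ref_trees.get(exon.chrom)
            novel = not (rtree and rtree.overlap(exon.start, exon.end))
            pos = classify_position(exon, tx)
            out.append(
                ExonClassification(
                    transcript_id=tx.transcript_id,
                    exon=exon,
                    novel=novel,
                    position_class=pos,
                    frame_modifying=frame_impact(exon) if pos == "internal" else None,
                    strand=tx.strand,
                )
            )
    return out


def acceptor_profile(
    exons: Sequence[ExonClassification] | Sequence[GenomicInterval],
    genome: Mapping[str, str],
    window: tuple[int, int] = (-20, 3),
    tract: tuple[int, int] = (-20, -5),
) -> tuple[np.ndarray, float, list[str]]:
    """Position-specific nucleotide probabilities around 3' splice acceptors.

    For each exon the strand-corrected window covering intron positions
    ``window[0]..-1`` and exon positions ``+1..window[1]`` is extracted
    (minus-strand windows are reverse-complemented).  First (5') exons have
    no acceptor and are skipped when position classes are available.

    Returns (4 x width probability matrix over A/C/G/T, mean pyrimidine
    fraction over the tract positions, list of extracted window strings).
    """
    lo, hi = window
    if lo >= 0 or hi < 0:
        raise ValueError("window must span the acceptor (lo < 0 <= hi)")
    width = -lo + hi
    windows: list[str] = []
    for item in exons:
        if isinstance(item, ExonClassification):
            if item.position_class == "five_prime":
                continue
            exon, strand = item.exon, item.strand
        else:
            exon, strand = item, item.strand
        seq = genome[exon.chrom]
        if strand == "-":
            g_lo, g_hi = exon.end - hi, exon.end - lo
            if g_lo < 0 or g_hi > len(seq):
                raise ValueError("sequence shorter than acceptor window")
            win = seq[g_lo:g_hi].translate(_COMPLEMENT)[::-1]
        else:
            g_lo, g_hi = exon.start + lo, exon.start + hi
            if g_lo < 0 or g_hi > len(seq):
                raise ValueError("sequence shorter than acceptor window")
            win = seq[g_lo:g_hi]
        windows.append(win.upper())
    if not windows:
        raise ValueError("no exons with an acceptor to profile")

    counts = np.zeros((4, width))
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for win in windows:
        for j, base in enumerate(win):
            if base in index:
                counts[index[base], j] += 1
    matrix = counts / counts.sum(axis=0, keepdims=True)
    t0, t1 = tract[0] - lo, tract[1] - lo + 1
    pyrimidine_fraction = float(matrix[[1, 3], t0:t1].sum(axis=0).mean())
    return matrix, pyrimidine_fraction, windows


def size_quantiles(
    exons: Sequence[GenomicInterval], q: Sequence[float] = (0.25, 0.5, 0.75)
) -> dict[float, float]:
    """Summary quantiles of exon sizes (novel vs annotated comparisons)."""
    sizes = np.array([len(e) for e in exons], dtype=float)
    return {float(p): float(np.quantile(sizes, p)) for p in q}


def read_assembled_gtf(path: str) -> list[AssembledTranscript]:
    """StringTie-style assembled GTF -> multi-exon transcripts only."""
    from .intervals import read_gtf

    genes = read_gtf(path)
    out = []
    for gid in sorted(genes):
        gene = genes[gid]
        for tid in sorted(gene.transcripts):
            exons = gene.transcripts[tid]
            if len(exons) >= 2:
                out.append(AssembledTranscript(tid, gene.strand, list(exons)))
    return out
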