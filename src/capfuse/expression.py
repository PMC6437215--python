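"""Exon-level and gene-level expression analysis.

Read-start densities per exon of a gene's main transcript, TPM
normalisation, junction changepoint detection (an abrupt in-gene coverage
step marks a fusion junction), and cohort expression-outlier flagging (a
promoter fusion deregulates a gene without producing a chimeric junction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval


@dataclass
class ExonCoverage:
    """Read 5'-end count and per-nt density for one exon (transcript order)."""

    gene_id: str
    exon_index: int
    interval: GenomicInterval
    read5p_count: int

    @property
    def density(self) -> float:
        return self.read5p_count / len(self.interval)


@dataclass
class ExpressionRecord:
    gene_id: str
    count: float
    effective_length: int
    tpm: float


def exon_density(
    read_starts: Sequence[tuple[str, int]] | Sequence[int],
    gene: GeneModel,
    main_transcript: str | None = None,
) -> list[ExonCoverage]:
    """Assign read 5' ends to exons of the main transcript and compute density.

    ``read_starts`` are (chrom, position) tuples, or bare positions taken to
    be on the gene's chromosome.  A start is assigned to at most one exon by
    half-open containment; a start at an exon's end coordinate is outside
    it.  Exon order is transcript 5'->3'.
    """
    tid = main_transcript or gene.main_transcript()
    exons = gene.transcripts[tid]
    chrom = gene.chrom
    counts = [0] * len(exons)
    for rs in read_starts:
        c, pos = rs if isinstance(rs, tuple) else (chrom, rs)
        if c != chrom:
            continue
        for i, exon in enumerate(exons):
            if exon.start <= pos < exon.end:
                counts[i] += 1
                break
    order = range(len(exons)) if gene.strand != "-" else range(len(exons) - 1, -1, -1)
    return [
        ExonCoverage(gene.gene_id, k, exons[i], counts[i])
        for k, i in enumerate(order)
    ]


def counts_to_tpm(records: Sequence[tuple[str, float, int]]) -> list[ExpressionRecord]:
    """Transcripts-per-million from (gene, count, effective length) triples.

    rate_g = count_g / length_g; TPM_g = rate_g / sum(rate) * 1e6, so the
    library's TPM values sum to one million.
    """
    if any(length <= 0 for _, _, length in records):
        raise ValueError("effective lengths must be > 0")
    rates = np.array([count / length for _, count, length in records], dtype=float)
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    tpms = rates / total * 1e6
    return [
        ExpressionRecord(gene, count, length, float(t))
        for (gene, count, length), t in zip(records, tpms)
    ]


def detect_changepoint(
    coverage: Sequence[ExonCoverage],
    min_fold: float = 3.0,
    pseudocount: float = 0.5,
) -> tuple[int, float, bool]:
    """Locate the exon boundary with the largest density step.

    Every internal boundary b (1..n-1) is scored exhaustively as
    |log2(mean density of exons < b / mean density of exons >= b)| with a
    pseudocount of ``pseudocount`` reads per exon stabilising empty
    segments.  Returns (argmax boundary, linear fold change across it, flag
    set when fold or its inverse >= ``min_fold``).  Ties break to the lowest
    boundary.  The fold is the raw left/right density ratio (infinite when
    the right segment is empty).
    """
    n = len(coverage)
    if n < 2:
        raise ValueError("changepoint detection needs >= 2 exons")
    dens = np.array([c.density for c in coverage], dtype=float)
    smoothed = np.array(
        [(c.read5p_count + pseudocount) / len(c.interval) for c in coverage]
    )
    best_b, best_score = 1, -1.0
    for b in range(1, n):
        score = abs(math.log2(smoothed[:b].mean() / smoothed[b:].mean()))
        if score > best_score + 1e-12:
            best_score, best_b = score, b
    left, right = dens[:best_b].mean(), dens[best_b:].mean()
    fold = float("inf") if right == 0 else left / right
    flagged = fold >= min_fold or (fold > 0 and 1.0 / fold >= min_fold)
    return best_b, fold, flagged


def cohort_outlier(
    expr: Mapping[str, float], fold_threshold: float = 10.0
) -> dict[str, tuple[bool, float]]:
    """Flag samples whose TPM is >= fold_threshold x the cohort median.

    For each sample the median is taken over the other samples.  A zero
    median makes any positive expression an outlier with infinite fold.
    Returns sample -> (flag, fold over median).
    """
    samples = sorted(expr)
    if len(samples) < 3:
        raise ValueError("cohort outlier test needs >= 3 samples")
    out: dict[str, tuple[bool, float]] = {}
    for s in samples:
        others = np.array([expr[t] for t in samples if t != s], dtype=float)
        med = float(np.median(others))
        if med == 0:
            fold = float("inf") if expr[s] > 0 else 0.0
            out[s] = (expr[s] > 0, fold)
        else:
            fold = expr[s] / med
            out[s] = (fold >= fold_threshold, fold)
    return out


def coverage_from_counts(gene: GeneModel, counts: Sequence[int]) -> list[ExonCoverage]:
    """Wrap per-exon counts (transcript 5'->3' order) as ExonCoverage."""
    exons = list(gene.transcripts[gene.main_transcript()])
    if gene.strand == "-":
        exons = exons[::-1]
    if len(counts) != len(exons):
        raise ValueError("count vector does not match exon count")
    return [
        ExonCoverage(gene.gene_id, k, exon, int(c))
        for k, (exon, c) in enumerate(zip(exons, counts))
    ]
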