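"""Capture-panel validation metrics.

On-target rate from aligned read pairs, spike-in fold enrichment relative
to conventional RNA-seq, limit of detection from a dilution series,
splice-junction coverage of annotated introns, and replicate coefficient of
variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CapturePanel, GeneModel, GenomicInterval, derive_introns


@dataclass
class ReadPairRecord:
    """An aligned read pair with uniqueness flag and spliced-alignment gaps.

    ``mapping_unique`` mirrors the uniquely-mapping criterion (e.g. a
    maximal aligner mapping score); ``splice_gaps`` are the skipped regions
    implied by N operations in the alignment.
    """

    read1: GenomicInterval
    read2: GenomicInterval
    mapping_unique: bool = True
    splice_gaps: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if self.splice_gaps is None:
            self.splice_gaps = []


@dataclass
class SpikeInMeasurement:
    spike_id: str
    targeted: bool
    concentration: float  # pM
    abundance_capture: float
    abundance_rnaseq: float
    detected: bool

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.abundance_capture < 0 or self.abundance_rnaseq < 0:
            raise ValueError("abundances must be >= 0")


@dataclass
class DetectionCurve:
    """Aggregated detection fractions over a concentration ladder."""

    points: list[tuple[float, float, int]]  # (concentration pM, fraction, n)

    def __post_init__(self) -> None:
        self.points = sorted(self.points)
        concs = [p[0] for p in self.points]
        if len(set(concs)) != len(concs):
            raise ValueError("duplicate concentrations after aggregation")
        if any(not 0 <= p[1] <= 1 for p in self.points):
            raise ValueError("detected fractions must be in [0, 1]")

    @classmethod
    def from_measurements(cls, spikes: Sequence[SpikeInMeasurement]) -> "DetectionCurve":
        by_conc: dict[float, list[bool]] = {}
        for s in spikes:
            if s.targeted:
                by_conc.setdefault(s.concentration, []).append(s.detected)
        return cls([(c, float(np.mean(v)), len(v)) for c, v in sorted(by_conc.items())])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def on_target_rate(pairs: Sequence[ReadPairRecord], panel: CapturePanel) -> float:
    """Fraction of uniquely-mapped pairs with >= 1 mate overlapping the panel.

    A pair is on-target when read1 OR read2 overlaps any panel interval by
    at least 1 bp (strand-agnostic); the denominator is all uniquely-mapped
    pairs.
    """
    unique = [p for p in pairs if p.mapping_unique]
    if not unique:
        raise ValueError("no uniquely-mapped read pairs")
    n_on = sum(1 for p in unique if panel.overlaps(p.read1) or panel.overlaps(p.read2))
    return n_on / len(unique)


def spikein_enrichment(
    measurements: Sequence[SpikeInMeasurement], geometric: bool = False
) -> dict:
    """Per-spike capture/conventional fold change and targeted/non-targeted means.

    Folds are computed only for spikes with both abundances > 0; the rest
    are excluded from the means and reported separately (no pseudocounts —
    a zero denominator would fabricate a fold).  Means are arithmetic by
    default; ``geometric`` switches to the geometric mean.
    """
    folds: dict[str, float] = {}
    excluded: list[str] = []
    by_group: dict[bool, list[float]] = {True: [], False: []}
    for m in measurements:
        if m.abundance_capture > 0 and m.abundance_rnaseq > 0:
            f = m.abundance_capture / m.abundance_rnaseq
            folds[m.spike_id] = f
            by_group[m.targeted].append(f)
        else:
            excluded.append(m.spike_id)
    if not folds:
        raise ValueError("no spike has both abundances > 0")

    def _mean(values: list[float]) -> float:
        if not values:
            return float("nan")
        if geometric:
            return float(np.exp(np.mean(np.log(values))))
        return float(np.mean(values))

    return {
        "fold_per_spike": folds,
        "mean_fold_targeted": _mean(by_group[True]),
        "mean_fold_nontargeted": _mean(by_group[False]),
        "excluded_spikes": excluded,
    }


def detection_lod(curve: DetectionCurve, threshold: float = 0.5) -> float | str:
    """Limit of detection: the concentration reaching the threshold fraction.

    Finds the lowest adjacent ladder pair bracketing the threshold and
    interpolates linearly in log2 concentration (the ladder is a dilution
    series).  Returns 'below-range' if the lowest point already meets the
    threshold and 'above-range' if the threshold is never reached.
    """
    pts = curve.points
    if len(pts) < 2:
        raise ValueError("detection curve needs >= 2 points")
    if pts[0][1] >= threshold:
        return "below-range"
    for (c1, f1, _), (c2, f2, _) in zip(pts, pts[1:]):
        if f1 < threshold <= f2:
            x1, x2 = math.log2(c1), math.log2(c2)
            x = x1 + (threshold - f1) / (f2 - f1) * (x2 - x1)
            return float(2**x)
    return "above-range"


def intron_junction_coverage(
    pairs: Sequence[ReadPairRecord], genes: Mapping[str, GeneModel]
) -> float:
    """Fraction of annotated introns fully contained in some splice gap.

    An intron counts as covered only when a read's gap contains the entire
    intron on the matching strand (full-containment, stranded — the
    fraction-of-intron requirement is 1.0).  The denominator is the
    deduplicated intron set; intronless genes contribute nothing.
    """
    introns: list[GenomicInterval] = []
    seen: set[tuple] = set()
    for gid in sorted(genes):
        for iv in derive_introns(genes[gid]):
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key not in seen:
                seen.add(key)
                introns.append(iv)
    if not introns:
        raise ValueError("annotation has no introns")
    gaps_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in pairs:
        for gap in p.splice_gaps:
            gaps_by_chrom.setdefault(gap.chrom, []).append(gap)
    covered = 0
    for intron in introns:
        for gap in gaps_by_chrom.get(intron.chrom, ()):
            if gap.strand == intron.strand and gap.contains(intron):
                covered += 1
                break
    return covered / len(introns)


def replicate_cv(counts) -> tuple[np.ndarray, float]:
    """Per-feature coefficient of variation across replicates, and its mean.

    CV = sample standard deviation (n-1) / mean; zero-mean features are
    excluded from the mean (their CV is NaN).
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a feature x replicate matrix with >= 2 replicates")
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    finite = cvs[~np.isnan(cvs)]
    if finite.size == 0:
        raise ValueError("all features have zero mean")
    return cvs, float(finite.mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PAIR_TSV_COLUMNS = [
    "read1_chrom", "read1_start", "read1_end", "read1_strand",
    "read2_chrom", "read2_start", "read2_end", "read2_strand",
    "mapping_unique", "splice_gaps",
]


def read_pairs_tsv(path_or_frame) -> list[ReadPairRecord]:
    """Flat read-pair TSV; splice_gaps is ';'-joined 'chrom:start-end:strand'."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(
        path_or_frame, sep="\t"
    )
    missing = [c for c in PAIR_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns {missing}")
    pairs = []
    for _, row in df.iterrows():
        gaps = []
        gap_text = row["splice_gaps"]
        if isinstance(gap_text, str) and gap_text:
            for token in gap_text.split(";"):
                loc, strand = token.rsplit(":", 1)
                chrom, span = loc.split(":")
                s, e = span.split("-")
                gaps.append(GenomicInterval(chrom, int(s), int(e), strand))
        pairs.append(
            ReadPairRecord(
                read1=GenomicInterval(
                    row["read1_chrom"], int(row["read1_start"]), int(row["read1_end"]), row["read1_strand"]
                ),
                read2=GenomicInterval(
                    row["read2_chrom"], int(row["read2_start"]), int(row["read2_end"]), row["read2_strand"]
                ),
                mapping_unique=bool(row["mapping_unique"]),
                splice_gaps=gaps,
            )
        )
    return pairs


def read_pairs_sam(path: str, unique_mapq: int = 255) -> list[ReadPairRecord]:
    """Read pairs from SAM/BAM; uniqueness = MAPQ >= unique_mapq on both mates.

    Splice gaps come from N CIGAR operations; gap strand follows the mate's
    alignment strand.
    """
    import pysam

    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            by_name.setdefault(aln.query_name, []).append(aln)
    pairs = []
    for name in sorted(by_name):
        alns = by_name[name]
        if len(alns) != 2:
            continue
        r1, r2 = sorted(alns, key=lambda a: a.is_read2)
        ivs, gap_lists = [], []
        for aln in (r1, r2):
            strand = "-" if aln.is_reverse else "+"
            ivs.append(
                GenomicInterval(aln.reference_name, aln.reference_start, aln.reference_end, strand)
            )
            gaps = []
            pos = aln.reference_start
            for op, length in aln.cigartuples or ():
                if op == 3:  # N: skipped region
                    gaps.append(GenomicInterval(aln.reference_name, pos, pos + length, strand))
                if op in (0, 2, 3, 7, 8):  # consume reference
                    pos += length
            gap_lists.append(gaps)
        pairs.append(
            ReadPairRecord(
                read1=ivs[0],
                read2=ivs[1],
                mapping_unique=r1.mapping_quality >= unique_mapq
                and r2.mapping_quality >= unique_mapq,
                splice_gaps=gap_lists[0] + gap_lists[1],
            )
        )
    return pairs


def read_spikein_tsv(path_or_frame) -> list[SpikeInMeasurement]:
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(
        path_or_frame, sep="\t"
    )
    return [
        SpikeInMeasurement(
            spike_id=str(row["spike_id"]),
            targeted=bool(row["targeted"]),
            concentration=float(row["concentration_pM"]),
            abundance_capture=float(row["abundance_capture"]),
            abundance_rnaseq=float(row["abundance_rnaseq"]),
            detected=bool(row["detected"]),
        )
        for _, row in df.iterrows()
    ]
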