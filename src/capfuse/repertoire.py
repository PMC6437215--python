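"""Immune-repertoire summarisation from clonotype tables.

Downstream of clonotype calling: per-sample repertoire statistics
(clonotype counts, top-clone fraction), partition into immunoglobulin and
T-cell receptor classes, and cross-sample clonal-dominance flagging (a
clonal malignancy shows 1-3 dominant clonotypes carrying most immune
reads, far above the polyclonal background of other samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

IG_LOCI = frozenset({"IGH", "IGK", "IGL"})
TCR_LOCI = frozenset({"TRA", "TRB", "TRG", "TRD"})
ALL_LOCI = IG_LOCI | TCR_LOCI


@dataclass(frozen=True)
class ClonotypeRecord:
    sample_id: str
    locus: str
    cdr3: str
    reads: int

    def __post_init__(self) -> None:
        if self.locus not in ALL_LOCI:
            raise ValueError(
                f"unknown locus {self.locus!r} in clonotype "
                f"{self.sample_id}/{self.cdr3}"
            )
        if self.reads < 1:
            raise ValueError("clonotype reads must be >= 1")


@dataclass
class RepertoireSummary:
    sample_id: str
    n_clonotypes: int
    total_reads: int
    top_clone_fraction: float
    per_locus: dict[str, int]
    ig_clones: int
    tcr_clones: int
    dominance_flag: bool | None = None


def summarize_repertoire(records: Sequence[ClonotypeRecord]) -> RepertoireSummary:
    """Per-sample repertoire statistics; clonotype identity is (locus, CDR3)."""
    if not records:
        raise ValueError("no clonotype records")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    reads_by_clone: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.locus, r.cdr3)
        reads_by_clone[key] = reads_by_clone.get(key, 0) + r.reads
    total = sum(reads_by_clone.values())
    per_locus: dict[str, int] = {}
    for locus, _ in reads_by_clone:
        per_locus[locus] = per_locus.get(locus, 0) + 1
    ig, tcr = partition_ig_tcr(records)
    return RepertoireSummary(
        sample_id=next(iter(sample_ids)),
        n_clonotypes=len(reads_by_clone),
        total_reads=total,
        top_clone_fraction=max(reads_by_clone.values()) / total,
        per_locus=per_locus,
        ig_clones=ig,
        tcr_clones=tcr,
    )


def partition_ig_tcr(records: Sequence[ClonotypeRecord]) -> tuple[int, int]:
    """Distinct clonotype counts in the IG and TCR receptor classes."""
    ig_clones: set[tuple[str, str]] = set()
    tcr_clones: set[tuple[str, str]] = set()
    for r in records:
        (ig_clones if r.locus in IG_LOCI else tcr_clones).add((r.locus, r.cdr3))
    return len(ig_clones), len(tcr_clones)


def dominance_flag(
    summary: RepertoireSummary,
    cohort: Sequence[RepertoireSummary],
    fold: float = 10.0,
) -> bool:
    """Flag a sample whose top clone dominates relative to the cohort.

    The statistic is the within-sample normalised top-clone abundance
    (top_clone_fraction), comparable across libraries of different depth.
    The sample is flagged when its statistic is >= ``fold`` x the median of
    the other cohort samples.
    """
    others = [s.top_clone_fraction for s in cohort if s.sample_id != summary.sample_id]
    if len(others) < 2:
        raise ValueError("dominance flag needs a cohort of >= 3 samples")
    med = float(np.median(others))
    if med == 0:
        return summary.top_clone_fraction > 0
    return summary.top_clone_fraction >= fold * med


def read_clonotype_tsv(path_or_frame) -> list[ClonotypeRecord]:
    """Clonotype TSV with columns sample_id, locus, cdr3, reads.

    MiXCR-style exports (cloneCount / nSeqCDR3 and a locus or V-hit column)
    are mapped onto the same fields when present.
    """
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(
        path_or_frame, sep="\t"
    )
    cols = set(df.columns)
    if {"cloneCount", "nSeqCDR3"} <= cols:
        locus_col = "locus" if "locus" in cols else "allVHitsWithScore"
        df = pd.DataFrame(
            {
                "sample_id": df.get("sample_id", "S1"),
                "locus": df[locus_col].astype(str).str.extract(r"(IGH|IGK|IGL|TRA|TRB|TRG|TRD)")[0],
                "cdr3": df["nSeqCDR3"],
                "reads": df["cloneCount"].astype(int),
            }
        )
    return [
        ClonotypeRecord(
            sample_id=str(row["sample_id"]),
            locus=str(row["locus"]),
            cdr3=str(row["cdr3"]),
            reads=int(row["reads"]),
        )
        for _, row in df.iterrows()
    ]
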