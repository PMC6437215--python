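"""Consensus fusion calling from two callers' output tables.

Targeted RNA-seq fusion callers each report many candidates, most of them
software-specific false positives.  The diagnostic computation here applies
an ordered filter chain to each caller's list independently — capture-panel
overlap, blacklist, read support, intra-chromosomal distance — then
intersects the two lists on overlapping breakpoint coordinates to produce
high-confidence consensus calls, and finally rescues single-caller calls of
known fusions reported in the sample's tumour type.

Every filter only removes calls (never mutates them), logs each removal
with a reason code, and the audit trail conserves counts: input = output +
sum of removals.  Orientation matters throughout: the 5' partner is listed
first and A-B is distinct from B-A (reciprocal fusions are separate calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .intervals import CapturePanel, GenomicInterval

Breakpoint = tuple[str, int, str]  # (chrom, 0-based position, strand)


@dataclass(frozen=True)
class FusionCall:
    """One caller's reported fusion, 5' partner first."""

    caller: str
    sample_id: str
    gene5: str
    gene3: str
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    junction_reads: int
    spanning_reads: int

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("gene symbols must be non-empty")
        if self.junction_reads < 0 or self.spanning_reads < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def pair(self) -> tuple[str, str]:
        """Ordered gene pair, upper-cased for cross-caller symbol matching."""
        return (self.gene5.upper(), self.gene3.upper())

    @property
    def support(self) -> int:
        return self.junction_reads + self.spanning_reads


@dataclass(frozen=True)
class BlacklistEntry:
    gene5: str
    gene3: str
    caller_scope: str = "*"
    sample_type_scope: str = "*"

    def matches(self, call: FusionCall, sample_type: str) -> bool:
        return (
            (self.gene5.upper(), self.gene3.upper()) == call.pair
            and self.caller_scope in ("*", call.caller)
            and self.sample_type_scope in ("*", sample_type)
        )


@dataclass
class ConsensusFusion:
    """A consensus call surviving the filter chain.

    ``tier`` is 'high-confidence' (found by both callers with overlapping
    coordinates; representative breakpoints from caller A) or
    'single-caller-known' (rescued known fusion seen by one caller only).
    """

    gene5: str
    gene3: str
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    tier: str
    evidence: dict[str, dict] = field(default_factory=dict)
    filters_passed: list[str] = field(default_factory=list)


@dataclass
class FilterAudit:
    """Per-step removal log; conserves call counts."""

    steps: list[dict] = field(default_factory=list)
    removed: list[dict] = field(default_factory=list)

    def record(self, step: str, before: int, kept: int, removals: list[tuple[FusionCall, str]]):
        self.steps.append({"step": step, "in": before, "kept": kept, "removed": before - kept})
        for call, reason in removals:
            self.removed.append(
                {
                    "step": step,
                    "caller": call.caller,
                    "gene5": call.gene5,
                    "gene3": call.gene3,
                    "reason": reason,
                }
            )


# ---------------------------------------------------------------------------
# The filter chain
# ---------------------------------------------------------------------------


def _bp_interval(bp: Breakpoint) -> GenomicInterval:
    chrom, pos, strand = bp
    return GenomicInterval(chrom, pos, pos + 1, strand)


def filter_on_panel(
    calls: Sequence[FusionCall], panel: CapturePanel, audit: FilterAudit | None = None
) -> list[FusionCall]:
    """Keep calls where at least one partner's breakpoint overlaps the panel.

    Strand-agnostic, >= 1 bp.  One on-panel partner suffices: capture pulls
    down the chimeric transcript, so novel non-targeted partners are kept.
    """
    kept, removed = [], []
    for c in calls:
        if panel.overlaps(_bp_interval(c.breakpoint5)) or panel.overlaps(
            _bp_interval(c.breakpoint3)
        ):
            kept.append(c)
        else:
            removed.append((c, "neither partner on capture panel"))
    if audit is not None:
        audit.record("panel", len(calls), len(kept), removed)
    return kept


def apply_blacklist(
    calls: Sequence[FusionCall],
    blacklist: Sequence[BlacklistEntry],
    sample_type: str = "*",
    audit: FilterAudit | None = None,
) -> list[FusionCall]:
    """Remove calls whose ordered pair matches a compatible blacklist entry."""
    kept, removed = [], []
    for c in calls:
        hit = next((e for e in blacklist if e.matches(c, sample_type)), None)
        if hit is None:
            kept.append(c)
        else:
            removed.append((c, f"blacklisted ({hit.gene5}-{hit.gene3}, caller={hit.caller_scope}, type={hit.sample_type_scope})"))
    if audit is not None:
        audit.record("blacklist", len(calls), len(kept), removed)
    return kept


def filter_support(
    calls: Sequence[FusionCall], min_reads: int = 2, audit: FilterAudit | None = None
) -> list[FusionCall]:
    """Require junction + spanning reads >= min_reads (sum rule)."""
    kept, removed = [], []
    for c in calls:
        if c.support >= min_reads:
            kept.append(c)
        else:
            removed.append((c, f"support {c.support} < {min_reads}"))
    if audit is not None:
        audit.record("support", len(calls), len(kept), removed)
    return kept


def filter_distance(
    calls: Sequence[FusionCall], min_distance: int = 10000, audit: FilterAudit | None = None
) -> list[FusionCall]:
    """Intra-chromosomal junctions must be >= min_distance nt apart (inclusive).

    Inter-chromosomal calls always pass; the rule removes read-through and
    mis-mapping artifacts between neighbouring genes.
    """
    kept, removed = [], []
    for c in calls:
        c5, p5, _ = c.breakpoint5
        c3, p3, _ = c.breakpoint3
        if c5 != c3 or abs(p5 - p3) >= min_distance:
            kept.append(c)
        else:
            removed.append((c, f"intra-chromosomal distance {abs(p5 - p3)} < {min_distance}"))
    if audit is not None:
        audit.record("distance", len(calls), len(kept), removed)
    return kept


def build_blacklist(
    cohort_calls: Sequence[FusionCall], min_sample_fraction: float = 0.9
) -> list[BlacklistEntry]:
    """Derive a recurrent-artifact blacklist from a cohort of call tables.

    For each caller separately, gene pairs present in at least
    ``min_sample_fraction`` of that caller's samples are emitted as entries
    scoped to that caller (recurrent everywhere = artifact, not biology).
    """
    samples_by_caller: dict[str, set[str]] = {}
    pair_samples: dict[tuple[str, str, str], set[str]] = {}
    for c in cohort_calls:
        samples_by_caller.setdefault(c.caller, set()).add(c.sample_id)
        pair_samples.setdefault((c.caller, *c.pair), set()).add(c.sample_id)
    n_samples = {k: len(v) for k, v in samples_by_caller.items()}
    if not n_samples or max(n_samples.values()) < 2:
        raise ValueError("cohort blacklist needs >= 2 samples")
    entries = []
    for (caller, g5, g3), samples in sorted(pair_samples.items()):
        if len(samples) >= min_sample_fraction * n_samples[caller]:
            entries.append(BlacklistEntry(g5, g3, caller_scope=caller))
    return entries


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _bp_close(a: Breakpoint, b: Breakpoint, tol: int) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= tol


def intersect_callers(
    calls_a: Sequence[FusionCall],
    calls_b: Sequence[FusionCall],
    breakpoint_tolerance: int = 10,
) -> tuple[list[ConsensusFusion], list[FusionCall], list[FusionCall]]:
    """Match calls found by both callers with overlapping coordinates.

    Per ordered gene pair, caller-A and caller-B calls are matched greedily
    by nearest breakpoints (same chromosome on each side, both positions
    within the tolerance); each input call is used at most once.  Ties break
    on lower 5' then 3' coordinates for determinism.  Returns the
    high-confidence consensus list plus each caller's unmatched leftovers.
    """
    by_pair_a: dict[tuple[str, str], list[FusionCall]] = {}
    by_pair_b: dict[tuple[str, str], list[FusionCall]] = {}
    for c in calls_a:
        by_pair_a.setdefault(c.pair, []).append(c)
    for c in calls_b:
        by_pair_b.setdefault(c.pair, []).append(c)

    consensus: list[ConsensusFusion] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for pair in sorted(set(by_pair_a) & set(by_pair_b)):
        cands = []
        for a in by_pair_a[pair]:
            for b in by_pair_b[pair]:
                if _bp_close(a.breakpoint5, b.breakpoint5, breakpoint_tolerance) and _bp_close(
                    a.breakpoint3, b.breakpoint3, breakpoint_tolerance
                ):
                    dist = abs(a.breakpoint5[1] - b.breakpoint5[1]) + abs(
                        a.breakpoint3[1] - b.breakpoint3[1]
                    )
                    cands.append((dist, a.breakpoint5[1], a.breakpoint3[1], b.breakpoint5[1], b.breakpoint3[1], a, b))
        cands.sort(key=lambda t: t[:5])
        for _, _, _, _, _, a, b in cands:
            if id(a) in used_a or id(b) in used_b:
                continue
            used_a.add(id(a))
            used_b.add(id(b))
            consensus.append(
                ConsensusFusion(
                    gene5=a.gene5,
                    gene3=a.gene3,
                    breakpoint5=a.breakpoint5,
                    breakpoint3=a.breakpoint3,
                    tier="high-confidence",
                    evidence={
                        a.caller: {
                            "junction_reads": a.junction_reads,
                            "spanning_reads": a.spanning_reads,
                            "breakpoint5": a.breakpoint5,
                            "breakpoint3": a.breakpoint3,
                        },
                        b.caller: {
                            "junction_reads": b.junction_reads,
                            "spanning_reads": b.spanning_reads,
                            "breakpoint5": b.breakpoint5,
                            "breakpoint3": b.breakpoint3,
                        },
                    },
                    filters_passed=["panel", "blacklist", "support", "distance", "intersection"],
                )
            )
    unmatched_a = [c for c in calls_a if id(c) not in used_a]
    unmatched_b = [c for c in calls_b if id(c) not in used_b]
    return consensus, unmatched_a, unmatched_b


def rescue_known(
    unmatched_a: Sequence[FusionCall],
    unmatched_b: Sequence[FusionCall],
    known_fusions: Sequence[tuple[str, str, set[str]]],
    sample_type: str = "*",
) -> list[ConsensusFusion]:
    """Rescue single-caller calls of known fusions for this tumour type.

    ``known_fusions`` entries are (gene5, gene3, cancer types) where the
    type set may contain "*".  Rescued calls stay at tier
    'single-caller-known' — never promoted to high-confidence.
    """
    known = {
        (g5.upper(), g3.upper()): types for g5, g3, types in known_fusions
    }
    out: list[ConsensusFusion] = []
    for c in list(unmatched_a) + list(unmatched_b):
        types = known.get(c.pair)
        if types is None:
            continue
        if "*" not in types and sample_type not in types:
            continue
        out.append(
            ConsensusFusion(
                gene5=c.gene5,
                gene3=c.gene3,
                breakpoint5=c.breakpoint5,
                breakpoint3=c.breakpoint3,
                tier="single-caller-known",
                evidence={
                    c.caller: {
                        "junction_reads": c.junction_reads,
                        "spanning_reads": c.spanning_reads,
                        "breakpoint5": c.breakpoint5,
                        "breakpoint3": c.breakpoint3,
                    }
                },
                filters_passed=["panel", "blacklist", "support", "distance", "known-rescue"],
            )
        )
    return out


@dataclass
class FusionConfig:
    min_reads: int = 2
    min_distance: int = 10000
    breakpoint_tolerance: int = 10
    blacklist_min_sample_fraction: float = 0.9


def call_fusions(
    calls_a: Sequence[FusionCall],
    calls_b: Sequence[FusionCall],
    panel: CapturePanel | None = None,
    blacklist: Sequence[BlacklistEntry] = (),
    known_fusions: Sequence[tuple[str, str, set[str]]] = (),
    sample_type: str = "*",
    config: FusionConfig | None = None,
) -> tuple[list[ConsensusFusion], FilterAudit]:
    """Run the full ordered chain: panel -> blacklist -> support -> distance
    -> caller intersection -> known-fusion rescue.

    Filters are applied to each caller's list independently, then the lists
    are intersected; leftovers go through the rescue step.  Returns the
    tiered consensus report and the per-call audit trail.
    """
    cfg = config or FusionConfig()
    audit = FilterAudit()
    filtered = {}
    for label, calls in (("A", list(calls_a)), ("B", list(calls_b))):
        if panel is not None:
            calls = filter_on_panel(calls, panel, audit)
        calls = apply_blacklist(calls, blacklist, sample_type, audit)
        calls = filter_support(calls, cfg.min_reads, audit)
        calls = filter_distance(calls, cfg.min_distance, audit)
        filtered[label] = calls
    consensus, rest_a, rest_b = intersect_callers(
        filtered["A"], filtered["B"], cfg.breakpoint_tolerance
    )
    consensus += rescue_known(rest_a, rest_b, known_fusions, sample_type)
    return consensus, audit


def enumerate_isoforms(
    consensus_by_sample: dict[str, Sequence[ConsensusFusion]],
    pair: tuple[str, str],
    breakpoint_tolerance: int = 10,
) -> list[dict]:
    """Catalogue distinct fusion isoforms of one gene pair across samples.

    Isoforms are equivalence classes of (breakpoint5, breakpoint3) after
    merging coordinates within the tolerance (greedy, in coordinate order,
    against each class's founding junction).  Each catalogue entry lists the
    representative junction and per-sample presence.
    """
    pair = (pair[0].upper(), pair[1].upper())
    events = []
    for sample_id in sorted(consensus_by_sample):
        for c in consensus_by_sample[sample_id]:
            if (c.gene5.upper(), c.gene3.upper()) == pair:
                events.append((c.breakpoint5, c.breakpoint3, sample_id))
    events.sort(key=lambda e: (e[0][0], e[0][1], e[1][0], e[1][1], e[2]))
    classes: list[dict] = []
    for bp5, bp3, sample_id in events:
        home = next(
            (
                k
                for k in classes
                if _bp_close(k["breakpoint5"], bp5, breakpoint_tolerance)
                and _bp_close(k["breakpoint3"], bp3, breakpoint_tolerance)
            ),
            None,
        )
        if home is None:
            home = {"gene5": pair[0], "gene3": pair[1], "breakpoint5": bp5, "breakpoint3": bp3, "samples": []}
            classes.append(home)
        home["samples"].append(sample_id)
    for k in classes:
        k["n_samples"] = len(set(k["samples"]))
    return classes


# ---------------------------------------------------------------------------
# Table dialects
# ---------------------------------------------------------------------------

CALLER_A_COLUMNS = [
    "FusionName",
    "JunctionReadCount",
    "SpanningFragCount",
    "LeftBreakpoint",
    "RightBreakpoint",
]
CALLER_B_COLUMNS = [
    "Gene_1_symbol",
    "Gene_2_symbol",
    "Fusion_point_for_gene_1",
    "Fusion_point_for_gene_2",
    "Spanning_pairs",
    "Spanning_unique_reads",
]


def _fmt_bp(bp: Breakpoint) -> str:
    chrom, pos, strand = bp
    return f"{chrom}:{pos + 1}:{strand}"  # dialects are 1-based


def _parse_bp(text: str, where: str) -> Breakpoint:
    parts = str(text).split(":")
    if len(parts) != 3 or parts[2] not in {"+", "-", "."}:
        raise ValueError(f"{where}: malformed breakpoint {text!r}")
    try:
        pos = int(parts[1])
    except ValueError as exc:
        raise ValueError(f"{where}: non-numeric breakpoint position in {text!r}") from exc
    return (parts[0], pos - 1, parts[2])


def to_caller_a_frame(rows: Iterable[dict]) -> pd.DataFrame:
    recs = [
        {
            "FusionName": f"{r['gene5']}--{r['gene3']}",
            "JunctionReadCount": r["junction_reads"],
            "SpanningFragCount": r["spanning_reads"],
            "LeftBreakpoint": _fmt_bp(r["bp5"]),
            "RightBreakpoint": _fmt_bp(r["bp3"]),
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=CALLER_A_COLUMNS)


def to_caller_b_frame(rows: Iterable[dict]) -> pd.DataFrame:
    recs = [
        {
            "Gene_1_symbol": r["gene5"],
            "Gene_2_symbol": r["gene3"],
            "Fusion_point_for_gene_1": _fmt_bp(r["bp5"]),
            "Fusion_point_for_gene_2": _fmt_bp(r["bp3"]),
            "Spanning_pairs": r["spanning_reads"],
            "Spanning_unique_reads": r["junction_reads"],
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=CALLER_B_COLUMNS)


def read_caller_a(path_or_frame, sample_id: str = "S1") -> list[FusionCall]:
    """Parse a STAR-Fusion-style table (FusionName 'G5--G3', 1-based bps)."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame, sep="\t")
    missing = [c for c in CALLER_A_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"caller-A table missing columns {missing}")
    calls = []
    for i, row in df.iterrows():
        name = str(row["FusionName"])
        if "--" not in name:
            raise ValueError(f"caller-A row {i}: malformed FusionName {name!r}")
        g5, g3 = name.split("--", 1)
        calls.append(
            FusionCall(
                caller="A",
                sample_id=sample_id,
                gene5=g5,
                gene3=g3,
                breakpoint5=_parse_bp(row["LeftBreakpoint"], f"caller-A row {i}"),
                breakpoint3=_parse_bp(row["RightBreakpoint"], f"caller-A row {i}"),
                junction_reads=int(row["JunctionReadCount"]),
                spanning_reads=int(row["SpanningFragCount"]),
            )
        )
    return calls


def read_caller_b(path_or_frame, sample_id: str = "S1") -> list[FusionCall]:
    """Parse a FusionCatcher-style table (unique junction reads + pairs)."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame, sep="\t")
    missing = [c for c in CALLER_B_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"caller-B table missing columns {missing}")
    calls = []
    for i, row in df.iterrows():
        calls.append(
            FusionCall(
                caller="B",
                sample_id=sample_id,
                gene5=str(row["Gene_1_symbol"]),
                gene3=str(row["Gene_2_symbol"]),
                breakpoint5=_parse_bp(row["Fusion_point_for_gene_1"], f"caller-B row {i}"),
                breakpoint3=_parse_bp(row["Fusion_point_for_gene_2"], f"caller-B row {i}"),
                junction_reads=int(row["Spanning_unique_reads"]),
                spanning_reads=int(row["Spanning_pairs"]),
            )
        )
    return calls


def read_blacklist(path: str) -> list[BlacklistEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            BlacklistEntry(
                gene5=str(row["gene5"]),
                gene3=str(row["gene3"]),
                caller_scope=str(row.get("caller", "*")),
                sample_type_scope=str(row.get("sample_type", "*")),
            )
        )
    return entries


def read_known_fusions(path: str) -> list[tuple[str, str, set[str]]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        types = {t.strip() for t in str(row["cancer_types"]).split(",")}
        out.append((str(row["gene5"]), str(row["gene3"]), types))
    return out


def consensus_frame(consensus: Sequence[ConsensusFusion]) -> pd.DataFrame:
    rows = []
    for c in consensus:
        row = {
            "gene5": c.gene5,
            "gene3": c.gene3,
            "breakpoint5": _fmt_bp(c.breakpoint5),
            "breakpoint3": _fmt_bp(c.breakpoint3),
            "tier": c.tier,
        }
        for caller in ("A", "B"):
            ev = c.evidence.get(caller, {})
            row[f"junction_reads_{caller}"] = ev.get("junction_reads", 0)
            row[f"spanning_reads_{caller}"] = ev.get("spanning_reads", 0)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene5", "gene3", "breakpoint5", "breakpoint3", "tier",
            "junction_reads_A", "spanning_reads_A",
            "junction_reads_B", "spanning_reads_B",
        ],
    )
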