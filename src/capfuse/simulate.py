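"""Synthetic study-condition generators.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes: a small random genome with planted gene
models and splice-acceptor motifs, two fusion callers' output tables with
software-specific false positives, spike-in dilution series with logistic
detection dropout, per-exon coverage with a breakpoint discontinuity,
clonotype abundance distributions, and replicate count matrices.

Noise families follow standard RNA-seq practice: Poisson for fusion read
support, negative binomial for exon coverage, lognormal for spike-in
abundance and replicate variation.  Every generator is a pure function of
its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, CapturePanel, write_gtf

BASES = np.array(list("ACGT"))
PYRIMIDINES = np.array(list("CT"))
PURINES = np.array(list("AG"))
IG_TCR_LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class CallerErrorModel:
    """Error structure of the two fusion callers.

    False positives are predominantly software-specific: each caller draws
    its own FP gene pairs, never duplicated in the other caller's table.
    ``shared_fp_rate`` injects the rarer identical-in-both artifacts.
    Breakpoint coordinates disagree between callers by a rounded-Normal
    jitter of scale ``breakpoint_jitter_sd`` nucleotides.
    """

    fp_per_sample: float = 10.0
    shared_fp_rate: float = 0.0
    dropout: float = 0.1
    breakpoint_jitter_sd: float = 2.0
    fp_read_mean: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("breakpoint_jitter_sd must be >= 0")


@dataclass
class FusionTruth:
    """A planted true fusion: ordered partners, breakpoints, expression."""

    gene5: str
    gene3: str
    breakpoint5: tuple[str, int, str]  # (chrom, 0-based pos, strand)
    breakpoint3: tuple[str, int, str]
    expression: float = 30.0

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 8)
    n_samples: int = 1
    fusion_truth: list[FusionTruth] = field(default_factory=list)
    caller_error: CallerErrorModel = field(default_factory=CallerErrorModel)
    spike_ladder: list[tuple[float, int]] = field(
        default_factory=lambda: [(8.0 * 2**k, 12) for k in range(-4, 9)]
    )
    clonal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clonal_fraction < 1.0:
            raise ValueError("clonal_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Reference genome + annotation
# ---------------------------------------------------------------------------

GENES_PER_CHROM = 20
_FIRST_GENE_START = 3000
_INTERGENIC_GAP = 12000  # keeps neighbouring breakpoints beyond the distance filter


def simulate_reference(cfg: SimulationConfig) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Random genome with planted gene models and splice-acceptor motifs.

    Each internal exon's acceptor carries a polypyrimidine-enriched window
    (pyrimidine probability 0.9 over intron positions -20..-5) and the
    canonical AG dinucleotide at -2,-1, so the acceptor-profile analysis has
    signal to find.  Byte-identical under a fixed seed.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.exons_per_gene
    genes: dict[str, GeneModel] = {}
    chrom_arrays: dict[str, np.ndarray] = {}
    cursor: dict[str, int] = {}

    for i in range(cfg.n_genes):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        pos = cursor.get(chrom, _FIRST_GENE_START)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        exons: list[GenomicInterval] = []
        for j in range(n_exons):
            length = int(rng.integers(80, 251))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length
            if j < n_exons - 1:
                pos += int(rng.integers(300, 801))
        cursor[chrom] = pos + _INTERGENIC_GAP
        gid = f"G{i:04d}"
        gene = GeneModel(gid, gid, strand, {f"{gid}.t1": exons})
        genes[gid] = gene

    for chrom, end in cursor.items():
        chrom_arrays[chrom] = rng.choice(BASES, size=end + 1000)

    for gene in genes.values():
        for exons in gene.transcripts.values():
            arr = chrom_arrays[exons[0].chrom]
            acceptors = exons[1:] if gene.strand == "+" else exons[:-1]
            for exon in acceptors:
                _plant_acceptor(arr, exon, gene.strand, rng)

    genome = {c: "".join(a) for c, a in sorted(chrom_arrays.items())}
    return genome, genes


def _plant_acceptor(arr: np.ndarray, exon: GenomicInterval, strand: str, rng) -> None:
    if strand == "+":
        s = exon.start
        tract = rng.random(16) < 0.9
        arr[s - 20 : s - 4] = np.where(
            tract, rng.choice(PYRIMIDINES, 16), rng.choice(PURINES, 16)
        )
        arr[s - 2] = "A"
        arr[s - 1] = "G"
    else:
        e = exon.end
        tract = rng.random(16) < 0.9
        # transcript pyrimidine == genomic purine on the minus strand
        arr[e + 4 : e + 20] = np.where(
            tract, rng.choice(PURINES, 16), rng.choice(PYRIMIDINES, 16)
        )
        arr[e] = "C"  # complement G at -1
        arr[e + 1] = "T"  # complement A at -2


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def panel_from_genes(
    genes: dict[str, GeneModel], name: str = "panel", per_exon: bool = False
) -> CapturePanel:
    """A capture panel covering every targeted gene.

    By default one interval per gene span (breakpoints of targeted genes
    always overlap, even with caller coordinate jitter); ``per_exon`` tiles
    individual exons instead.
    """
    ivs, gids = [], []
    for gid in sorted(genes):
        if per_exon:
            for exons in genes[gid].transcripts.values():
                for exon in exons:
                    ivs.append(exon)
                    gids.append(gid)
        else:
            ivs.append(genes[gid].span())
            gids.append(gid)
    return CapturePanel(name, ivs, gids)


# ---------------------------------------------------------------------------
# Fusion truths and caller outputs
# ---------------------------------------------------------------------------


def plant_fusions(
    genes: dict[str, GeneModel],
    n_fusions: int,
    expression: float = 30.0,
    seed: int = 0,
    interchromosomal_only: bool = False,
) -> list[FusionTruth]:
    """Pick gene pairs and exon-boundary breakpoints for true fusions.

    Distinct genes are always separated by at least the intergenic gap, so
    intra-chromosomal truths clear the junction-distance filter.
    """
    rng = np.random.default_rng(seed)
    gids = sorted(genes)
    truths: list[FusionTruth] = []
    used: set[tuple[str, str]] = set()
    attempts = 0
    while len(truths) < n_fusions:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("cannot place requested fusions")
        g5, g3 = (gids[k] for k in rng.choice(len(gids), 2, replace=False))
        if (g5, g3) in used:
            continue
        if interchromosomal_only and genes[g5].chrom == genes[g3].chrom:
            continue
        bp5 = _donor_site(genes[g5], rng)
        bp3 = _acceptor_site(genes[g3], rng)
        used.add((g5, g3))
        truths.append(FusionTruth(g5, g3, bp5, bp3, expression))
    return truths


def _donor_site(gene: GeneModel, rng) -> tuple[str, int, str]:
    exons = gene.transcripts[gene.main_transcript()]
    k = int(rng.integers(0, max(1, len(exons) - 1)))
    exon = exons[k] if gene.strand == "+" else exons[len(exons) - 1 - k]
    pos = exon.end - 1 if gene.strand == "+" else exon.start
    return (exon.chrom, pos, gene.strand)


def _acceptor_site(gene: GeneModel, rng) -> tuple[str, int, str]:
    exons = gene.transcripts[gene.main_transcript()]
    k = int(rng.integers(1, len(exons))) if len(exons) > 1 else 0
    exon = exons[k] if gene.strand == "+" else exons[len(exons) - 1 - k]
    pos = exon.start if gene.strand == "+" else exon.end - 1
    return (exon.chrom, pos, gene.strand)


def simulate_caller_outputs(
    truth: list[FusionTruth],
    err: CallerErrorModel,
    sample_id: str,
    seed: int,
    genes: dict[str, GeneModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit one sample's tables for caller A and caller B.

    Each true fusion appears in each caller's table independently with
    probability ``1 - dropout``; junction and spanning read counts are
    Poisson around the planted expression, and breakpoints are jittered
    independently per caller.  Caller-specific false positives never share a
    gene pair across the two tables; shared false positives are injected as
    identical rows in both.

    Returns the two tables in the caller-A (STAR-Fusion-like) and caller-B
    (FusionCatcher-like) TSV dialects.
    """
    from .fusions import to_caller_a_frame, to_caller_b_frame

    rng = np.random.default_rng(seed)
    rows_a: list[dict] = []
    rows_b: list[dict] = []
    truth_pairs = {(t.gene5, t.gene3) for t in truth}

    for t in truth:
        for rows in (rows_a, rows_b):
            if rng.random() < err.dropout:
                continue
            rows.append(
                {
                    "gene5": t.gene5,
                    "gene3": t.gene3,
                    "bp5": _jitter(t.breakpoint5, err.breakpoint_jitter_sd, rng),
                    "bp3": _jitter(t.breakpoint3, err.breakpoint_jitter_sd, rng),
                    "junction_reads": int(rng.poisson(t.expression)),
                    "spanning_reads": int(rng.poisson(t.expression)),
                }
            )

    fp_universe = _fp_universe(genes)
    seen_fp: set[tuple[str, str]] = set(truth_pairs)
    for rows in (rows_a, rows_b):
        n_fp = int(rng.poisson(err.fp_per_sample))
        for _ in range(n_fp):
            pair_row = _draw_fp(fp_universe, seen_fp, err, rng)
            if pair_row is not None:
                rows.append(pair_row)

    n_shared = int(rng.poisson(err.shared_fp_rate))
    for _ in range(n_shared):
        pair_row = _draw_fp(fp_universe, seen_fp, err, rng)
        if pair_row is not None:
            rows_a.append(dict(pair_row))
            rows_b.append(dict(pair_row))

    return to_caller_a_frame(rows_a), to_caller_b_frame(rows_b)


def _jitter(bp: tuple[str, int, str], sd: float, rng) -> tuple[str, int, str]:
    chrom, pos, strand = bp
    if sd > 0:
        pos = max(1, pos + int(round(rng.normal(0.0, sd))))
    return (chrom, pos, strand)


def _fp_universe(genes: dict[str, GeneModel] | None) -> list[tuple[str, str, int, str]]:
    """(gene_id, chrom, breakpoint pos, strand) candidates for false positives."""
    if genes:
        out = []
        for gid in sorted(genes):
            g = genes[gid]
            exons = g.transcripts[g.main_transcript()]
            out.append((gid, g.chrom, exons[0].end - 1, g.strand))
        return out
    return [
        (f"FPG{i:03d}", f"chr{i % 5 + 1}", 100000 + 40000 * i, "+") for i in range(60)
    ]


def _draw_fp(universe, seen: set, err: CallerErrorModel, rng) -> dict | None:
    for _ in range(200):
        i, j = rng.choice(len(universe), 2, replace=False)
        g5, c5, p5, s5 = universe[int(i)]
        g3, c3, p3, s3 = universe[int(j)]
        if (g5, g3) in seen:
            continue
        seen.add((g5, g3))
        return {
            "gene5": g5,
            "gene3": g3,
            "bp5": (c5, int(p5 + rng.integers(0, 500)), s5),
            "bp3": (c3, int(p3 + rng.integers(0, 500)), s3),
            "junction_reads": int(1 + rng.poisson(err.fp_read_mean)),
            "spanning_reads": int(rng.poisson(err.fp_read_mean)),
        }
    return None


def truth_frame(truth: list[FusionTruth]) -> pd.DataFrame:
    """Planted truths in TSV-ready form, so tests never re-derive them."""
    return pd.DataFrame(
        [
            {
                "gene5": t.gene5,
                "gene3": t.gene3,
                "chrom5": t.breakpoint5[0],
                "pos5": t.breakpoint5[1],
                "strand5": t.breakpoint5[2],
                "chrom3": t.breakpoint3[0],
                "pos3": t.breakpoint3[1],
                "strand3": t.breakpoint3[2],
                "expression": t.expression,
            }
            for t in truth
        ]
    )


# ---------------------------------------------------------------------------
# Spike-in dilution series
# ---------------------------------------------------------------------------


@dataclass
class SpikeDetectionModel:
    """Detection and abundance model for spike-in standards.

    Detection of a spike is Bernoulli with probability following a logistic
    curve in log2 concentration (midpoint ``c50_pM``, slope per doubling).
    Captured abundance is concentration x enrichment x lognormal noise;
    non-targeted spikes leak through at ``leakage`` of the enrichment.

    Noise has two lognormal components: ``input_sd`` is shared between the
    capture and conventional measurements of the same spike (the same
    aliquot feeds both libraries, so this component cancels in the
    enrichment fold), while ``assay_sd`` is drawn independently per
    measurement.
    """

    c50_pM: float = 2.0
    slope: float = 3.0
    enrichment: float = 40.0
    input_sd: float = 0.2
    assay_sd: float = 0.15
    leakage: float = 0.001

    def detect_prob(self, concentration_pM: float) -> float:
        x = math.log2(concentration_pM) - math.log2(self.c50_pM)
        if math.isinf(self.slope):
            return 1.0 if x >= 0 else 0.0
        return 1.0 / (1.0 + math.exp(-self.slope * x))


def simulate_spikein_series(
    ladder: list[tuple[float, int]],
    detection_model: SpikeDetectionModel,
    seed: int,
    n_nontargeted: int = 0,
    library_id: str = "L1",
) -> pd.DataFrame:
    """Spike-in table over a dilution ladder of (concentration pM, n spikes)."""
    if any(c <= 0 for c, _ in ladder):
        raise ValueError("ladder concentrations must be > 0")
    rng = np.random.default_rng(seed)
    m = detection_model

    def _ln(sd: float) -> float:
        return rng.lognormal(-sd**2 / 2, sd) if sd > 0 else 1.0

    rows = []
    k = 0
    for conc, n_spikes in ladder:
        for _ in range(n_spikes):
            shared = _ln(m.input_sd)
            rows.append(
                {
                    "spike_id": f"SPK{k:04d}",
                    "targeted": True,
                    "concentration_pM": conc,
                    "library_id": library_id,
                    "abundance_capture": conc * m.enrichment * shared * _ln(m.assay_sd),
                    "abundance_rnaseq": conc * shared * _ln(m.assay_sd),
                    "detected": bool(rng.random() < m.detect_prob(conc)),
                }
            )
            k += 1
    concs = [c for c, _ in ladder]
    for _ in range(n_nontargeted):
        conc = float(concs[int(rng.integers(0, len(concs)))])
        shared = _ln(m.input_sd)
        rows.append(
            {
                "spike_id": f"SPK{k:04d}",
                "targeted": False,
                "concentration_pM": conc,
                "library_id": library_id,
                "abundance_capture": conc * m.enrichment * m.leakage * shared * _ln(m.assay_sd),
                "abundance_rnaseq": conc * shared * _ln(m.assay_sd),
                "detected": False,
            }
        )
        k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exon coverage with a planted discontinuity
# ---------------------------------------------------------------------------


def simulate_exon_coverage(
    gene: GeneModel,
    junction_exon_index: int,
    fold: float,
    depth: float,
    dispersion: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-exon read-start counts for the gene's main transcript.

    Exon indexing is transcript 5'->3' order.  Exons before the boundary
    index have mean ``depth * fold * length``; exons at or after it have
    mean ``depth * length`` (negative binomial with the given dispersion;
    ``dispersion == 0`` gives the noiseless rounded means).  Boundary 0 or
    n_exons means no internal breakpoint.
    """
    exons = list(gene.transcripts[gene.main_transcript()])
    if gene.strand == "-":
        exons = exons[::-1]
    n = len(exons)
    if not 0 <= junction_exon_index <= n:
        raise ValueError("junction_exon_index out of range")
    rng = np.random.default_rng(seed)
    counts = np.empty(n, dtype=np.int64)
    for i, exon in enumerate(exons):
        mean = depth * len(exon) * (fold if i < junction_exon_index else 1.0)
        if dispersion <= 0:
            counts[i] = int(round(mean))
        else:
            r = 1.0 / dispersion
            counts[i] = rng.negative_binomial(r, r / (r + mean)) if mean > 0 else 0
    return counts


# ---------------------------------------------------------------------------
# Clonotypes
# ---------------------------------------------------------------------------


def simulate_clonotypes(
    n_clones: int,
    alpha: float,
    clonal_fraction: float,
    total_reads: int,
    seed: int,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Clonotype table: power-law background, optional planted dominant clone.

    Background clone abundances follow rank^(-alpha) normalised to
    ``(1 - clonal_fraction) * total_reads``; a planted clone (the first row)
    receives exactly ``clonal_fraction`` of reads before rounding.  Read
    counts are integerised by largest remainder so they sum exactly to
    ``total_reads``; zero-read clones are dropped.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0.0 <= clonal_fraction < 1.0:
        raise ValueError("clonal_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    if n_clones == 1:
        fractions = np.array([1.0])
    elif clonal_fraction > 0:
        bg = np.arange(1, n_clones) ** (-float(alpha))
        fractions = np.concatenate(
            [[clonal_fraction], (1 - clonal_fraction) * bg / bg.sum()]
        )
    else:
        bg = np.arange(1, n_clones + 1) ** (-float(alpha))
        fractions = bg / bg.sum()

    reads = _largest_remainder(fractions * total_reads, total_reads)
    seen: set[tuple[str, str]] = set()
    rows = []
    for r in reads:
        if r == 0:
            continue
        while True:
            locus = IG_TCR_LOCI[int(rng.integers(0, len(IG_TCR_LOCI)))]
            cdr3 = "".join(rng.choice(BASES, 36))
            if (locus, cdr3) not in seen:
                seen.add((locus, cdr3))
                break
        rows.append({"sample_id": sample_id, "locus": locus, "cdr3": cdr3, "reads": int(r)})
    return pd.DataFrame(rows)


def _largest_remainder(x: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(x).astype(np.int64)
    short = total - int(floors.sum())
    order = np.argsort(-(x - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def simulate_replicates(
    base_counts: np.ndarray, cv: float, n_replicates: int, seed: int
) -> np.ndarray:
    """Feature x replicate matrix with multiplicative lognormal noise.

    The lognormal is parameterised so each feature's expectation equals its
    base count and its coefficient of variation equals ``cv``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    base = np.asarray(base_counts, dtype=float)
    if cv == 0:
        return np.tile(base[:, None], (1, n_replicates))
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    factors = rng.lognormal(-(sigma**2) / 2, sigma, size=(base.size, n_replicates))
    return base[:, None] * factors


# ---------------------------------------------------------------------------
# Read pairs (on-target QC and splice-junction coverage)
# ---------------------------------------------------------------------------


def simulate_read_pairs(
    panel: CapturePanel,
    n_pairs: int,
    on_target_prob: float,
    seed: int,
    unique_prob: float = 1.0,
    read_length: int = 100,
    offtarget_chrom: str = "chrOff",
) -> pd.DataFrame:
    """Aligned read pairs with a set on-target probability.

    On-target pairs have read1 inside a random panel interval; off-target
    pairs land on a decoy chromosome outside the panel.  Emulates the
    double-capture enrichment of the assay; no fragment-length model.
    """
    rng = np.random.default_rng(seed)
    ivs = panel.intervals
    rows = []
    for i in range(n_pairs):
        unique = bool(rng.random() < unique_prob)
        if rng.random() < on_target_prob and ivs:
            iv = ivs[int(rng.integers(0, len(ivs)))]
            s1 = int(max(0, iv.start + rng.integers(-read_length // 2, max(1, len(iv)))))
            chrom = iv.chrom
        else:
            chrom = offtarget_chrom
            s1 = int(rng.integers(1000, 1_000_000))
        s2 = s1 + read_length + int(rng.integers(0, 200))
        rows.append(
            {
                "pair_id": f"P{i:06d}",
                "read1_chrom": chrom,
                "read1_start": s1,
                "read1_end": s1 + read_length,
                "read1_strand": "+",
                "read2_chrom": chrom,
                "read2_start": s2,
                "read2_end": s2 + read_length,
                "read2_strand": "-",
                "mapping_unique": unique,
                "splice_gaps": "",
            }
        )
    return pd.DataFrame(rows)


def simulate_splice_pairs(
    genes: dict[str, GeneModel],
    covered_fraction: float,
    seed: int,
    reads_per_intron: int = 2,
    overhang: int = 20,
) -> pd.DataFrame:
    """Spliced read pairs whose gaps exactly cover a set fraction of introns.

    Exactly ``round(covered_fraction * n_introns)`` introns (chosen at
    random) receive reads with a splice gap equal to the intron on the
    matching strand; the remainder receive a partial-gap read that fails the
    full-containment rule.
    """
    from .intervals import derive_introns

    rng = np.random.default_rng(seed)
    introns: list[GenomicInterval] = []
    seen = set()
    for gid in sorted(genes):
        for iv in derive_introns(genes[gid]):
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key not in seen:
                seen.add(key)
                introns.append(iv)
    n_cov = int(round(covered_fraction * len(introns)))
    covered = set(rng.permutation(len(introns))[:n_cov].tolist())
    rows = []
    k = 0
    for idx, intron in enumerate(introns):
        full = idx in covered
        for _ in range(reads_per_intron if full else 1):
            if full:
                gap = intron
            else:  # gap starting 10% into the intron: not full containment
                trim = max(1, len(intron) // 10)
                gap = GenomicInterval(
                    intron.chrom, intron.start + trim, intron.end, intron.strand
                )
            r1s = max(0, gap.start - overhang)
            rows.append(
                {
                    "pair_id": f"J{k:06d}",
                    "read1_chrom": gap.chrom,
                    "read1_start": r1s,
                    "read1_end": gap.end + overhang,
                    "read1_strand": gap.strand,
                    "read2_chrom": gap.chrom,
                    "read2_start": gap.end + overhang,
                    "read2_end": gap.end + overhang + 50,
                    "read2_strand": "-" if gap.strand == "+" else "+",
                    "mapping_unique": True,
                    "splice_gaps": f"{gap.chrom}:{gap.start}-{gap.end}:{gap.strand}",
                }
            )
            k += 1
    return pd.DataFrame(rows)
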