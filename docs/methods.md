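# Methods

`capfuse` implements the post-alignment analysis layer of a targeted RNA-seq
fusion-gene diagnostic: consensus fusion calling from two callers' output
tables, capture-panel QC against spike-in standards, exon-level coverage
analysis at fusion junctions, novel-exon classification, and immune-repertoire
summarisation. This note describes the models and procedures, the parameters
that matter, what the synthetic-data generators emulate, and the design
choices made where the design was genuinely open.

## Coordinate model

All coordinates are 0-based half-open internally (BED-native). GTF input
(1-based inclusive) is converted on read and back on write; the caller table
dialects print 1-based breakpoints and are converted likewise. Chromosome
names are used verbatim — no "chr" normalisation — to avoid silent namespace
mismatches. Capture-panel overlap queries are strand-agnostic, because
hybridisation probes capture cDNA of either orientation; intron-coverage
queries are stranded, because splice direction is meaningful.

## Consensus fusion calling

Fusion callers on targeted RNA-seq emit many candidates, most of them
software-specific false positives. The filter chain is applied to each
caller's list independently, in order:

1. **Panel overlap** — keep a call when at least one partner's breakpoint
   overlaps a panel interval by ≥ 1 bp. One targeted partner suffices:
   capture pulls down the whole chimeric transcript, so novel non-targeted
   partners are detectable and must not be discarded.
2. **Blacklist** — remove calls whose ordered gene pair matches a curated
   entry compatible with the call's caller and the sample type. A blacklist
   can also be derived from a cohort (`build_blacklist`): per caller, gene
   pairs present in ≥ 90% of samples (default `min_sample_fraction=0.9`) are
   recurrent artifacts, scoped to that caller.
3. **Read support** — junction + spanning reads ≥ 2 (`min_reads`). The sum
   rule is the most permissive faithful reading of a bare read-count
   threshold; a per-column mode can be obtained by pre-filtering.
4. **Junction distance** — intra-chromosomal calls need breakpoints
   ≥ 10,000 nt apart (inclusive; `min_distance`), removing read-through and
   neighbour-gene mismapping artifacts. Inter-chromosomal calls always pass.

The surviving lists are then **intersected**: for each ordered gene pair
(5′ partner first; A–B and B–A are distinct, reciprocal fusions are separate
events), caller-A and caller-B calls are matched greedily by nearest
breakpoints, requiring the same chromosome on each side and both positions
within `breakpoint_tolerance` (default ±10 nt — callers disagree by small
offsets around the true junction; a point-coordinate "overlap" needs an
explicit tolerance). Each input call is used at most once; ties break on
lower 5′ then 3′ coordinate for determinism. Matches become
**high-confidence** consensus calls with caller A's coordinates as
representative and both callers' evidence retained.

Leftover single-caller calls pass through a **known-fusion rescue**: calls
whose ordered pair appears in a curated known-fusion list with a cancer type
compatible with the sample are emitted at the lower tier
`single-caller-known`, never promoted. This replaces interactive manual
curation with a reproducible rule plus a complete audit trail: every removal
is logged with a reason code, and counts are conserved (input = survivors +
removals at every step).

Isoform enumeration groups consensus junctions of one gene pair across
samples into equivalence classes within the breakpoint tolerance (greedy, in
coordinate order, against each class's founding junction).

## Capture QC

- **On-target rate**: fraction of uniquely-mapped read pairs with ≥ 1 mate
  overlapping the panel by ≥ 1 bp. Uniqueness is a boolean on input records
  (from SAM, MAPQ ≥ 255 by default), since the criterion is aligner-specific.
- **Spike-in enrichment**: per spike, fold = capture abundance /
  conventional abundance, computed only where both are > 0; zero-abundance
  spikes are excluded and reported separately rather than pseudocounted
  (a pseudocount would fabricate folds for undetected spikes). Summary means
  are arithmetic by default, geometric by flag.
- **Limit of detection**: the detection curve (fraction of spikes detected
  per ladder concentration) is interpolated linearly in log2 concentration
  between the lowest adjacent pair bracketing the threshold (default 0.5).
  Dilution ladders are geometric, so log2 is the natural scale. Degenerate
  curves return "below-range"/"above-range".
- **Intron junction coverage**: an annotated intron counts as covered only
  when a read's splice gap contains the *entire* intron on the matching
  strand (full containment, not partial overlap). The denominator is the
  deduplicated intron set over all transcripts.
- **Replicate CV**: per-feature sample standard deviation (n−1) over mean,
  zero-mean features excluded; replicates are a sample, not a population.
  Note the n−1 sample SD is itself biased low at n = 3 replicates
  (E[s] ≈ 0.89 σ), so recovered mean CVs sit slightly below the generating
  CV; the acceptance check budgets for this.

## Expression analysis

Per-gene read 5′-end counts are assigned to exons of the **main transcript**
(longest by summed exonic length, ties to the lowest transcript id — the
choice of "main isoform" is otherwise unspecified) by half-open containment,
and normalised to exon length. TPM is count/length rates scaled to sum to
10⁶; effective length is the exon length with no fragment-length correction
(quantifier-grade length modelling is out of scope).

**Changepoint detection** scores every internal exon boundary b exhaustively:
score(b) = |log2(mean density left of b / mean density right of b)|, with a
pseudocount of 0.5 reads per exon stabilising empty segments (genes have at
most ~100 exons, so exhaustive search is exact and oracle-checkable). The
reported fold is the raw density ratio (infinite for an empty right
segment); a gene is flagged when the fold or its inverse reaches `min_fold`
(default 3). Ties go to the lowest boundary. The estimate is equivariant
under exon-order reversal (boundary mirrors, fold inverts).

**Cohort outliers**: a sample is flagged for a gene when its TPM is ≥ 10×
(configurable) the median of the *other* samples; this catches promoter
fusions that deregulate a gene without producing a chimeric junction. A zero
median with positive expression reports an infinite fold.

## Novel exons

Only multi-exon assembled transcripts overlapping a targeted gene's span are
considered. An exon is **novel** iff it overlaps zero reference exons by
even 1 bp; the test is strand-agnostic by design (any-overlap exclusion
against the combined annotation). Position classes are per-transcript: first
exon in transcript orientation → 5′, last → 3′, rest internal; a
deduplication report is available since transcripts may share exons. Frame
impact is defined for internal exons only: length mod 3 ≠ 0 shifts the
reading frame. The acceptor profile extracts strand-corrected windows over
intron −20..−1 and exon +1..+3 around each 3′ splice site (window
configurable) and reports per-position base probabilities plus the mean
pyrimidine fraction over −20..−5 — polypyrimidine-tract and AG-motif
evidence that candidate novel exons are genuinely spliced.

## Immune repertoire

Clonotype identity is exactly (locus, CDR3 string); fuzzy CDR3 merging is
the upstream caller's concern. Summaries report clonotype counts, the
top-clone read fraction, and the IG ({IGH, IGK, IGL}) vs TCR
({TRA, TRB, TRG, TRD}) partition. Clonal dominance is flagged when a
sample's top-clone fraction (within-sample normalised, hence comparable
across libraries of different depth) is ≥ 10× the median of the other
cohort samples.

## Synthetic study conditions

The generators in `capfuse.simulate` are pure functions of (config, seed)
and produce byte-identical outputs under a fixed seed.

- **Reference**: a uniform-ACGT random genome with planted single-transcript
  genes (3–8 exons of 80–250 nt, introns 300–800 nt, 20 genes per
  chromosome, 12 kb intergenic gaps so distinct genes always clear the
  junction-distance filter). Every internal acceptor carries a planted
  polypyrimidine tract (pyrimidine probability 0.9 over −20..−5) and the
  canonical AG at −2,−1, so motif analyses have signal to find.
- **Caller outputs**: true fusions appear per caller with probability
  1 − dropout, with Poisson junction/spanning counts around the planted
  expression (default 30) and independently jittered breakpoints (rounded
  Normal, sd 2 nt — the disagreement the consensus tolerance must absorb).
  False positives are predominantly software-specific: each caller draws its
  own random gene pairs, never duplicated in the other table; shared
  artifacts are injected identically into both and are, by construction, the
  failure mode the blacklist exists for.
- **Spike-ins**: abundance = concentration × enrichment × shared input
  noise (lognormal sd 0.2, common to both library types and cancelling in
  the fold) × assay noise (sd 0.15 per measurement); detection is Bernoulli
  on a logistic in log2 concentration (midpoint 2 pM, slope 3 per doubling);
  non-targeted spikes leak at 10⁻³ of the enrichment.
- **Exon coverage**: negative binomial per exon with dispersion 0.05 — the
  assay's replicate CV (~0.07) implies near-Poisson counts, so 0.05 is a
  conservative upper bound; dispersion 0 gives the deterministic noiseless
  limit.
- **Clonotypes**: power-law background (rank^−α) with an optional planted
  dominant clone holding an exact read fraction; integerisation by largest
  remainder conserves total reads.
- **Replicates**: multiplicative lognormal noise parameterised to preserve
  the expectation and hit the target CV exactly in population.

What the generators do **not** emulate: read-level sequence errors,
alignment and mapping ambiguity, fragment-length and GC bias, FFPE
degradation profiles, multi-isoform genes, and symbol aliasing between
callers. Passing tests therefore show the analysis layer is correct given
well-formed caller tables and alignments; they do not validate upstream
aligner or caller behaviour on real libraries.

## Numerical choices and degenerate inputs

Interpolation for LOD is linear in log2; changepoint pseudocount 0.5;
enrichment zeros excluded, never pseudocounted; empty BED panels warn but
parse; single-exon transcripts yield no introns and reject changepoint
analysis; zero uniquely-mapped pairs, all-zero counts, and empty clonotype
inputs raise errors rather than returning silent zeros. All greedy
procedures (caller matching, isoform clustering) order candidates
deterministically before matching.

## Known limitations

Cohort-level diagnostic rates from the original clinical application depend
on patient sequencing data and per-sample curation decisions and are not
recomputable here; the acceptance script instead measures the method's
operating characteristics (precision, recall, recovery rates, calibration)
on the synthetic study conditions above, at desk scale (100–200 simulations
per quantity). Gene-symbol matching between callers is exact after
upper-casing; no alias table is applied. The within-locus clonotype noise
filter hinted at by upstream tools is not implemented.
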