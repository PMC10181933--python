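# Methods

This note documents the models and procedures `circlescope` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## Evidence model for circular DNA

A circular molecule sequenced with short paired-end reads leaves two
alignment signatures relative to the linear reference: fragments
spanning the circle junction either produce a read aligned in two pieces
(a primary alignment plus an SA-tagged supplementary, clipping at the
junction) or a pair whose mates face away from each other on the
reference (outward / RF orientation, versus inward / FR for ordinary
fragments). These two classes, and only these, are treated as
circle-supporting evidence. Orientation is derived from SAM flags and
mate coordinates at parse time; records with MAPQ < 5, secondary and
duplicate-flagged records are dropped uniformly at the parsing boundary.
Coordinates are 0-based half-open everywhere internally; SAM is 1-based
on disk and converted at the boundary.

## Circle calling

Calling is per cell and two-step: find read-enriched regions, then
require junction evidence at their edges.

**Enrichment detection.** Read starts are binned (default 50 bp). The
background start rate is estimated genome-wide, with two robustness
guards motivated by the data regime this assay produces: (i) the naive
rate (total reads / effective genome length) is refined by iteratively
excluding bins above the current enrichment threshold, because in
heavily circle-loaded cells the circles themselves can carry the
majority of the library and would otherwise inflate the background
several-fold; (ii) the estimate is capped by the median bin count
(zero-padded to the effective genome length) whenever that median is
nonzero, which is robust even when enriched bins are a large minority.
Candidate regions are built at two thresholds: maximal runs of bins
holding a weak occupancy threshold t2 = max(2, ⌈λ_bin⌉ + 1) form the
skeleton; runs are merged across gaps up to `max_gap` (default 500 bp,
the library's insert scale, producing the variable-width behaviour); a
merged run survives only if it contains at least one strong bin
(Poisson upper tail of λ_bin below `bin_p` = 1e-4), and weak runs
without a strong seed are trimmed from the group edges. The two-level
construction is what keeps boundaries tight: interior coverage dips of a
true circle stay bridged, while chance background clumps near an edge
cannot attach to the region and drag the boundary outward. Region ends
are additionally clamped one bin past the last supported bin so a stray
background read starting inside the run cannot extend the edge by a read
length. Each candidate is scored with a one-sided Poisson upper tail on
its read count against rate × (span + 2·max_gap) — the pad compensates
the selection bias of testing merged clusters — with single-read
candidates never significant, and Benjamini–Hochberg (ties broken by
genomic position) returns regions with q < 0.001. When a mask BED is
supplied, the effective genome length excludes masked bases.

**Classification.** A support read counts toward a region when its
alignment overlaps either edge window [start − E, start + E) or
[end − E, end + E), E = `edge_slack` (default 150 bp, the read length).
Distinct read ids are counted once, split evidence taking precedence
over outward evidence for reads that are both. Regions with
n_split + n_outward ≥ `min_support` (default 2) are classified circular.
The support threshold is deliberately a parameter: it is an empirical
operating point, not a derived constant.

On the generator's recovery conditions (1-Mb genome, ~10 circles of
0.5–50 kb per cell at 20× with 1× linear background, 20 cells) the
caller's recall and precision are ≥ 0.98 with mean boundary error
~30 bp; the suite asserts ≥ 0.95 and mean error ≤ 150 bp.

## Cell quality control

DNA QC treats mtDNA as a positive control present in every intact cell:
pass iff mean chrM depth ≥ 10 reads/bp (total aligned bases / 16,569)
and ≥ 85% of chrM positions have depth ≥ 1. "Captured" is read as
breadth at depth ≥ 1, the most literal reading; the depth cutoff is
configurable. Both rules are strict "fewer than" comparisons, so
equality passes. Nuclei carry no mtDNA and pass DNA QC vacuously. RNA
QC counts features after restricting to genes detected in ≥ 3 cells
(≥ 5,000 for cell lines, ≥ 2,000 for T cells and nuclei) and excludes
cells with mitochondrial expression above 15% (2.5% for nuclei);
mitochondrial genes are recognized by chrM location or an `MT-` name
prefix to tolerate annotation dialects. TPM divides counts by gene
length, scales each cell to 1e6 and applies ln(1 + x).

## Recurrence and co-occurrence

Reads overlapping a cell's classified circles are counted into 100-kb
bins by alignment start (deterministic for straddlers) and normalized to
counts per million of the cell's library. Positivity is a per-cell
one-sided Poisson test at raw P < 0.05 — no multiple-testing correction,
matching the stated contract — against the cell's background mean over
nonzero non-chrM bins. The tested bin is excluded from its own
background (leave-one-out): without this, a cell whose only circle is a
massive amplicon would test the amplicon bin against itself and never
call it positive. When a cell has a single nonzero bin the fallback
background is the mean over all non-chrM bins. Cells with fewer than 10
nonzero bins are flagged as having an unstable background. Bins are
categorized with precedence ecDNA (overlap with the bulk amplicon
reconstruction) > chrM > other. Co-occurrence subtracts intervals
shared between amplicons before testing overlap, so a circle confined to
a shared segment counts for neither; an amplicon fully covered by
exclusions is rejected as undetectable.

## Dosage and phasing

Relative copy number per cell and amplicon is
log2(mean coverage of amplicon genes / background), where background is
the trimmed mean of non-amplicon gene coverages with the top and bottom
5% removed (k = ⌊0.05·n⌋ per side; ≥ 20 background genes required). The
trimming guards against incomplete amplicon identification leaving a few
amplified genes in the background. The procedure is described in the
field both as "winsorized" and as removal of the tails; the removal
reading is implemented, with a winsorize option that clamps instead.
Amplicon genes are those overlapping the union of the cell's own
classified circles and the supplied amplicon reconstruction — the union
covers cells where the caller misses the amplicon, and the estimate
records which source applied. Genes on any cell circle are excluded
from the background even when not part of a named amplicon.

Dosage–expression coupling reports Pearson r, two-sided p and the
least-squares line between the per-cell estimate and CPM expression
summed over amplicon genes. SNP phasing uses a two-sided exact binomial
test of bulk B-allele frequency against 0.5 (p < 0.05, configurable):
BAF > 0.5 assigns the alternate allele to the gained (amplified) side,
BAF < 0.5 the reference; cells are then genotyped at every known SNP
with the bulk assignment retained, which makes the mono-allelic origin
of an amplicon directly visible as per-cell BAFs sitting on one side of
0.5. Small-circle content is n(circles < 3 kb)/n(circles) with a strict
inequality on end − start; ranked cells split into bottom 40% "low",
top 40% "high" (k = ⌊0.4·n⌋ each), middle "mid", ties broken by cell id.

## Microhomology

Windows are 100 bp per junction: [start − 50, start + 50) and
[end − 50, end + 50), i.e. 50 bp inside the circle and 50 bp of flanking
linear DNA; circles shorter than 100 bp, or with flanks running off the
chromosome, are dropped and counted. The two windows of a circle are
compared with an exact ungapped local-alignment scan: per-diagonal
maximum-segment recursion (Kadane) over the +1/−2 score matrix, O(mn),
reporting the best segment's score, matched bases and span. This is the
optimum that seeded megablast extension approximates; computing it
exactly makes the scan verifiable against an independent full
Smith–Waterman-style recursion, with which it agrees on 100% of random
window pairs. Microhomology is contiguous by definition, so the scan is
ungapped. The reverse complement of the end window is scanned as well
(the strand of the homology is not observable from the windows alone)
and the better orientation is reported.

Significance follows the megablast convention: matched length ≥ 4 (the
word size acting as a minimum homology length) and E < 1, with
E = K·m·n·e^(−λS). Both constants are computed numerically at startup
rather than tabulated: λ solves E[e^(λX)] = 1 for the ±(+1/−2) step
distribution at background match probability 1/4 (λ ≈ 1.3327), and K
uses the fact that this walk is skip-free upward (its only positive step
is +1), giving K = r·c with r = q(1 − e^(−2λ)) the descending-ladder
rate and c the limit of P(reach y before dropping below 0)·e^(λy) from a
small absorbing linear system (K ≈ 0.62). The resulting E-values agree
with blastn's to within ~10%.

One property of this rule is worth stating plainly: E < 1 is permissive.
For 100-bp windows the significance threshold sits near score 7, and two
random 100-mers share a segment that good roughly half the time (the
same is true of blastn run with these exact parameters). Significance
under this rule therefore measures "at least as much homology as a
shared ~7-mer", not rarity under the null; callers needing a stringent
null should lower `max_expect`.

## Chromatin randomization

The observed statistic is either the circle-size-weighted mean of a
fixed-bin CPM track, Σ size_i·mean_i / Σ size_i, or the percentage of
circle edges (exact start/end points; an `edge_pad` is available) lying
inside a peak. The null re-places every circle uniformly at random
N = 1,000 times, preserving its length and its chromosome (chromosome
preservation conserves per-chromosome signal composition; a
cross-chromosome mode exists), inside the unmasked genome — gaps are
sampled with probability proportional to the number of valid start
positions, so placement is exactly uniform over legal layouts.
Randomized circles may overlap each other; a circle longer than every
unmasked gap on its chromosome is an error naming the circle. Empirical
P is (1 + #{null ≥ obs})/(N + 1) for enrichment and with ≤ for
depletion; both are always reported, their sum exceeds 1 by at least
1/(N + 1) (ties), and the minimum attainable P is 1/(N + 1). With the
observed layout drawn from its own null the empirical P is uniform on
{k/(N + 1)} (KS-checked in the suite).

## mtDNA lineage

The built-in pileup caller (alt called at AF ≥ 0.01 and ≥ 3 supporting
reads; depth 0 yields no call) stands in for heavyweight somatic
callers; consensus filtering is faithful to the two-step rule — a
variant must be called in ≥ 2 cells by the same caller, and must then be
called by both callers — with the built-in caller run at a strict
(0.01/3) and a lenient (0.005/2) parameterization as the two callers for
synthetic data. Every cell is then genotyped at every retained variant:
AF = alt count / depth, missing (not zero) where depth is 0. Filtering
drops variant columns with max AF < 5% or mean AF outside (0.1%, 30%),
then cells with < 3 informative variants, iterated to a fixpoint; the
bounds are configuration, not constants, because they are empirical
operating points. Clustering is complete-linkage on Euclidean distances
between AF vectors (the distance metric was an open choice; Euclidean
matches the default of the standard hierarchical-clustering routine and
is configurable), with missing AFs imputed as 0 for the distance
computation — at high mtDNA depth, absence of support is near-equivalent
to absence of the variant — and recorded in a missingness mask. Rows
are ordered by cell id before linkage so ties resolve deterministically;
the dendrogram exports to newick. Entries with AF ≥ 0.95 can be flagged
homoplasmic, letting the same machinery genotype cell-line identity.

## The synthetic-data generator

The generator produces data with the statistical structure the pipeline
assumes, so every stage is testable offline; it does not attempt
base-level realism.

**What it emulates.** Per cell: Poisson(`small_circle_rate`, default
700/cell, matching the reported per-cell median of ~700 circles) private
small circles with log-normal sizes (median 2 kb, σ 0.8, plus an
optional second mode at 20 kb with weight 0.15 capturing the observed
bimodal size distribution; a log-uniform option exists for controlled
recovery experiments); the cell's clone's multi-fragment ecDNA amplicons
with copy numbers drawn per cell (fixed, Poisson or log-normal); and one
mtDNA circle (default copy number 100). Digestion is modelled as
per-molecule retention probabilities (circular, linear): none (1, 1),
exo1d (0.90, 0.05), exo5d (0.85, 0.002), with PmeI + exo5d demoting
motif-carrying circles (GTTTAAAC; always present on the simulated chrM,
as mtDNA is a PmeI substrate) to linear retention. Only the relative
enrichment outcome matters downstream, so kinetics are not modelled; the
exo5d circular:linear ratio of 425 is of the order of the ~400-fold
mtDNA depletion the PmeI control exhibits. Coverage of a circle is
`circle_depth_per_copy` × copy number × retention with per-copy parity
to the linear genome at the defaults, so enrichment comes entirely from
digestion; fragments are uniform in circle coordinates, fragments
wrapping the origin become outward-facing pairs, reads crossing a
junction become SA-tagged split alignments with complementary soft
clips, and a minimum of 2 junction-spanning fragments per circle is
guaranteed (the caller's evidence model presumes detectable junctions).
Small circles within a cell are placed ≥ 1 kb apart by rejection
sampling — real small circles essentially never stack, and separation
keeps per-cell truth unambiguous. Expression is negative-binomial
(gamma–Poisson) with mean baseline_g × CN^coupling for amplicon genes;
background genes are placed clear of amplicon fragments so the
amplicon/background split of the dosage model is unambiguous. mtDNA
pileups draw alt counts Binomial(depth, clone heteroplasmy) over a
uniform error rate; SNP tables use BAF = (1 + CN)/(2 + CN) for the
mono-allelically amplified allele. A smooth Gaussian-bump signal track
with matching peak calls serves as a stand-in chromatin mark.

**What it does not emulate.** Sequencing error at base level, GC and
mappability biases, rolling-circle chimeras and branching artifacts,
doublets and ambient contamination, structurally rearranged amplicon
variants beyond the fragment list given, and real genome repeat
structure (genomes are i.i.d. random sequence; PmeI motifs occur
naturally roughly every 65 kb in addition to the planted chrM site).
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed read-evidence model, not robustness to
alignment artifacts in real libraries; the configurable `mismap_rate`
(default 0) is the only mapping-noise knob.

**Determinism.** Every generator op draws from
`default_rng([seed, op_code, cell_index])`, so outputs are
bit-reproducible for a fixed config seed, independent of call order, and
cells are independent work units.

## Problem sizes

The benchmarks run at desk scale by design: 1-Mb genomes, tens of cells,
~10 circles per cell for caller recovery; 24 cells across copy numbers
{2, 8, 32} for dosage; 1,000 window pairs for the microhomology oracle;
200 replicates × 1,000 permutations for randomization calibration; 100
cells for lineage recovery. These sizes make every property measurable
in seconds to a couple of minutes while keeping the estimated quantities
(rates, correlations, calibration curves) stable across seeds.

## Known limitations

The caller reports single-interval regions; reconstructing the
multi-fragment architecture of an amplicon from its junction graph is
out of scope (the reconstruction is an input). The enrichment model is
start-count Poisson and can in principle split a region at a long
zero-coverage gap inside a true circle (> `max_gap`). The recurrence
test's background definition makes chrM-bin positivity sensitive to a
dominant amplicon bin in the same cell. E < 1 microhomology significance
is permissive by construction (see above). The pipeline runs cells
serially; the per-cell independence contract makes parallel execution
safe but none is built in.
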