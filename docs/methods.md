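# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `methdesert`, in the order data flows through the package.

## Coordinate frame

All coordinates are 0-based half-open and serialize as BED.  The universal
frame is a `WindowGrid`: fixed-width windows (default 100 kb) tiled from
position 0 of each chromosome.  Trailing partial windows are dropped so
every window offers the same sampling opportunity — window methylation
levels are only comparable at equal width.  A window is flagged *excluded*
when ≥50 % of its bases fall in assembly gaps; windows with minor gap
overlap stay in the frame because the downstream minimum-event filter
already removes windows that cannot be sampled.  The 50 % rule is a design
choice: the alternative (shifting windows around gaps) would make the frame
assembly-dependent and window indices unstable.

Size-matched segment sampling (the permutation null) draws, for each
element, segments of identical length with uniform start on the same
chromosome; draws overlapping a gap are redrawn up to 100 times and flagged
if still gap-overlapping (relevant only for chromosomes that are nearly all
gap).

## Window methylome

A window's methylation level is Σ methylated events / Σ total events over
the per-CpG bisulfite observations falling in it.  Windows with fewer than
`min_events = 20` CpG sampling events are invalid; a deep-coverage variant
additionally requires ≥100 mapped reads and ≥100 events.  Input is per-CpG
aggregated counts, not reads: every statistic in the package depends only
on per-window event sums, and bisulfite read mapping is upstream of this
package's scope.

Replicate methylomes are averaged in level space (unweighted mean of the
two window levels, valid only where both are valid), not by pooling counts;
with two replicates of similar depth the two differ negligibly, and
level-space averaging keeps each donor's methylome equally weighted
regardless of coverage imbalance.

Methylation deserts at percentile *p* are the valid windows at or below the
k-th smallest level, k = max(1, ⌊p·n_valid⌋), ties included — so the desert
fraction can exceed *p* by the tied mass, and a fully tied methylome is
flagged degenerate.  Desert calls depend only on the ranking of levels and
are therefore invariant under monotone transforms.

Estimation accuracy per window uses the Clopper–Pearson exact binomial
interval (conservative and well-defined at the 0 and 1 boundaries; the
method choice is ours, as is the switch from relative to absolute
half-width at level 0 where relative error is undefined).  A window passes
at error bound ε and confidence γ when the interval half-width relative to
the point estimate is ≤ ε.

## Methylation index

Methylated cytosines deaminate to thymine; over evolutionary time a CpG
methylated in the germline accumulates C→T (or G→A on the minus strand)
polymorphism with the ancestral allele being the CpG base.  Such a SNP is
an *mSNP*: alleles {C,T} with ancestral C and the next base G, or alleles
{G,A} with ancestral G and the previous base C.  Unknown ancestral state or
missing flanking context never classifies as an mSNP.

Per window the raw index is r = N_mSNP / (N_CpG · N_SNP): the denominator
is proportional to the expected mSNP count under genome-uniform
methylation, so r is a relative methylation proxy.  The reported MI is r
rescaled so the mean over valid windows is exactly 1 — the index is only
defined up to scale, and fixing the genome-wide mean makes "MI = 0"
(no mSNP at all) and "MI > 0" strata, rankings, and fold comparisons
well-defined.  Windows without any SNP are invalid; a window with N_CpG = 0
gets MI 0 when it also has no mSNP and is flagged invalid otherwise (an
mSNP without a reference CpG is an annotation inconsistency).  CpGs are
counted as dinucleotides (once, not per strand) on the reference window
sequence; a CpG straddling a window boundary belongs to the window of its
cytosine.

## LCR detection

The genome is cut into consecutive 500 bp fragments and compared
all-against-all through a gapped-pattern k-mer index: a 21 bp pattern
sampling 13 positions (8 unsampled in the middle; the default layout
samples offsets 0–6 and 15–20 and is a config constant).  Gapped sampling
tolerates point mismatches; at identity *i* a placement survives with
probability i^13.  k-mers with an N at any sampled position (either strand)
are never hashed.

Before comparison, k-mers over-represented in high copy-number repeats
(HCRs: LINEs/SINEs/microsatellites, supplied as an annotation) are
blacklisted: every k-mer with HCR frequency > 10 is chi-square tested
(2×2: its HCR vs non-HCR counts against HCR vs non-HCR base totals),
Benjamini–Hochberg corrected at FDR 0.1, and excluded when significantly
enriched.  This lets the self-comparison see segmental duplications without
repeat-masking the genome.

Fragment pair scores are shared-k-mer counts; inverted matches are read
from forward-vs-reverse-complement code collisions and counted once per
shared placement.  k-mers occurring more than 100 times genome-wide are
skipped (no positional information; the blacklist should already cover
them).  Pairs scoring below `min_score = 10` shared k-mers are dropped —
the paper-gap default that separates genuine homology from background
collisions of a 13-letter code.

The reciprocal filter keeps a pair only if each fragment is in the other's
top-50 match list and neither list exceeds 1000 entries (tandem-repeat
hubs); ties at rank 50 break by score then partner coordinate.

Merging chains co-oriented matches that are near each other on side A
(< 1 kb) and on the same alignment diagonal.  Because fragment starts
quantize true positions to the 500 bp grid, one duplication populates up to
two adjacent diagonals; the diagonal tolerance is therefore the configured
radius (250 bp) widened by one fragment length.  Chaining is a union-find
over matches, so interleaved multi-partner families chain correctly.  A
merged block is kept when score density (total score / side-A block length)
exceeds 0.05.

Merged blocks are then *refined*: the two block sequences are globally
aligned (edlib Needleman–Wunsch; the extended CIGAR distinguishes matches
from mismatches) and the maximum-scoring sub-path — match +1,
mismatch/gap −2, found by a Kadane pass over CIGAR runs — defines the
member coordinates and the core identity.  The −2 penalty matters: optimal
unit-cost alignment of unrelated DNA still matches ~55–60 % of columns, so
a ±1 scoring would never trim the up-to-one-fragment of flanking unique
sequence that merging attaches to each block end; −2 trims anything below
~67 % local identity while keeping any plausible paralog core (≥85 %).
Identity is matches / alignment columns over that core.  We use edlib
(unit-cost NW) rather than an affine-gap aligner: it is exact, fast enough
for 50 kb members, and on substitution-dominated paralogy the two scoring
schemes give indistinguishable identities; alignment-path ambiguity
contributes ≲0.2 percentage points.

Clustering into paralog families is single-linkage over two criteria:
k-mer content similarity 1 − (|symmetric difference| + ln(1 + size
difference)) / |intersection| ≥ 0.5 (the threshold is a package default;
an empty intersection never clusters), or any positional overlap between
members of different pairs.  "Pair size" is the total bases of the pair's
two members.  After clustering, members shorter than 1 kb or below 90 %
identity to their matched paralog are removed.

DP-LCR regions — the NAHR substrate — are the gaps between same-cluster
matched pairs that are directly oriented, intrachromosomal, each member
≥10 kb, identity ≥95 %, gap in (0, 10 Mb); overlapping regions are merged.

The pipeline's contract is correctness on synthetic genomes up to ~50 Mb
(a 20 Mb genome takes well under a minute on one CPU); it does not attempt
the parallel scheduling needed for a 3 Gb assembly.

## NAHR signature

Each CNV is classified against the flattened LCR architecture with a fixed
precedence: overlapping members of ≥2 different clusters → *complex*;
overlapping exactly one cluster's members → *lcr_overlapping*; lying
strictly inside the gap between its two nearest flanking LCRs →
*whole* vs *scattered* (covering ≥40 % vs <40 % of the inter-LCR distance,
measured between the inner LCR edges) crossed with *paralogous* vs
*non-paralogous* (flanks in the same vs different clusters); otherwise
*unassociated*.  The 40 % cutoff is the one stated operational threshold
for the whole-region signature; the precedence order is fixed because a
CNV can geometrically satisfy several patterns.

The NAHR contingency is the 2×2 table {paralogous, non-paralogous flanks} ×
{whole, scattered}, tested by Pearson chi-square without continuity
correction; the fold is the odds ratio.  The fraction of CNVs attributable
to NAHR is reported both over all CNVs and over LCR-associated CNVs, since
either denominator is defensible.

## Structural heterozygosity

Under the infinite-allele model at drift–mutation equilibrium the ratio of
heterozygosity rates of two neutral loci equals the ratio of their mutation
rates, so per-locus 2pq ranks loci by structural mutability.  Any aberrant
copy-number signal (gain or loss) marks presence of a minor structural
allele; q is its carrier frequency.  Loci are defined by merging
overlapping calls across samples (merge gap 0 — strict overlap).

Trio correction gives each pedigree family one vote: the numerator counts
families with ≥1 carrier and the denominator is the family-collapsed cohort
size, identical at every locus.  This reproduces the intended counting
(a parent–child transmitted variant among 10 samples gives q = 1/9) and
has the property that duplicating a child's inherited calls changes no
locus's heterozygosity — the defining requirement of the correction.  A
variant collapsing only at shared-variant loci would shift the denominator
locus by locus and break that invariance.  Verbose mode also emits the
uncorrected per-sample variant.

Desert stratification assigns a locus to the desert stratum when any window
it overlaps is a desert, and compares strata by means, SDs, and a
two-sample KS test.

## Association statistics

*KS association*: two-sample KS of methylation levels, element-bearing
valid windows vs the rest, with the lower-median group reported as the
direction.  The exact small-sample null is used below a combined n of 50,
the asymptotic law above (at the package's typical group sizes the
asymptotic rejection rate is within Monte-Carlo error of nominal).

*Permutation association*: each element is scored as the event-weighted
mean level of the valid windows it overlaps (elements overlapping only
invalid windows are excluded and counted), and compared by KS against the
scores of 100 size-matched random segments per element.  D_max then has the
interpretation of the excess fraction of elements associated with the
lower tail.

*Distance decay*: flanks of a given size placed at increasing distances
outward of each element edge (clipped at chromosome ends, empty flanks
dropped), scored as above, and KS-compared per distance against flanks of
size-matched random segments drawn once per call.

*Enrichment fold*: (fraction of elements whose windows intersect a
stratum) / (fraction of valid windows in the stratum), with a 2×2
chi-square p (exact binomial fallback when an expected cell is 0).  The
case-control variant contrasts two element sets directly (Fisher fallback
at degenerate margins).

*Relative / attributable risk* over window groups: with a = element
windows, e = exposure windows (deserts or DP-LCR windows), RR =
P(a|e)/P(a|¬e) and AR = [P(a) − P(a|¬e)]/P(a), the population attributable
fraction.  The excess-risk difference P(a|e) − P(a|¬e) is emitted in the
extras since attributable-risk conventions vary.  RR is flagged infinite
when P(a|¬e) = 0.

*Feature permutation*: observed feature–stratum overlap count against
length-matched uniform replacements, n_perm replicates; p uses the add-one
estimator (1 + #{null ≥ obs})/(n_perm + 1) and is never 0.

All resampling is seeded and the seed is recorded in every result object.

## Synthetic data

The generator emulates the statistical structure the analyses assume, with
defaults chosen as the package's canonical study conditions:

- **Genome**: i.i.d. bases at GC 0.41 (human-like); no repeat landscape, no
  isochores.  Duplications copy a source segment, substitute each base with
  probability 1 − identity (uniformly to another base), reverse-complement
  if inverted, and insert after the configured separation; placement is
  rejection-sampled with a 1 kb margin between planted segments.
- **Methylome**: background window levels Beta(6, 2) (mean 0.75, matching
  the high-methylation mode of sperm); deserts at level 0.03; per CpG,
  events ~ Poisson scaled so a window averages `mean_events_per_window`
  (default 787, the realism guide for low-coverage sperm bisulfite data)
  and methylated events ~ Binomial at the window's true level.
- **SNPs**: each CpG becomes an mSNP with probability slope × window
  methylation (strand uniform); background SNPs on non-CpG bases with
  ancestral = reference, so they can never classify as mSNPs.
- **Elements**: placed inside a uniformly chosen desert window with
  probability π = F·f/(1 − f + F·f) (F the configured fold, f the desert
  window fraction), else inside a uniform non-desert window.  π makes the
  desert *odds* enrichment equal F; the ratio-of-proportions fold measured
  downstream is F/(1 − f + F·f), slightly below F (9.17 for F = 10 at
  f = 0.01).
- **CNV cohort**: per locus, each unrelated sample (and each trio parent)
  carries the variant with planted q; children inherit each parental
  variant with probability 1/2 (no de novo events).  A configured fraction
  of loci are NAHR-type: intervals covering 60–95 % of a DP-LCR region and
  strictly inside it.  Diploid genotypes are not modeled — variant
  presence/absence mirrors the allele-frequency treatment of aCGH data.

What passing tests on this generator do **not** show: robustness to real
repeat landscapes (the blacklist is exercised on planted high-copy tracts,
not a RepeatMasker annotation), to mappability-driven coverage bias, to
indel-diverged paralogs (identity handles them; the simulator plants only
substitutions), or to population structure in the cohort.

## Numerical choices and degenerate inputs

- Clopper–Pearson at k = 0 / k = n uses the exact 0 and 1 bounds.
- Desert percentile over an all-tied methylome returns everything, flagged.
- `compute_identity` returns 0 with a degenerate flag at length ratio > 5.
- Chi-square tests are Pearson without continuity correction throughout;
  zero expected cells fall back to exact tests and are flagged.
- Permutation p-values use the add-one estimator; minimum 1/(n_perm + 1).
- All orderings (windows, matches, clusters, regions) are deterministic:
  identical inputs and seeds give byte-identical outputs.

## Benchmark problem sizes

The validation suite runs, as its canonical conditions: a 20 Mb genome with
12 qualifying direct duplication pairs (10–50 kb, identity 0.95–0.99,
separation 0.1–8 Mb log-uniform, clipped to the hosting chromosome), 6
inverted and 6 sub-threshold pairs; a 20-pair genome for the identity
estimator; 2000-window methylomes at ~250 events/window for desert
recovery and statistical calibration (200 null replicates per test, 50
replicates for fold recovery); a 10 Mb genome for MI recovery; and a
200-sample cohort over 100 loci for heterozygosity.  These sizes make the
whole validation reproducible in minutes on a single CPU while keeping
every Monte-Carlo tolerance meaningful.
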