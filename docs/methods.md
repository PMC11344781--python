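# Methods

`exorigin` reconstructs the sequence architecture of budding-yeast replication
origins from ChIP-Exo-style data: stranded counts of read 5' ends, whose
forward- and reverse-strand pileups mark the two lambda-exonuclease stop
positions flanking a protein-protected stretch of DNA.  The package analyses
where the origin recognition complex (ORC) and the MCM2-7 double hexamer (DH)
sit relative to the origin's sequence elements — the A-element (ARS consensus
sequence, ACS) and the B2-element — and how element spacing, DNA shape and
deformability relate to origin licensing.

## Coordinate model and conventions

All coordinates are 0-based half-open (BED-native); GFF3 is converted on read.
A read contributes one tag at its 5' end: `start` on the forward strand,
`end - 1` on the reverse strand.  Element distances are anchor-to-anchor — the
conserved central adenine of the ACS to the conserved thymidine of B2 — in
*origin-local orientation* (downstream positive along the A-element strand).

A footprint call consists of the modal forward-strand position (left boundary
`L`), the modal reverse-strand position (right boundary `R`), inclusive width
`R - L + 1`, and centre `floor((L + R)/2)`.  The downstream footprint edge is
`centre + floor(width/2)`.  These conventions are mutually consistent: a 64 bp
DH whose centre is 51 bp from a B2 anchor has its edge 19 bp from the anchor
(51 − 32 = 19), which the acceptance suite asserts exactly.

## Footprint estimation

Composite profiles aggregate tags on a ±W offset axis around aligned anchors;
'−'-strand anchors are flipped (offsets negated, strands swapped) so all
origins share one orientation.  Boundaries are the argmax of each smoothed
strand vector.  Smoothing uses a symmetric sliding window with fractional
half-width: width 2.5 gives kernel (0.25, 1, 1, 1, 0.25)/3.5 over offsets
−2..+2, which never moves a peak.  Because the kernel top is flat, an isolated
spike smooths to a 3-bin plateau; argmax ties are therefore broken by the raw
(unsmoothed) boundary height, then by proximity to the anchor.  Per-site calls
use the same estimator inside a ±100 bp window (wide enough for every planted
footprint boundary, narrow enough to exclude secondary DH peaks of multi-peak
origins) and require ≥10 tags per strand; failures are `NoCall` values, never
exceptions, so genome-wide sweeps never abort.

Origins are classed `single` / `dominant` / `multi` from a midpoint-density
score that pairs forward signal half a footprint upstream with reverse signal
half a footprint downstream (geometric mean of the smoothed strand tracks,
smoothing width 15 bp).  Local maxima above a noise floor — max(3× the
regional median, 10% of the primary peak) — and separated by ≥40 bp are
peaks; `multi` requires a secondary peak at ≥0.5× the primary (`r_multi`).
These thresholds are configuration parameters; the defaults reproduce the
planted-class recovery suite and no published numeric rule exists for them.

Occupancy is the tag count in a 100 bp window around the binding centre,
scaled per million library tags.  The 60 vs 800 bp localisation ratio counts
tag 5' ends.  Note a representation caveat: with boundary tags, the two
pileups of a 64 bp footprint fall just *outside* a 60 bp window around the
footprint centre, so this statistic is substantially lower than the
read-depth (coverage) version of the same ratio computed on full-length
reads — the two are not comparable numerically.

## Occupancy classes, phase changes, tests

C1–C4 are contiguous quartile blocks of origins sorted by descending G2-phase
ORC occupancy, sizes differing by at most one with extra members in earlier
blocks (323 origins → 81/81/81/80); M1–M5 are the analogous MCM quintiles.
Ties break by origin id, making the assignment a deterministic function of
the occupancy multiset.  Phase changes are reported per class as
`100·(mean_b − mean_a)/mean_a` of library-normalised occupancies (mean by
default; median available).  Paired comparisons use the two-sided Wilcoxon
signed-rank test (exact null for n ≤ 25, normal approximation with continuity
correction above, zero differences dropped; scipy backend) with a Student's t
companion.

Non-origin ORC sites are found by a 200 bp sliding window (step 50) outside
every origin ±1 kb: G1 count ≥ 5× the unmasked-genome background per window
and depth-normalised G2 count ≤ 0.5× the G1 count.  Overlapping windows merge;
each site gets a tag-centroid centre, a footprint call, and the signed
gene-local distance to its nearest TSS (upstream negative).  The enrichment
thresholds are configuration defaults — the original analysis delegated event
calling to a mixture model and printed no equivalent numbers.

## Motifs

PWMs carry a background, a pseudocount, and an anchor column (defaults: the
most A-informative column for the ACS, the most T-informative for B2,
overridable in the MEME-minimal motif file via a `# ANCHOR` line).  Scores are
log2 odds with pseudocount-regularised probabilities.  Score p-values come
from the exact distribution of a background word's score, computed by dynamic
programming over per-column score atoms; the atom set is exact up to 300 000
distinct scores and is rebinned onto a grid of `resolution` bins per column
beyond that, so for ordinary motif widths the p-values are exact (the test
suite checks equality with exhaustive enumeration).  Scanning covers both
strands; '−'-strand hits are scored against the reverse-complemented matrix,
giving an exactly mirror-symmetric hit set under reverse complementation of
the input.

B2 discovery is a ZOOPS (zero-or-one occurrence per sequence) EM: each window
holds a motif occurrence at a uniform prior position with probability γ, or
is background.  The observed-data log-likelihood is asserted non-decreasing
every iteration; a pseudocount floor prevents degenerate columns.  B2
assignment scans the 150 bp anchor-to-anchor window downstream of the
A-element in origin-local orientation at p ≤ 1e-4 (a conventional scanning
stringency, configurable); a hit is orientation-`correct` when it lies on the
strand opposite the A-element, the geometry of head-to-head DH formation.

## Spacing periodicity

A–B2 anchor distances are histogrammed at 1 bp over 41–141 bp and smoothed
(width 2.5).  Extrema are plateau-aware local maxima/minima (a flat run
reports its centre).  The dominant period is the lag (8–20 bp) maximising the
autocorrelation of the mean-subtracted smoothed histogram; significance comes
from shuffling histogram bins (1 000 permutations, α = 0.05), and a
non-significant maximum is reported as "no periodicity".  Origins are
labelled peak/valley by their nearest extremum, and the share of summed MCM
occupancy carried by peak-labelled origins summarises the coupling between
spacing and licensing.

## DNA shape

Shape features are looked up per position from a pentamer table: per-bp
features (minor groove width, propeller twist, electrostatic potential proxy)
for the centred pentamer, step features (roll, helical twist) assigned to the
step's left bp; the 2 bp margins are undefined.  The original analysis
extracted precomputed genome tracks; computing from sequence lets synthetic
genomes work, and a real pentamer table can be supplied to match database
values.  Element-aligned signatures are per-offset medians over ±30 bp
windows with a seeded percentile-bootstrap 95% CI over sequences (1 000
replicates by default; the CI construction is a package choice).  Profile
comparison finds the integer shift minimising the mean squared difference
over the overlap.

## Deformation energy

The energy to morph a sequence onto a protein-bound target conformation uses
a multivariate Ising-type model: per dinucleotide step and substate, a
harmonic term `½ (x − x0)ᵀ K (x − x0) + offset` in the target's helical
coordinates (inter-base-pair parameters, optionally augmented with the
flanking base pairs' intra-base-pair parameters), plus nearest-neighbour
substate couplings.  The minimum over substate assignments is found exactly
by transfer-matrix dynamic programming (verified against brute force).
Energies are kcal/mol; coordinates deg/Å.  The numeric parameter set of the
published model and the structure-derived target table are external inputs
the package consumes as JSON/TSV; tests and the demo use a seeded synthetic
model (`generate_deformation_model`, labelled synthetic), so demo energies
are internally comparable but not on the published scale.  Per-position
energy decompositions are approximate by construction: coupling terms belong
to step pairs, not single steps.

## Synthetic data: what it emulates and what it does not

The generator plants, per origin: an ACS sample on a random strand; with
probability 0.727 a B2 sample at an anchor distance drawn from the comb
{42: 0.10, 54: 0.20, 66: 0.40, 78: 0.20, 90: 0.10} (reverse-complemented
relative to the A-element with probability 0.808, plus 1–3 extra B2 copies at
12 bp intervals with probability 0.370); an AT-skewed inter-element stretch
(skew 0.3 on the A-element strand); ORC footprints of 53 bp (G2/S, centre
+10) and 79 bp (G1, centre +20); and a 64 bp DH centred 51 bp upstream of the
B2 anchor with 6 bp Gaussian placement jitter, displaced outside the ORC
footprint with probability 0.07.  Peak classes are drawn at the observed
rates (0.415/0.255/0.33) by planting secondary DHs 120 bp downstream at 0.3
(dominant) or 0.8–1.0 (multi) relative weight.  ORC occupancy redistributes
G2→G1 by quartile factors 0.52/0.83/1.62/3.31 and MCM loading scales
1/0.67/0.54/0.54, matching the reported percentage changes.  G1-only
non-origin ORC sites (53 bp footprints) are planted upstream of gene TSSs at
|N(0, 180 bp)| distances.  Tag tracks place forward 5' ends at
round(N(L, σ)) and reverse ends at round(N(R, σ)) with σ = 2 bp, multinomial
site totals, and a 10% uniform noise floor — a realism choice; the exact
total equals the requested depth.

Deliberately not simulated: nucleosomes and chromatin context, replication
timing, sequencing error, read-length/coverage structure (tags are points,
not reads), PCR duplicates, and mappability.  Passing tests therefore show
that the estimators recover a planted architecture under boundary-jitter and
uniform-noise conditions — not that they are robust to every artefact of real
sequencing data.

The shipped ACS (17 columns) and B2 (13 columns) matrices are synthetic
stand-ins patterned on the elements' published character (T-rich ACS with a
conserved central adenine; an inverted-ACS-like, largely C-free B2 with a
conserved thymidine).  Their sharpness was set, before the statistical suite
was frozen, so that PWM-sampled words are recoverable by scanning (≥95% of
planted anchors at p ≤ 1e-3), which real position-specific scoring of these
elements supports; weaker matrices would make planted-truth recovery
ill-posed rather than hard.

## Problem sizes and defaults

The demo and acceptance runs use 200 origins on two ~400 kb chromosomes,
150 000 tags per protein/phase, 1 000 spectrum permutations, 500 random
deformation baselines, and 200-replicate bootstrap CIs — sizes at which every
statistic is stable and a full run takes well under a minute on one core.
All randomness flows from a single integer seed; rerunning a config is
byte-identical.

## Known limitations

- Multi-peak origins can contaminate per-site boundary modes when a secondary
  DH's boundary falls inside the call window; the composite estimates and the
  planted-truth medians are unaffected, but per-origin DH/ORC overlap is a
  few percent below the planted rate on multi-heavy worlds.
- The localisation ratio on boundary tags is not numerically comparable to a
  read-depth version (see above).
- With a synthetic deformation model, element energies have no reason to be
  ordered A < B2 < random; reproducing published energy values requires the
  external parameter set and target conformation.
- EM refinement is single-motif ZOOPS; OOPS/ANR modes and motif E-values are
  out of scope.
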