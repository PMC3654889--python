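# Methods

This note documents the models and procedures implemented in `seqppi`,
the conventions chosen where the underlying definitions admit more than
one reading, and what the synthetic benchmark does and does not show.

## Sequence descriptors

All encoders operate on sequences over the 20 standard amino-acid
letters. Non-standard residues are a parsing-policy question (rejected
with a warning by default; optionally U→C, B→D, Z→E with X-containing
records dropped) because the descriptor tables define only 20 letters
and silent guessing would corrupt the features.

**Physicochemical table.** Six residue properties (hydrophobicity,
side-chain volume, polarity, polarizability, solvent-accessible surface
area, net charge index of side chains) ship as packaged TSV data. For
the autocovariance encoders each column is standardized to mean 0 and
SD 1 over the 20 amino acids; the SD is the population SD (ddof = 0),
an arbitrary but fixed choice since only the relative scale matters.

**Auto covariance (AC).** For property *j* and lag *d* ∈ 1..lg
(default lg = 30):

    AC(d, j) = Σ_{i=1}^{L−d} (P_{i,j} − P̄_j)(P_{i+d,j} − P̄_j) / (L − d)

with P̄_j the sequence mean of the property profile. Output ordering is
property-major (all lags of property 1, then property 2, …), 180 values
per protein. Requires L > lg.

**Moran autocorrelation (MAC).** Same centered lag products, but
normalized by the overall population variance of the profile:

    MAC(d, j) = [Σ (P_{i,j} − P̄_j)(P_{i+d,j} − P̄_j) / (L − d)] / [Σ (P_{i,j} − P̄_j)² / L]

for d ∈ 1..dmax (default 30), 180 values per protein. A constant
profile makes the ratio 0/0; the implementation detects exactly
constant profiles (min = max) and returns 0, the limit of a vanishing
signal, and the same detection zeroes AC's deviations so homopolymer
AC/MAC vectors are exactly zero rather than floating-point dust.

**Conjoint triads (CT).** The 20 letters are collapsed to 7 classes by
dipole and side-chain volume ({A,G,V}, {C}, {D,E}, {F,I,L,P},
{H,N,Q,W}, {K,R}, {M,S,T,Y}); each of the L−2 windows of three
consecutive residues is a triad, giving a 7³ = 343-bin histogram.
Counts are divided by L−2 by default so sequences of different length
are comparable (entries then sum to 1); raw counts are available via
`ct_relative=False`.

**Local descriptors (LD).** Ten overlapping regions are cut from the
sequence (1-based inclusive positions, length L): the four quarters
A–D with boundaries at ⌊L/4⌋, ⌊L/2⌋, ⌊3L/4⌋ (so A–D partition the
sequence exactly); the halves E, F; the central 50 %
G = ⌊L/4⌋+1 .. ⌊L/4⌋+⌈L/2⌉; the first 75 % H = 1 .. ⌈3L/4⌉; the final
75 % I; and the central 75 % J = ⌊L/8⌋+1 .. ⌊L/8⌋+⌈3L/4⌉. The
floor/ceil conventions are one consistent reading of "quarters /
halves / 75 % regions"; they are fixed and documented because
reproducibility requires a single rule. Each region yields 63 CTD
values: 7 composition percentages; 21 transition percentages, one per
unordered pair of distinct groups, counting adjacent positions where
the two groups neighbour in either order, over len−1 adjacencies; and
35 distribution values — per group, the sequence positions (as % of
region length) of its first occurrence and of occurrences number
⌈0.25·n_g⌉, ⌈0.5·n_g⌉, ⌈0.75·n_g⌉ and n_g. Groups absent from a region
contribute five zeros. 630 values per protein; requires L ≥ 4.

**Pair assembly.** Per-protein blocks are interleaved as AC_A, AC_B,
CT_A, CT_B, LD_A, LD_B, MAC_A, MAC_B — per-descriptor concatenation of
the two proteins, with the inter-block order fixed by the package —
for 2×(180+343+630+180) = 2666 features per pair. Pair rows are
ordered; deduplicating (A,B)/(B,A) is the caller's concern.

## Preprocessing and dimension reduction

Features are affinely mapped per column so the training minimum/maximum
land on −1/+1. Constant training columns map to 0, and unseen data
falling outside the training range is clipped to [−1, 1] to keep the
classifier input domain bounded. Rescaling precedes PCA; the reverse
order is also defensible but one order had to be fixed, and scaling
first prevents high-variance raw features (AC blocks) from dominating
the projection purely by units.

PCA is fitted on training data only — fitting on all data before
splitting would leak test information into the projection. The
default keeps the smallest number of leading components reaching 95 %
cumulative explained variance (a standard operating point; an explicit
component count is also accepted). Eigenvalues use the 1/(N−1)
covariance; components are computed by SVD (numerically equivalent to
a symmetric eigensolver on the covariance, and cross-checked against
one in the tests) with each component's sign fixed so its
largest-magnitude loading is positive.

## Extreme learning machine and ensemble

A single hidden layer of L neurons with sigmoid activation; hidden
weights and biases are drawn uniform on [−1, 1] (the canonical ELM
convention) and never trained. Each neuron's weights and bias are one
row of a single (L, n+1) draw, so for a fixed seed the first L′
neurons of a larger network coincide with the L′-neuron network; this
makes training error provably non-increasing in L for a fixed seed,
which the tests exploit. Targets are one-hot (one column per class);
output weights are β̂ = H⁺T computed by SVD with singular values below
1e−8·σ_max truncated — the minimum-norm least-squares solution.
Prediction takes the argmax score, ties toward the lower class index.

The ensemble trains `n_members` (default 15, kept odd so binary votes
cannot tie) ELMs with identical L on identical data; member seeds
derive from the master seed by a fixed odd-stride counter, so runs
reproduce end to end. Votes are hard labels, majority wins.

The hidden-layer size is the one hyperparameter that matters.
`select_hidden_count` picks it by mean stratified-CV accuracy of a
single ELM over a grid (default 20–300 in steps of 10, ties toward the
smaller size; single-ELM search is an order of magnitude cheaper than
ensemble search and lands in the same region). The package default is
L = 200: on the synthetic benchmark the selection procedure
consistently chooses sizes around 180–220 and the accuracy curve is
flat near its peak there. `cross_validate` uses the configured fixed
size rather than re-running the grid inside every fold, keeping the
protocol's cost linear in the grid only when selection is explicitly
requested.

## Evaluation protocol

Stratified 5-fold cross-validation (per-fold class proportions within
one sample of global). Per fold, scaler, PCA and ensemble are fitted
on the four training folds only. Metrics: accuracy, sensitivity
TP/(TP+FN), precision TP/(TP+FP), and Matthews correlation coefficient
(TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). A metric whose
denominator vanishes (e.g. MCC under all-positive predictions) is
reported as undefined rather than coerced to 0, because a silent zero
misreports a degenerate prediction as an anticorrelated one. The
report lists per-fold rows plus mean and sample SD (ddof = 1; with 5
folds the estimator choice moves the SD by ~12 %, and the sample form
is the conventional default).

## Synthetic benchmark

The generator emulates a curated benchmark's shape — a balanced set of
positive and negative pairs over a proteome — with i.i.d. background
sequences (uniform over the 20 letters by default, configurable
frequencies) of uniform random length, default range 50–400 residues
respecting the 50-residue floor used when assembling real datasets.

The interaction signal is planted as charge-complementary motif pairs:
a pool of `n_motif_pairs` (default 3) pairs (α, β) with α a D/E patch
and β a K/R patch of `motif_length` (default 6) residues. With
probability `p_signal` a positive pair has α written into a random
window of protein A and β into protein B; negatives are never touched.
Charged low-complexity patches mirror real electrostatic interface
elements (E/K coiled coils, acidic activation domains, basic NLS-like
patches) and — critically — are distinctive in the reduced 7-group
alphabet, so the conjoint-triad and local-descriptor blocks can see
them. Motifs of uniformly random composition would produce triads
indistinguishable from background and an essentially unlearnable
benchmark, defeating the generator's purpose. Every pair uses its own
two proteins, so implants never leak across pairs, and implants are
verifiable by substring search.

What passing on this benchmark shows: the full pipeline recovers a
planted, representable signal (mean CV accuracy ≈ 0.95 at 500+500
pairs, full signal, lengths 50–150), behaves at chance on label-
shuffled data, and degrades monotonically as `p_signal` drops. What it
does not show: performance on real interactomes, where the signal is
weaker, heterogeneous, homology-structured and confounded with
composition biases — none of which the i.i.d. generator models.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the full protocol at
500+500 pairs (and 200+200 for the signal-probability sweep), sizes at
which the benchmark's behaviour is stable while a complete run stays in
the minutes range on a single core. Tolerances: standardization and CT
sums are checked to 1e−10/1e−12; PCA orthonormality and variance
conservation to 1e−8; exact-interpolation residuals to 1e−6. Degenerate
inputs are errors, not silent results: empty FASTA records, unresolved
pair ids, non-binary labels, sequences shorter than an encoder's
minimum (L > lg for AC, L > dmax for MAC, L ≥ 3 for CT, L ≥ 4 for LD),
all-identical PCA rows, even ensemble sizes, and infeasible
stratifications all raise with a message naming the offender.

## Known limitations

* Sequence-identity redundancy filtering (the 40 % identity criterion
  used when assembling real benchmarks) is out of scope; only the
  length floor is provided as a dataset utility.
* The ELM pseudoinverse is dense; problems far beyond ~10⁴ training
  pairs × 300 hidden units would want a blocked or regularized solver.
* PCA is batch-only (no incremental fitting) and the projection is
  refitted per CV fold by design.
* Undefined metrics propagate as missing values into fold aggregation;
  a report with a degenerate fold shows NaN rather than a number.
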