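# Methods

This note documents the models, conventions and numerical choices behind
`ribonet`, and what its synthetic benchmarks do and do not demonstrate.

## Genotypes and conventions

A genotype is a fixed-length RNA string over {A, C, G, U}; the default
length is 35 (the catalytic core of the ligase ribozyme under study).
Positions are 1-based within the core; an offset of +44 converts to
absolute coordinates in the full ribozyme where needed. Variant names use
`posBASE` tokens joined by `/` (`7G/8C/19U`), with `WT` for the empty set.

A combinatorial library over N chosen loci is projected onto bitvectors:
wild allele = 0, mutant allele = 1, and **locus 0 (the lowest core
position) is the least significant bit**. The integer value of the
bitvector is the genotype's index in every vector quantity ("binary
order"). This single convention fixes the ordering of the Walsh–Hadamard
transform; the alternative (wild = 1) changes the sign pattern of
odd-order background-averaged terms but none of the package's conclusions.

Mutant enumeration is position-major with bases in alphabetical order, so
outputs are reproducible without sorting: 3L single mutants (105 at
L = 35) and 9·C(L,2) double mutants (5355).

## Activity quantification

Reads are assigned to the ligated or unligated pool by an exact barcode
match at the start of the read; the variable core is excised between exact
flank matches and rejected if any base call beyond an allowance of
`max_low_quality_bases` (0, or 1 for the deeply mutated libraries) falls
below Phred 20. Variants are discarded when either replicate's total count
is below `min_total_reads` (30 for the distant-anchor library, 100
otherwise). FL = N_lig/(N_lig+N_unlig); RA = FL/FL_WT, uncapped. The
duplicate RA values are summarized by their mean and population standard
deviation (divisor n; with n = 2 the choice of divisor only rescales).
Neutrality is RA ≥ 0.2, inclusive.

Barcode and flank matching tolerate no mismatches: the simulators honor
exactness, and real-data preprocessing beyond this (adapter trimming,
index handling) is out of scope.

## Genetic operators

Tournament selection samples `tournament_size` contestants without
replacement, keeps the highest-RA contestant (ties broken uniformly), and
returns the losers; chosen parents are not re-selected. One-point
crossover cuts uniformly in 1..L−1 (end cuts excluded so both children are
true recombinants) and returns one child by a fair coin flip. The mutation
operator substitutes each position independently with probability 1/35 to
a uniform alternative base — one substitution per call in expectation —
and may return the input unchanged; novelty against previously assayed
genotypes is enforced by the generation designers (rejection with a cap of
100 attempts per requested offspring), not by the operator.

Two designers correspond to the two algorithm phases: the first mutates
every recombinant immediately after crossover; the second emits pure
recombinants plus a smaller set of point mutants drawn from parents and
recombinants, which empirically preserves activity far better. Control
genotypes (e.g. the wild type, carried in every generation as the RA
reference) overwrite random slots after deduplication and may duplicate
history by design.

## Neutrality classifiers

Sequences are one-hot encoded position-major (4·L columns; 1×140 for the
35-nt core). Five families are supported through a single sklearn-style
estimator, with hyperparameters pinned so results do not drift across
library versions: L2 logistic regression (C = 1), linear-kernel SVM
(C = 1), k-NN (k = 5), gradient-boosted trees (depth 10, 100 trees), and
an MLP with 128/64/32 ReLU layers trained by Adam (learning rate 0.005,
batch 1024, 100 epochs, log loss). The MLP is scikit-learn's
implementation; it follows the reference architecture's layer sizes and
optimizer but has no batch-normalization or dropout layers — acceptable
here because the package's benchmarks use it as one family among five,
not as a tuned production model.

Class imbalance is handled only by threshold tuning, never reweighting:
`fit` carves 10% out of the training data (stratified), fits on the
remainder, and sets the decision threshold to the ROC point maximizing the
geometric mean √(TPR·(1−FPR)), ties resolving to the lowest threshold. If
the carve-out is too small to contain both classes the threshold stays at
0.5. Evaluation reports precision, recall, accuracy, F1 and the null
accuracy (majority-class fraction); undefined metrics are NaN with a
degenerate flag rather than silently zero.

## Classifier-guided evolution

The guided loop replaces measured RA with predicted neutrality: within a
tournament, a uniform pick among the predicted-neutral contestants wins
(or among all contestants if none is predicted neutral). Each round
generates offspring — `recombinant_fraction` (default 0.8) by crossover of
two selected parents, the rest by point mutation of a parent — classifies
them, and keeps the predicted-neutral ones as the next population; the
final round generates `final_population` candidates and returns only the
predicted-neutral ones. Intermediate-round filtering can be deferred to
the final round by a flag.

Two design choices matter for the loop's dynamics:

- **Novelty** is enforced against the loop's own running history (not the
  experimental history), making the search self-avoiding. On a narrow
  neutral ridge this acts as a ratchet: consumed genotypes cannot be
  revisited, so new neutral offspring necessarily appear farther out.
- **Elitism** (`keep_parents`, off by default) carries the selected
  parents into the next round's population. Without it, a round in which
  no novel offspring is predicted neutral extinguishes the population;
  with it, lean rounds merely pause the advance. The ridge-crossing
  benchmarks enable it.

The loop reports the mean Hamming distance from a reference per round, the
predicted-neutral fraction of each round's offspring, and an extinction
round if the population dies out.

## Epistasis mathematics

**Log-additive model.** The expected ln(RA) of a multi-mutant is the sum
of its constituent single mutants' ln(RA); a perfect fit (R² = 1, computed
as scikit-learn's coefficient of determination) means no epistasis.
Truncating the WT-relative Walsh–Hadamard basis at order 1 reproduces this
model exactly inside the combinatorial subspace — the two formulations
coincide, and a test asserts it numerically.

**Directional epistasis.** The neutral fraction at Hamming distance n from
a reference is fitted to ω(n) = e^(−α·n^β) by nonlinear least squares
(initial values α = 0.5, β = 1.0, positivity bounds; distance classes
n = 1..3 by default, matching single/double/triple mutant data). α is the
robustness decay; β > 1 indicates excess negative epistasis, β < 1 excess
positive, β = 1 balance or none. When per-point uncertainties are
supplied, they are used as absolute weights so the reported standard
errors are calibrated — the simulation benchmarks pass binomial standard
errors.

**Reciprocal sign epistasis.** For every unordered pair of genotypes two
substitutions apart whose two single-mutant intermediates are both
assayed, the pair exhibits reciprocal sign epistasis when both endpoints
strictly exceed, or both strictly trail, both intermediates; the call is
independent of which endpoint is the reference. Pairs are binned by the
closer endpoint's distance to the wild type. On a complete biallelic
landscape every hypercube square contributes its two diagonals, giving
2^N·C(N,2)/2 pairs (3,932,160 at N = 16); a vectorized census handles the
complete case, a quadratic scan the sparse case, and the two agree exactly
on random landscapes at N ≤ 8. Additivity precludes reciprocal sign
epistasis, which the additive-landscape check confirms.

**Walsh–Hadamard decomposition.** With w the ln(RA) vector in binary
order, `e_rel = G·w` gives epistatic terms relative to the all-wild
reference and `e_avg = V·H·w` gives background-averaged terms, where G, H
and V follow 2×2 block recursions (G₁ = [[1,0],[−1,1]], H₁ = Hadamard,
V₁ = diag(½,−1)) and a term's interaction order is the popcount of its
index (C(N,k) terms of order k). Because all three matrices are Kronecker
powers of their 2×2 base, the transforms are computed by in-place
butterflies over each bit level in O(N·2^N) without materializing any
matrix; dense matrices (capped at N = 12) exist purely as a brute-force
test oracle. Inverses: G⁻¹ shares G's structure with the sign flipped,
H⁻¹ = H/2^N, V is diagonal. Truncated reconstruction zeroes all
coefficients above a chosen order and applies the inverse; R² against the
observed vector, together with the cumulative term fraction
Σ_{j≤k} C(N,j)/2^N (0.2% at N = 16, k = 2), quantifies how much of the
landscape low-order interactions explain. An option restricts the R² to
variants whose distance exceeds the truncation order, as a robustness
check.

RA values are clamped below at ε = 10⁻³ before logarithms (configurable):
exact zeros are artifacts of finite sequencing depth, and the clamp keeps
log-space vectors finite without materially moving sub-threshold variants.

## Neutral paths

A direct path between the all-wild and all-mutant anchors is a permutation
of the N loci; its chain visits N+1 genotypes. Path neutrality at
threshold t is judged on the N−1 strict intermediates (the anchors are the
known-active endpoints; a flag includes them). Sampling draws uniform
permutations deduplicated to the requested count, switching to exhaustive
enumeration with subsampling when the request approaches N!. Genotypes
discarded upstream may be marked NaN; paths through them are
non-evaluable and excluded from both numerator and denominator, counted
separately. The vectorized evaluator handles 10⁶ paths at N = 16 in
memory (~60 MB of indices).

## Synthetic data: what it emulates, and what it does not

**Spectrum landscapes** draw sparse background-averaged coefficients at
prescribed orders (counts and Gaussian scales per order), invert the
weighted Walsh–Hadamard transform to get ln(RA) for all 2^N genotypes, and
optionally add i.i.d. Gaussian noise. Ground truth is returned alongside,
so truncation and recovery claims are checked against construction, not
convention.

**Two-anchor networks** make a genotype with k mutations neutral iff its
mutations all fall within the first min(k + w − 1, N) loci of a canonical
order, or it lies within Hamming distance w − 1 of the all-mutant anchor —
a band that widens toward a mutationally robust neighborhood around the
distant genotype, the way a distant functional variant can carry a
structural module tolerant of further mutation. Width 1 leaves a single
neutral chain (accessibility
exactly 1/N!); width N makes everything neutral. Neutral genotypes draw RA
uniformly from [0.2, 1] (the wild anchor is pinned at 1); off-ridge
genotypes draw from [0, 0.1], a safety margin below the threshold. For
N ≤ 6 the exact accessible-path fraction is computed by exhaustive
enumeration and returned as ground truth.

**Read simulation** draws per-variant, per-replicate depth as Poisson
around a mean (negative binomial optionally), and ligated counts as
binomial in the true FL = RA·FL_WT (clipped at 1). FASTQ emission writes
barcode + flank + core reads at Phred 30 with an optional fraction of
low-quality bases to exercise the filters. There is no PCR bias, no
base-level sequencing error and no chimera model: replicate-noise analysis
of the real assay shows count–error correlation is weak, so binomial
sampling noise suffices for testing the estimators. Passing benchmarks
therefore demonstrates correctness of the computations, not robustness to
real library-preparation artifacts.

The default reference core is a fixed synthetic 35-nt sequence; no result
depends on its identity.

## Benchmark conditions and problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen once:

- WH oracle equivalence at N ≤ 12 (dense cap), round-trip inversion at
  N = 16; agreement thresholds 10⁻⁹.
- Truncated-reconstruction checks on a 16-locus landscape with a sparse
  order ≤ 3 spectrum (10/15/10 terms, scale 0.5).
- The sequencing round trip at N = 10 and two depths (300 and 30,000 reads
  per variant per replicate): background-averaged coefficient RMSE must
  fall with depth. The order-0 term is excluded from the comparison
  because normalizing by the *observed* wild-type FL shifts the whole
  log-landscape by a constant, which lands entirely in order 0.
- Directional-fit recovery at ω classes n = 1..3 with 1000 variants per
  class, 20 seeds, parameters within 3 calibrated standard errors (one
  seed is allowed to miss — the nominal 3σ rate).
- Mutation-operator calibration over 10⁵ seeded calls (±0.01 around the
  expected 1.0 substitutions per call).
- Ridge traversal: N = 16, width 4, start population = all neutral
  genotypes with ≤ 3 mutations (standing diversity: a production run would
  start from a full prior generation rather than a single sequence),
  200 offspring and 60 parents per round, tournament 3, 300 rounds,
  novelty + elitism on. Success is the round-wise maximum of the
  population's mean Hamming distance reaching 0.75·N, checked over 5
  seeds. The mechanism is the self-avoiding ratchet described above; the
  per-round population is sized so parent diversity keeps the frontier
  from trapping, and the margin at these conditions is comfortable
  (typical maxima ≈ 0.79–0.84·N).

## Known limitations

- Secondary-structure prediction, compressed-sensing coefficient recovery
  from subsamples, and significance testing of individual epistatic terms
  are out of scope.
- The reciprocal-sign census's sparse path is quadratic in dataset size;
  use the complete-landscape path for 2^N data.
- Classifier determinism for the MLP is per-seed only; metric tolerances
  in tests absorb backend-level nondeterminism.
- The guided loop trains nothing: the classifier is fixed (the workflow
  retrains once, before the loop, on all prior generations).
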