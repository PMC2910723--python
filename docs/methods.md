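# Methods

## Model and statistic

A binding profile is an ordered list of genomic intervals (0-based,
half-open, BED convention; strand is ignored). Duplicate coordinates are
independent locations: a site bound by k factors contributes k records to
any pool it enters. Two locations overlap when they lie on the same contig
and share at least one base; abutting half-open intervals do not overlap.

The co-occurrence matrix **C** holds a score for every unordered pair of
joint-pool records whose intervals overlap. Two scoring policies are
provided: `binary` (c_ij = 1 for any overlap, c_ii = 1) and `bases`
(c_ij = shared bases, c_ii = interval length). Only the binary policy has
reference validation values; `bases` is exercised structurally by the test
suite. The matrix stores all overlapping pairs, including pairs within one
factor: homogeneous overlaps never contribute to the *observed* statistic
(which sums only A×B combinations) but can score under a resampled
assignment that splits them across the factors.

The statistic for an assignment (set A, set B) is S = Σ_{i∈A, j∈B} c_ij.
The diagonal term c_ii enters when a record is dually assigned, and a fully
dually-assigned overlapped pair contributes 4 under binary scoring (two
off-diagonal plus two diagonal terms). S is symmetric in the two sets,
additive over contigs, and bounded by |A|·|B| under binary scoring.

Matrix assembly proceeds one contig at a time with a start-sorted sweep and
an active min-heap of open intervals; cross-contig pairs can never overlap,
so this equals a whole-genome all-pairs scan (asserted against a brute-force
oracle in the tests).

## Resampling schemes

Each scheme redraws the assignment per iteration and estimates
p̂ = #(S* ≥ S_obs)/iterations. Ties count as exceedance and no +1
correction is applied; a zero-exceedance result is reported as
`< 1/iterations` (the `p_conservative` property exposes the
(exceed+1)/(iterations+1) estimate for users who want it).

* **Permutation** — n_A records of the two-profile pool to A, the rest
  to B. For the simple model the p-value is exactly P_m · P_pair with
  P_m = C(2m,m)·C(n_A+n_B−2m, n_A−m)/C(n_A+n_B, n_A) and
  P_pair = 2^m (m!)²/(2m)!.
* **Independent** — A and B are independent without-replacement draws; the
  same record may serve both factors.
* **Hybrid** — the pool is partitioned into records with at least one
  *heterogeneous* observed overlap (set O; same-factor overlaps do not
  qualify) and singletons (set S). A draws n_A from O ∪ S; B draws n_B from
  (O \ A) ∪ S. The draw order (A first, B restricted on O) is fixed; this
  scheme reduces exactly to the permutation test when S = ∅ and to two
  independent draws when O = ∅, where the null pmf is the hypergeometric
  C(n_A,k)·C(h−n_A, n_B−k)/C(h,n_B), h = n_A+n_B — both limits are asserted
  in the tests. A draw leaving fewer than n_B eligible records raises an
  error rather than silently retrying; with a two-factor pool this cannot
  occur (eligible ≥ n_A+n_B−n_A = n_B).
* **FL** — the pool is every record of every factor in the dataset; n_A are
  drawn for A, then n_B from the remainder. On a two-factor dataset this is
  the permutation test. Replicate factors duplicate coordinates in the pool
  as independent records, which is what makes the scheme sensitive to
  dataset composition.

Sampling is vectorised: a row of uniform keys ranks the pool and the k
smallest keys form a without-replacement draw of size k (for the hybrid
B-draw, blocked records' keys are set to +∞; for FL the first n_A and next
n_B order statistics give the sequential draws). Iterations run in batches
sized to roughly 2×10⁶ key draws so memory stays flat.

## Randomness and reproducibility

Each test consumes a single `numpy` generator seeded from its `seed`
argument; identical seed and parameters give bit-identical results. Because
iterations are independent, an iteration budget may be split across
partitions whose seeds derive from `SeedSequence(seed).spawn`, and merging
by summing exceedance counts (`run_partitioned`/`merge_results`) matches a
single stream statistically — the contract a message-passing parallel
driver would rely on; no such driver is shipped. The screening driver
derives each (pair, method) seed by hashing the factor names with CRC-32,
so pair-pool results are bitwise invariant to adding or removing unrelated
factors from the dataset.

## Two-stage screening

`survey_then_full` first runs a short survey (default 100 iterations); if
p̂ exceeds the cut-off (default 0.1) the pair is flagged screened-out,
otherwise a fresh full run (default 5000 iterations, independent stream)
provides the estimate. `screen_all_pairs` applies this to all k(k−1)/2
pairs and reports raw p-values (no multiple-testing correction by default,
with optional Benjamini–Hochberg columns behind a flag) plus per-factor
overlap tallies: a site counts as overlapped when it has ≥1 heterogeneous
overlap with the partner factor, rendered `count/total (pct)` at 3
significant figures.

## Co-localization index

`ci_index` computes N/R (or its log), the ratio of observed to resampled
co-occurrence counts; `ci_distribution` simulates its distribution under
permutation resampling. On 40 overlapped pairs the CI distribution is
nearly unchanged between 10 and 1000 singletons per factor (two-sample KS
statistic < 0.05 at 5000 iterations, equal medians) — the index tracks the
absolute overlap count, not the overlapped fraction, so a high CI alone
cannot distinguish a genuinely colocalized pair from a large profile with
a small overlapped fraction.

## Synthetic generators

`make_simple_model` lays out m overlapped clusters (100-base sites
overlapping by 50 bases) followed by the singleton sites of each factor,
all 1000 bases apart on one contig. The geometry is arbitrary and fixed:
under binary scoring only the overlap topology matters, and a test asserts
that rescaled geometry yields identical results. `make_fl_scenario` adds
replicate factor pairs at coordinates identical to the tested pair's and,
optionally, one factor with entirely disjoint sites. The generators emulate
overlap topology only — they produce no bursty site clustering, chromosome
structure, or length variation of real profiles, so passing reference
values demonstrates correctness of the statistics, not robustness to
real-data irregularities; on real data the resampling schemes inherit
whatever non-uniformity the observed profiles carry.

## Numerical choices

All combinatorial closed forms are evaluated with log-gamma and
exponentiated at the end, so pool sizes of 10⁴ or more neither overflow nor
lose precision. Scores are sums of small integers in double precision, so
the exceedance comparison `S* ≥ S_obs` is exact under both policies.
Out-of-range arguments to the hypergeometric pmf return 0; an empty joint
pool is an input error.

## Reference problem sizes

The acceptance driver uses the configurations with known reference
behaviour: closed forms at (m=10; n=20 and n=2000) and m=20; permutation at
m=10 with 990 singletons per factor (100 000 iterations); independent at 10
pure pairs (50 000); hybrid at m=10/20 with 0–10 singletons per factor
(100 000); FL at 40 pairs with 1 or 3 replicate factor pairs (100 000).
Stochastic expectations in the test suite were frozen from 1–2 million
iteration calibration runs of the same engines; checks allow three binomial
standard errors of the run plus the calibration's own uncertainty.

## Known limitations

* The hybrid and FL schemes have no closed-form p-values for mixed pools;
  everything beyond the stated limits is Monte-Carlo only.
* Resolution is bounded by 1/iterations; two-stage screening trades tail
  resolution for throughput on screened-out pairs.
* Distance-threshold ("within d bases") co-occurrence, strand awareness and
  motif/PWM-based null models are out of scope; the method assumes the
  profiles already embody the underlying sequence biases.
* The FL(r) variant (one factor held fixed) is deliberately not
  implemented: it treats the two factors asymmetrically.
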