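# Methods

## Model and hypotheses

Observations x_{i1}, …, x_{i n_i} for groups i = 1..k (k ≥ 3) are assumed
independent with continuous distribution functions F_i under the location
model F_i(x) = F(x − μ − θ_i). The test problem is one-sided and ordered:

    H0: F1 = … = Fk        H1: F1 ≥ F2 ≥ … ≥ Fk, strict somewhere,

i.e. responses tend to increase with the group index. The group order is part
of the hypothesis: the package never sorts groups by label or by value, and
the CLI requires the ordering explicitly. Continuity means ties have
probability zero; observed ties are handled by fixed conventions (below) and
flagged with a warning rather than refused.

## Statistics

Write N = Σ n_i and N* = Π n_i. A *k-tuplet* takes one observation from each
group in hypothesis order.

- **KTMB**: kernel = number of fixed points of the tuple's rank permutation,
  k(x1..xk) = Σ_i I(R(x_i) = i); T = sum of kernels over all N* tuples.
  Attainable kernel values are {0..k} \ {k−1}. Under H0 the kernel has mean 1
  and variance 1 (moments of the fixed-point count of a uniform random
  permutation), so E0[T] = N*.
- **TM** (Terpstra–Magel): kernel = I(x1 ≤ … ≤ xk, at least one strict).
- **KTP**: kernel = Spearman correlation between within-tuple ranks and the
  group indices 1..k (average ranks under ties; a fully tied tuple scores 0).
- **JT** = Σ_{l<m} U_lm with U_lm the count of strictly ascending pairs;
  **MJT** = Σ_{l<m} (m − l) U_lm.

All five are rank statistics, hence invariant under strictly increasing
transformations of the data.

Two computation routes exist for the tuple statistics. `tuple_statistic`
enumerates tuples lexicographically with a budget guard (default 10^7
tuples). The production route counts, for each observation x of group i and
each rank r, the number of tuples in which x has min-rank r, as the
coefficients of Π_{l≠i}(d_l + c_l z), where c_l is the count of group-l
values strictly below x and d_l = n_l − c_l. This gives all three tuple
statistics in O(k² N) per dataset and vectorizes over simulation replicates
(`batch_statistics`). For tie-free data the two routes are identical (tested
against each other and against naive oracles); under ties the fast route
remains exact for KTMB (min-rank), while TM and KTP fall back to kernel
enumeration.

Tie conventions: min-rank for KTMB; the non-strict TM definition; average
ranks for KTP; strict inequality only in U_lm (no ½ credit).

## Null distributions and moments

Under H0 the statistic depends only on which pooled ranks land in which
group, and all N!/(n1!…nk!) rank partitions are equally likely.

- **Enumeration** (`enumerate_null_pmf`): visits every partition (budget
  10^6), computes the statistic on the rank data via the vectorized route and
  tallies an exact PMF. Probabilities are `fractions.Fraction`s up to 10^5
  partitions; moments are always computed in exact integer arithmetic (KTP
  values are scaled by k(k²−1) to make them integral). The three tabulated
  small designs — (2,1,1): mean 2, variance 8/3; (2,1,2): mean 4, variance
  103/15; (1,1,3): mean 3, variance 5 — are reproduced bit-exactly.
- **Tie-pattern decomposition** (`exact_null_moments`): Var(T) is the sum of
  Cov(kernel_a, kernel_b) over all ordered pairs of tuples. The covariance
  depends only on the set S of positions where the two tuples share an
  observation; tuples with S = ∅ are independent. For each non-empty S the
  covariance is computed exactly (rational arithmetic) by enumerating all
  (2k − |S|)! orderings of the distinct values involved, memoized per
  (k, S, statistic), and weighted by the pair count
  Π_{i∈S} n_i · Π_{i∉S} n_i(n_i − 1). Exact for arbitrary sample sizes;
  enumeration per pattern caps at k ≤ 5 by default ((2k−1)! permutations),
  beyond which Monte Carlo takes over. Equality with full enumeration is
  tested across every k ∈ {3,4} design with ≤ 10^4 partitions.
- **Closed forms**: JT uses the standard Mann–Whitney moments,
  E = (N² − Σn_i²)/4 and V = [N²(2N+3) − Σn_i²(2n_i+3)]/72. For MJT the
  variance follows from pairwise Mann–Whitney covariances: two counts sharing
  group g on the same side contribute +n_g n_a n_b/12, on opposite sides
  −n_g n_a n_b/12, disjoint counts are uncorrelated. Both closed forms are
  verified against partition enumeration for all small designs in the tests.
  (An exact closed form beats the seeded-Monte-Carlo default that was the
  obvious alternative for MJT; MC remains available.)
- **Monte Carlo** (`mc_null_moments`): seeded random rank partitions,
  method/reps/seed recorded in the result.

The `auto` policy picks closed forms for JT/MJT, enumeration within budget,
then tie-pattern, then Monte Carlo. An advisory JSON cache
(`MomentsCache`) can persist moments across runs; it is off unless a path is
supplied.

## Inference

`run_test` standardizes the observed statistic, Z = (T − E0T)/√V0T, and
reports the one-sided upper-tail normal p-value, rejecting at Z ≥ z_{1−α}
(no continuity correction). `run_battery` reports all five tests in the
fixed order KTMB, KTP, JT, MJT, TM at a shared α. This is the large-sample
rule appropriate for data analysis; on very small designs the lattice of T
is coarse and the normal tail can differ substantially from α — e.g. for
sizes (2,1,1) the exact size of the nominal-0.05 normal rule is
P(T = 6) = 1/12 ≈ 0.083. The tests document this rather than hide it.

## Simulation engine

`PowerScenario` fixes (sizes, θ, log-F df pair, α, reps, seed). Data follow
X_ij = θ_i + ε_ij with ε_ij = log of an F(d1, d2) variate (natural log;
(d1, d2) = (numerator, denominator) df). Equal df give errors symmetric
about 0 (X ~ F(d,d) ⇒ 1/X ~ F(d,d)); the study's df pairs (2, 4.5),
(4.5, 4.5) and (10, 4.5) span right-skewed to left-skewed noise. Default
reps = 10,000 and α = 0.05 are the study's conditions; replicate r is
seeded by SeedSequence((seed, r)) so individual datasets are reproducible
and all tests see identical data (variance reduction for power
differences).

Two rejection rules are available (`critical_policy`):

- **null_quantile** (default): reject when the statistic reaches
  c = the smallest support value whose null CDF is ≥ 1 − α, taken from the
  exact enumerated PMF when the partition count is within budget and from a
  seeded 100,000-draw Monte Carlo null sample otherwise. For KTMB at
  (4,4,4) this gives c = 108 with exact size 0.0501.
- **normal**: reject at E0T + z_{1−α}·√V0T.

The quantile rule is the default for size/power studies because the discrete
statistics are skewed on small designs and the normal rule's true size can
drift far from α (KTMB at (4,4,4): 0.0647; TM: 0.0652; JT, nearly symmetric,
stays at 0.0463). On such coarse lattices *no* deterministic rule achieves
size exactly α for every statistic — the attainable sizes jump between
support points (JT's exact-quantile size at (4,4,4) is 0.0632) — which is an
inherent property of discrete tests, not an implementation artifact; designs
with richer support (e.g. (10,10,5)) calibrate closely for all five tests.

`estimate_power` computes each test's critical value once, evaluates all
requested tests on the shared replicates in vectorized chunks, and returns
rejection proportions with SE = √(p(1−p)/reps). `dp_metrics` reports the
relative power differences 100·(KTMB − TM)/TM ("gain") and
100·(min(KTP, JT, MJT, TM) − KTMB)/KTMB ("loss"). `run_study` maps a
scenario list to a table, recording per-scenario failures without aborting.

## What the generator does and does not emulate

The generator produces iid location-shifted log-F noise — the simulation
design of the original power study. It does not emulate features of real
clinical data such as ordinal/discrete responses with heavy ties, covariate
structure, unequal dispersions across groups, or dependence between
subjects. Passing the simulation checks therefore validates the statistics,
their null distributions and the rejection machinery under the stated
location-shift model, not robustness to those real-data departures (the tie
conventions are deterministic and tested, but their operating
characteristics under heavy ties are not part of the study design).

## Numerical choices and defaults

- Enumeration budgets: 10^6 partitions (PMF/moments), 10^7 tuples (literal
  tuple sums), rational PMF probabilities up to 10^5 partitions; tie-pattern
  cap k ≤ 5. All are keyword-configurable.
- Problem sizes in the test suite and acceptance script: 10,000 replicates
  per simulation cell (matching the study), and the oracle-equivalence sweep
  covers every k ∈ {3,4} design with ≤ 10^4 partitions.
- Degenerate inputs: empty groups, non-finite values, k < 3 for tests,
  α ∉ (0, 0.5], non-positive null variance, unknown labels and non-numeric
  values in files all raise typed errors naming the offender.
- KTP on a fully tied tuple returns 0 (no trend evidence); zero rank
  variance cannot otherwise occur.
- All Monte Carlo paths take explicit seeds and record them in their
  results.

## Known limitations

- One-sided, non-decreasing alternatives only; no umbrella or two-sided
  variants, no MJT weights other than m − l.
- p-values come from the normal approximation, not from exact conditional
  permutation tails; for tiny designs use the exact PMF directly.
- The tie-pattern engine needs (2k−1)! enumeration per pattern, so exact
  moments stop at k = 5 (Monte Carlo beyond).
- Exact PMFs are limited by the partition budget; the (5,5,5,5) design
  (≈ 1.17 × 10^10 partitions) is counted but never enumerated.
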