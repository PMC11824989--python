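# Methods

## Scope and model

`rarepop` estimates, for a single diploid population genotyped at L loci,
the smallest sample size n* at which subsamples of size ≥ n* statistically
reproduce the full dataset.  "Reproduce" is operationalized as four fixed
criteria evaluated on the mean over replicate subsamples (see below).  The
package deliberately analyzes **one population per run**: if an input file
carries a population column it is treated as inert metadata (a prefix
column), never as a grouping factor.  Haploid and polyploid data are out of
scope.

## Input formats

Genotypes are read from comma-separated Structure-style files in either row
dialect (one row per individual with two columns per locus, or two rows per
individual with one column per locus).  Missing allele copies are coded 0 or
-9.  Parsing rules worth stating:

- Rows are paired **by adjacency** in the two-row dialect; when a label
  column is present, the two rows of a pair must carry the same label.
- `n_prefix_columns` (default 1) leading columns are skipped as metadata;
  the first of them is used as the individual label.
- `first_individual_line` (default 1) gives the 1-based line where genotype
  data begin; if the last skipped line has the shape of a header, locus
  names are recovered from it, otherwise names `L1…` are generated.
- A genotype with exactly one missing copy contributes its scored copy to
  allele counts (maximizing information for frequencies) but is excluded
  from the observed-heterozygosity denominator at that locus, where a
  single copy cannot show heterozygosity.
- Allele codes are opaque integer labels everywhere except inside the
  simulator, where the stepwise mutation model needs an ordering.

The run configuration is a `key = value` text file (`#` comments), chosen
over a structured format because it diffs cleanly and has nothing nested.

## Statistics

With p_a the frequency of allele a among non-missing copies at a locus:

- **H_O** per locus: heterozygotes / individuals with both copies scored;
  undefined (NaN, skipped by means) when no individual is fully scored.
- **H_E** per locus: 1 − Σ_a p_a² (Nei gene diversity).  No 2n/(2n−1)
  small-sample correction is applied: the uncorrected form makes the
  size-N subsample reproduce the full-dataset value exactly, which is the
  natural fixed point for a rarefaction analysis (identity subsample ⇒
  zero difference on every criterion).
- **F_ST** between a subsample and the full dataset: per locus,
  H_T = 1 − Σ_a p̄_a² with p̄ the unweighted mean of the two pools and
  H_S the mean of the two pools' H_E; the statistic is the **mean of the
  per-locus ratios** (H_T − H_S)/H_T over loci with H_T > 0, and 0 when no
  locus qualifies.  A mean-of-ratios without variance correction is used
  on purpose: the quantity is meant to *feel* sample-size bias (small
  subsamples drift away from the source pool and the criterion catches
  it), not to be an unbiased estimator of population differentiation — a
  Weir–Cockerham-style estimator would sit near 0 at every size and the
  criterion would never discriminate.
- **Nei's standard distance** (1972): D = −ln(J_xy / √(J_x J_y)) with the
  identities J averaged over loci scored in both pools; D = +∞ when the
  pools share no allele (the valid limit; it propagates to tables as an
  explicit `Inf` token rather than raising, keeping replicate aggregation
  total).
- **Rogers' distance** (1972): mean over loci of √(½ Σ_a (p_a − q_a)²),
  bounded in [0, 1]; allele unions per locus, absent codes at frequency 0.
- **Common alleles**: full-dataset frequency ≥ `min_allele_freq`
  (default 0.05); the rest are rare.  Detection fractions for the common,
  rare, and complete allele sets count alleles with nonzero subsample
  frequency.  The globally most/least common alleles (ties broken by locus
  order, then code) are tracked per subsample for the extreme-frequency
  output.
- **Frequency deviation**: mean over all full-dataset alleles of
  |p_sub − p_full| (absent alleles at 0).  The mean is taken per replicate
  first, then aggregated across replicates, so every replicate weighs
  equally regardless of how many alleles it detects.

## Rarefaction design

The ladder contains the multiples of the smallest subsample size strictly
below N plus N itself (N = dataset size, optionally capped by
`max_sample_size`; the comparison baseline is always the *full* dataset,
so capping the ladder never changes the statistics at the retained sizes).
Each size gets `n_resamples` (default 50) independent without-replacement
draws; replicate index sets may repeat by chance — draws are independent.
The full-size point is rarefied like any other (its replicates are
degenerate identical draws), keeping table shapes uniform and providing an
internal zero check.

**Seeding.** One master seed governs a run.  Each (size, replicate) pair
gets its own counter-derived substream (`SeedSequence(seed,
spawn_key=(size, replicate))`), so adding or removing ladder sizes leaves
every other draw unchanged, and runs are bit-reproducible from the
manifest (config + seed + input checksum).

**Aggregation.** Per size and statistic: mean, sample standard deviation
(ddof = 1, defined as 0 for a single replicate), min, max, over non-NaN
replicates.

**Decision rule.** A size passes a criterion when the aggregate **mean**
meets the threshold (0.95 common-allele detection ≥; 0.01 frequency
deviation ≤; 0.05 F_ST ≤; 0.05 H_E difference ≤).  The default
"persistent" rule requires the pass to hold at every larger ladder size as
well — this encodes plateau-reaching and is robust to a single lucky size;
a "first-pass" rule is available via `pass_rule = first` for users who
want the literal first crossing.  The overall minimum is the maximum of
the four per-criterion minima and is "not reached" as soon as any
criterion never stabilizes.

## Forward simulator

A two-sex Wright–Fisher model with non-overlapping generations:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 600 | constant census size, exactly n/2 per sex |
| n_generations | 10 | generations after the founding draw |
| p_kam | 0.5 | probability a mutation event is K-allele rather than stepwise |
| SSR preset | 10 loci, K = 20, μ = 1e-4 | microsatellite-like |
| SNP preset | 2 500 loci, K = 2, μ = 1e-7 | biallelic-SNP-like |

Founding ("maximal variability"): every allele copy i.i.d. uniform over
the K states.  Mating: each offspring draws its mother uniformly from the
females and its father uniformly from the males, with replacement
(promiscuous random mating — the simplest scheme consistent with random
mating; with equal sex numbers its variance effective size equals the
census size, so heterozygosity decays by the standard (1 − 1/2N) per
generation).  Transmission: per locus independently, one uniformly chosen
copy from each parent (free recombination).  Mutation: each transmitted
copy mutates with probability μ; the event is K-allele (uniform over the
K − 1 other states) with probability p_kam, otherwise stepwise ±1 with
**inward reflection** at the boundaries (1→2, K→K−1) — reflection keeps
states in range without piling probability mass onto the boundary states.
K = 2 makes both models coincide (the only alternative state).  Offspring
sexes are assigned exactly n/2 : n/2, a deterministic reading of a 1:1 sex
ratio.

What the simulator emulates: neutral mutation–drift equilibrium-bound
dynamics of a single closed random-mating population.  What it does not:
selection, migration/structure, selfing or other non-random mating,
linkage, genotyping error, and missing data — so a green simulation test
says the pipeline behaves correctly on clean neutral data, not that any
empirical dataset will behave likewise.

## Group comparison

The two-sided Wilcoxon rank-sum test compares minimum sample sizes between
groups (e.g. SNP vs SSR datasets).  W is the midrank sum of the first
group minus n_x(n_x+1)/2.  The p-value uses the exact null distribution
when the pooled values have no ties and the normal approximation with tie
correction and continuity correction otherwise (the conventional default,
matching R's `wilcox.test`).  On the bundled 19-dataset survey of
published minima, SNP (n = 7) vs SSR (n = 12) overall minima give W = 16,
p ≈ 0.026.  W is computed by midranks in-house; the p-value is delegated
to `scipy.stats.mannwhitneyu`, and tests assert the two routes agree.

## Numerical and degenerate-input policy

- Frequencies sum to 1 within 1e-9 per locus; statistics bounded by
  construction are asserted in tests, not clamped.
- Loci with no scored copies yield empty frequency maps; they are skipped
  by the pairwise statistics and NaN-skipped in means.
- Tables are CSV with full-precision floats; NaN/±Inf are written as
  explicit `NaN`/`Inf`/`-Inf` tokens and round-trip.
- When the dataset has no rare allele, the rare-allele output table is
  written with an empty body and its plot is skipped with a logged notice.

## Known limitations

- Uniform random subsampling only; clustered or spatially biased sampling
  designs are not modeled, and results on such data will be optimistic.
- The F_ST criterion statistic is intentionally biased (see above); do not
  report it as a population-differentiation estimate.
- Memory grows with loci × replicates for the per-locus outputs; datasets
  in the low-thousands of markers and a few hundred individuals are the
  intended scale.
- The heterozygosity-decay validation compares the simulator against
  H(t) = H(0)·(1 − 1/2N)^t anchored at the *observed* founding
  heterozygosity; the idealized anchor (1 − 1/K)·(1 − 1/2N)^t ignores the
  O(1/2N) founding-sample deficit in H(0) and is only checked at loose
  tolerance.
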