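# Methods

## Problem setting

Genotyping-by-sequencing (GBS) and similar reduced-representation
protocols yield, for each sample at each SNP, a pair of allelic read
counts (r_R, r_A) — often zero or very small.  Conventional pipelines
threshold on depth, discard most of the data, and impute the rest from
hard genotype calls.  `gbsimpute` instead keeps the read counts in play:
every genotype receives a probability distribution over {0, 1, 2} (the
ALT-allele dosage) from two sources of evidence — the reads themselves
and the sample's neighbours in genotype space — and the two are blended
with a weight tuned on held-out data.  Nothing requires a reference
panel or ordered markers, which is why the approach suits non-model
organisms with fragmented or unreliable assemblies.

## Inference from read counts

The likelihood of genotype g given the counts is binomial:

    L_0 = f(r_R; n, 1 - e),  L_1 = f(r_R; n, 1/2),  L_2 = f(r_A; n, 1 - e)

with n = r_R + r_A, f the binomial pmf, and e the per-read error rate
(default 0.01, the conventional value for GBS pipelines; configurable
through `ErrorModel`).  Normalising the three likelihoods gives the
*inferred* distribution p^n; its argmax is the inferred genotype.
Likelihoods are evaluated in log space and exponentiated after
subtracting the maximum, so depths in the hundreds cannot underflow the
normalisation.  A (0, 0) entry yields the uniform distribution — absent
data and zero reads are informationally identical under this model.

## LD-kNN imputation

Entries with depth at most the case threshold d are imputed from the
entries with depth above d (the "known" genotypes):

1. LD between sites is the squared Pearson correlation r² of known
   genotypes over pairwise-complete samples (0 when fewer than two
   complete pairs exist or a site is constant on them).  Both the
   all-pairs matrix and the scalar routine compute r² from integer sums
   in the same operation order, so the two routes agree bitwise for
   realistic sample counts.
2. For a target site a, the l sites with highest r² form its LD window
   (ties to the lower site index).
3. The distance from sample b to sample s is the Manhattan distance of
   their genotypes over the LD window, restricted to sites where both are
   non-missing, rescaled by l / (number of usable sites), plus 1.  The +1
   keeps inverse-distance weights finite for identical samples; a pair
   sharing no usable site is held at the maximal distance 1 + 2l rather
   than excluded.  The rescaling treats partially observed windows as if
   their observed density of disagreement continued across the window.
4. The k nearest samples with a known genotype at a (fewer if fewer
   exist; distance ties to the lower sample index) vote with weight
   1/distance, and the normalised vote is the *imputed* distribution p^m.

k and l are chosen by exhaustive grid search (defaults k in 1..10,
l in {2, 4, 8, 16, 32}, clipped to the data size) maximising the
fraction of masked training genotypes whose imputed argmax matches their
known value; ties prefer smaller l, then smaller k.  The neighbour table
is built once per case at the largest l, and smaller l values reuse its
prefix columns — valid because each row is sorted by decreasing r².

## Calling

The called distribution is the convex blend

    p^c = w * p^m + (1 - w) * p^n

applied only to entries with depth <= d; deeper entries keep p^n
unchanged.  A single w per case is fitted by exhaustively scanning
{0, 0.01, ..., 1.00} for maximal calling accuracy on a second masked
partition.  The scan is exhaustive because accuracy in w is not
guaranteed unimodal; since both endpoints are in the grid, the training
accuracy at the chosen w can never fall below pure inference or pure
imputation.  Accuracy ties break to the smallest w, i.e. toward
read-count evidence when the training data are indifferent.

## Filters and cases

Two pre-filters run once per analysis, on genotypes inferred at depth >=
8 (configurable): a MAF filter (default: drop sites with minor allele
frequency below 0.05, or with fewer than two genotyped entries) and an
exact Hardy-Weinberg test (default alpha 0.01, Bonferroni-corrected by
the number of sites actually tested; sites with fewer than two genotypes
are not tested).  The HWE test is the standard conditional exact test on
genotype counts; a genotyping-error-rate hook is carried in the
configuration for error-aware variants but does not enter the test.

A *case* is one (d, SNP missingness, sample missingness) combination.
An entry is missing for the missingness filter iff its depth is <= d —
the same boundary used everywhere: inference above d, imputation at or
below.  Sites are filtered before samples, and sample fractions are
recomputed on the reduced site set, so the order is observable and
fixed.  Cases whose dataset empties, or that retain too few masked
genotypes (default minimum 30), are reported as skipped with the reason
— on very sparse datasets entire regions of the grid are legitimately
infeasible, mirroring how strict missingness settings cannot be tested
on sparse real datasets.

## Accuracy estimation by masking

Genotypes with depth >= 30 are treated as known (their inferred genotype
is taken as truth).  A masked set (default 10,000 entries; any evaluation
in this package that simulates its own data uses 2,000) is drawn
uniformly without replacement; for each entry a target depth is drawn
from the dataset's own empirical distribution of depths <= d_a (default
8, the largest d under comparison — this keeps accuracies comparable
across d), and reads are deleted uniformly at random until the target
remains.  The surviving REF count is therefore hypergeometric given the
original counts and the target — a property the tests verify against the
closed form.

The masked set is split 40/30/30 into k/l-training, w-training and test
partitions (the proportions are a package default; only disjointness is
essential).  Each masked genotype is evaluated with only itself
down-sampled.  The known-genotype matrix and LD table are built once
from the unmasked counts: a single masked low-depth genotype cannot
change them, because a sample is never its own neighbour and a site
never sits in its own LD window.  Test genotypes whose reduced depth
exceeds d are called by inference alone, consistent with the calling
rule.  Reported per case: test accuracy at the fitted w, the two
endpoint accuracies (w = 0, pure inference; w = 1, pure imputation), and
a correlation between known and called genotypes with both centred by
the per-site mean known genotype, which removes the MAF-driven
component of agreement.  The centring means are taken from the
known-genotype matrix because every retained site has depth-above-d
entries by construction.

When a grid of cases is swept, one master masked set is drawn on the
pre-filtered matrix; each case keeps the entries surviving its own
filters and re-partitions them with a case-specific seed, so cases are
comparable yet independently partitioned.  A case is flagged *good* when
no other case has at least as many SNPs, at least as many samples, and a
strictly higher accuracy (or correlation, if that is the optimisation
metric); the user picks among the good cases and applies one, reusing
its fitted (k, l, w) — the call phase does not re-optimise.  In the call
phase, a site left with no known genotype after sample filtering cannot
be imputed; its low-depth entries keep their inferred distributions and
are tallied in the log rather than aborting the run.

## Synthetic data generator

`synth` emulates the structure this method relies on, with known truth:

- **Genotypes**: a pool of founder haplotypes (default 4) is drawn site
  by site, ALT frequency uniform on [0.1, 0.5]; each sample is two
  haplotype mosaics.  Crossovers occur only at block boundaries (every
  `block_len` sites, default 50) with probability `recomb_rate *
  block_len` per boundary, giving strong within-block LD that decays
  across blocks — the signal LD-kNN imputation needs.  Fewer founders
  and longer blocks mean stronger LD.
- **Reads**: per-entry depth is negative-binomial (mean 4, size 0.3) with
  10% zero-inflation by default — heavy-tailed like real GBS, with many
  empty entries and a small fraction of very deep genotypes that serve as
  the known set — and ALT reads are binomial with success probability
  {e, 1/2, 1-e} by genotype.

What the generator does *not* model: restriction-site dropout correlated
between related samples, mapping bias, paralog collapse, population
structure beyond the founder mosaic, and depth correlated with genotype.
Passing tests therefore show the pipeline recovers truth when its LD
assumption holds and errors are binomial; they do not certify behaviour
under systematic artefacts.

## Numerical and design choices

- All tie-breaks (argmax genotypes, LD partners, neighbours, k/l/w
  grids) go to the lowest index or smallest value, making every run
  bit-reproducible from its seed; two runs from the same configuration
  produce byte-identical summary tables and VCFs.
- The exact HWE p-value sums, over all heterozygote counts compatible
  with the observed allele counts, the probabilities not exceeding the
  observed configuration's; it is computed with log-factorials and
  normalised in place.
- VCF input consumes only the AD FORMAT field (REF count first); GT/PL
  fields in the input are ignored and re-derived.  Records that are not
  biallelic SNPs are dropped and counted.  Output VCFs carry GT (argmax,
  ties to the lower genotype), the original AD, and a 3-float GP field
  (p0, p1, p2 rounded to 3 decimals), plus header lines recording the
  case and fitted parameters.
- Problem sizes in the test-suite and in `scripts/acceptance.py` follow
  the generator defaults (200 samples x 1,000 sites, 2,000 masked
  genotypes for evaluation); the acceptance sweep uses depth thresholds
  {1, 2, 3} x missingness {0.6, 0.7, 0.8} because the simulated depth
  profile is sparse enough that stricter combinations empty the dataset
  (those appear as skipped rows, exercising the same reporting path real
  sparse datasets trigger).

## Known limitations

- Biallelic diploid markers only; no per-base quality awareness.
- One global w per case; no per-depth or per-sample weighting.
- The correlation metric centres by the known-genotype site mean, which
  is an estimate of the true site mean and degrades at extreme
  missingness.
- LD r² bit-reproducibility across the scalar and matrix routes assumes
  the intermediate integer sums are exactly representable in float64;
  this holds comfortably below ~10^6 samples.
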