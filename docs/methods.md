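# Methods

## Model and scope

All tests operate on a gene × lane matrix of read counts with each lane
assigned to one of two biological conditions. The count of one gene in one
lane is modelled as Poisson: a gene's reads are a small fraction of a
lane's total, so the binomial sampling of reads onto genes is well
approximated by independent Poissons. The Poisson assumption equates mean
and variance; it describes technical replicates (relane/rerun of the same
library) well, but biological replicates are typically overdispersed, for
which a negative-binomial observation model would be needed — that
extension is deliberately out of scope, and results on biological
replicates should be read with this in mind.

## Likelihood-ratio tests

Within one condition with replicate counts $x_1 \dots x_m$ and pooled
count $x$, the ratio for a shared mean is $\Lambda_1 = x^x / (m^x \prod_j
x_j^{x_j})$; across conditions, with pooled counts $x$ (from $m$ lanes)
and $y$ (from $n$ lanes), $\Lambda_3 = (m/(m+n))^x (n/(m+n))^y
(x+y)^{x+y} / (x^x y^y)$. Small values reject.

**Calibration.** $-2\log\Lambda$ is referred to a chi-square with $m-1$
(within) or 1 (between) degrees of freedom (Wilks). This is an asymptotic
choice: it is accurate for means of roughly 20 and above (the Monte-Carlo
suite verifies type-I error within [0.005, 0.02] at the 1% level for
means in [20, 2000]) and conservative-to-liberal behaviour at very small
counts is not corrected. An exact conditional (binomial) calibration is a
known alternative and is not implemented.

**Numerics.** $\log\Lambda$ is accumulated as $\sum w\,\log(\text{num}/
\text{den})$ with the $0\log 0 = 0$ convention, i.e. each term is the log
of a ratio of integer-valued floats rather than a difference of logs.
When sample means agree under the null the ratio is exactly 1.0 in
floating point, so $\Lambda = 1$ and $p = 1$ *exactly* for equal-mean
inputs, including all-zero genes. A final clip enforces $\log\Lambda \le 0$.

No multiple-testing correction is applied by default: the methods report
raw per-gene levels, which is also how the summary percentages (fraction
of genes similar at the 1%, 2.5%, 5%, 10% levels) are defined. Adjusted
p-values can be obtained downstream from the p-value column.

## Bayesian predictive test

With a flat prior on the Poisson mean integrated out, the conditional law
of one replicate given the pooled count $s$ of the other $m-1$ replicates
is negative binomial with size $s+1$ and success probability $(m-1)/m$;
for $m = 2$ this is the classical Audic–Claverie law. The implementation
evaluates the log-pmf from log-gamma terms and takes tail sums from the
regularized incomplete-beta form of the negative-binomial CDF; tests
cross-check it against an exact big-integer factorial-ratio oracle and
verify normalization to $10^{-9}$.

**Acceptance interval.** The published definition asks for integers $a,
b$ whose lower and upper predictive tails each carry mass $\alpha$. On a
discrete law those equalities generally have no exact solution, and as
written on the *unnormalized* joint chain they cannot hold at all; the
interval is therefore computed on the normalized conditional law with the
inner convention

* $a$ = smallest integer with $P(X \le a) \ge \alpha$,
* $b$ = largest integer with $P(X \ge b) \ge \alpha$,

which guarantees inclusive coverage $P(a \le X \le b) > 1 - 2\alpha$.
"1% level" maps to $\alpha = 0.01$ per tail (confidence $1 - 2\alpha$).
Against the published worked example (pooled counts 3711, 180, 7, 16)
this convention reproduces the lower endpoints exactly and the upper
endpoints to within 3 counts; a ±3-count discrepancy per endpoint is the
documented tolerance for the unstated boundary convention, and all four
published DE calls are reproduced exactly. (The worked example's fifth
row prints an interval matching a pooled count ~10× smaller than the one
shown and is treated as a misprint.)

**Uses.** Within a condition the check is a leave-one-out sweep: each
replicate is tested against the interval built from the other $m-1$; a
gene passes only if all replicates do, making the verdict order-free (the
single-holdout variant would depend on replicate labelling). Across
conditions the test requires equal replicate numbers $m = n$: the two
pooled counts are exchangeable draws of one two-replicate law, the
interval is built from condition-1's pooled count and condition-2's count
is checked against it. With $m \ne n$ the pooled counts have different
means under the null and the construction is invalid; the library refuses
rather than rescales.

## Normalization

**TPM** divides each lane by its total and multiplies by $10^6$ (per-lane
scaling only; no transcript-length adjustment — the historical usage for
count matrices). Lanes with zero total are rejected.

**TMM.** `tmm_scale_factor(test, ref)` returns the *total* relative scale
of a lane against a reference: genes zero in either lane are dropped,
per-gene ratios $M_g = \log_2(t_g/r_g)$ are doubly trimmed (default 30%
per side by $M$, 5% per side by average log-abundance $A$ — the canonical
trims of the method), and averaged with precision weights from the
binomial delta-method variance $\frac{N_t-t}{N_t t} + \frac{N_r-r}{N_r r}$.
Because $M$ is taken on raw counts, a lane that is exactly $c$ times the
reference yields factor $c$ — the factor carries library size *and*
composition. `normalize_tmm` then divides out the size part: the
compositional factor of lane $j$ is $f_j N_{ref} / N_j$, factors are
centred to geometric mean 1, and each lane is divided by (lane total ×
factor) on a per-million scale. Consequences: identical lanes reproduce
TPM exactly; a pure library-size difference normalizes to elementwise
equality; multiplying a lane by a constant is absorbed up to the shift the
depth-dependent precision weights induce (≲0.5% on Poisson-like data —
the invariance is approximate by construction, and the reference-lane
choice, the lane whose upper quartile is closest to the mean upper
quartile, can also switch under rescaling).

**Quantile.** Lanes are sorted; the reference distribution is the
rank-wise *median across lanes* of the sorted values; each entry receives
the reference value at its within-lane rank. Ties within a lane receive
the mean of their tied ranks' reference values — a deterministic,
symmetric rule, with the side effect that lanes containing ties do not
share the reference multiset exactly (the classical identical-multiset
property holds for tie-free lanes, and tests assert it there).

Because both tests are defined on integer counts while normalization
produces reals, `round_counts` (half away from zero) converts a
normalized matrix back to integers before testing; the workflow leaves
the choice of normalization to the caller.

## DE workflow

Genes are stratified by pooled per-condition counts before testing:
category 1 (zero in both) is untestable; category 2 (exactly zero on one
side, at least `present_min` reads on the other — default 5) is called DE
by presence/absence without a test, mirroring how absent-in-one genes are
conventionally reported, with a flag to route them through the test
instead; category 3 (at least `present_min` on both sides) is tested.
Pairs with a nonzero count below the threshold somewhere fit none of the
three strata; they are marked indeterminate (category 0) and excluded
rather than silently folded into a stratum, which would distort the
tested-gene denominator. "Absent" is strict zero — a deliberate reading,
since reclassifying low counts as absent changes the category-2/3 split.

Fold changes are $\log_2((x/m + 0.5)/(y/n + 0.5))$; the 0.5 pseudo-count
keeps folds finite for category-2 genes and is a package choice, not an
attributed formula. The expression-strength summary histograms
$\log_{10}(1 + \text{mean count})$ for all genes and for the significant
set on shared bin edges, each normalized to unit sum — a significant set
that concentrates in one expression stratum, rather than tracking the
all-gene distribution, indicates a method biased by expression strength.

## Simulator

`simulate_counts` draws per-gene means λ_g log-uniform on [5, 5000] by
default — spanning weakly to very highly expressed genes so that summary
distributions cover the realistic dynamic range — then lane counts
Poisson(λ_g · size factor), with condition-2 means multiplied by a known
fold for a spiked DE fraction. Defaults: size factors 1, no DE spike.
Each gene draws from its own substream (seed spawn keys), so enlarging
the gene set never reshuffles existing genes, and everything is
reproducible from one integer seed. The generator emulates the ideal
regime the tests assume — independent Poisson counts, exact size factors,
no overdispersion, no correlated genes — so passing calibration here
validates the arithmetic and the chi-square/interval calibration, not
robustness to biological variability or compositional bias in real data.

**Study sizes.** The calibration suite uses 10,000 null genes (λ
log-uniform [20, 2000], 2 vs 2 lanes) for the LRT type-I check and
10,000 paired draws at λ ∈ {10, 100, 1000} for interval coverage; these
sizes give Monte-Carlo standard errors near 0.001 at the 1% level, small
enough to resolve the tested bands.

## Known limitations

* Poisson only: overdispersed (negative-binomial) data will inflate both
  tests' rejection rates; technical replicates are the intended input.
* Chi-square calibration is asymptotic; counts below ~20 are not exactly
  calibrated at the stated level.
* The Bayesian two-condition test requires equal replicate numbers.
* TMM assumes most genes are not DE between a lane and the reference;
  quantile matching forces identical distributions and can erase global
  shifts that are biologically real.
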