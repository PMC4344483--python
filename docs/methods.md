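# Methods

This note records the statistical model implemented by `ascnseg`, the default
parameter choices, and the reasoning behind the main algorithmic decisions.

## Problem

Given allele-specific read counts at germline-heterozygous SNVs in a tumor
and its matched normal, estimate the relative copy number of each *haplotype*
(parental chromosome) along the genome, segment it into regions of constant
allele-specific copy number (ASCN), classify the aberration carried by each
region, and estimate the fraction of cells carrying each aberration.

## Data and notation

At locus *t* on a chromosome, let `(x_A, x_B)` be the tumor read counts of
alleles A and B and `(y_A, y_B)` the matched-normal counts. Only loci that
are heterozygous in the normal are used. `N = Σ(x_A + x_B)` and
`M = Σ(y_A + y_B)` are the tumor and normal totals over the retained loci.

## Coverage model and bias cancellation

Counts are modeled as independent Poissons whose means share a *site bias*
`h(t)` (mappability, GC, capture efficiency) and *allelic biases* `b_A(t)`,
`b_B(t)` (reference bias), identical in tumor and normal because both
libraries are processed the same way. The tumor mean is further multiplied
by the relative copy number `c` of the haplotype carrying the allele.
Conditioning on the per-allele total `n = x + y` removes the bias terms:

    x | n ~ Binomial(n, p),   p = N·c / (N·c + M)

so the success probability depends only on the relative copy number and the
library totals, not on `h` or `b`. This is the property that lets the method
run without GC or mappability correction; it is exercised end-to-end by an
acceptance test comparing detection thresholds with and without simulated
biases.

The inverse map is `c = p/(1-p) · M/N`, and the per-locus *observed* ASCN
is `(x/y) · (M/N)`.

## Mixture likelihood

Which allele sits on which haplotype (the phase `I_t`) is unobserved and,
by Mendelian segregation, Bernoulli(1/2) independently across loci. Within a
region of constant ASCN with haplotype success probabilities
`p_a ≤ p_b`, each locus therefore contributes a two-component mixture:

    L_t = 1/2 · Bin(x_A; n_A, p_a) Bin(x_B; n_B, p_b)
        + 1/2 · Bin(x_A; n_A, p_b) Bin(x_B; n_B, p_a)

The mixture weights are *fixed* at 1/2; only `(p_a, p_b)` are estimated,
by EM over the latent phase. Implementation notes:

- The binomial coefficients do not depend on the parameters, so EM iterates
  on coefficient-free kernels and the constants are added once at the end.
  This is what makes genome-scale segmentation fast (the coefficients
  otherwise dominate the run time).
- Likelihood contributions are grouped per allele before summation and the
  E-step uses the unnormalized posterior pair, so results are *bit-exact*
  under any relabeling of alleles A and B.
- Two starts are used (a moment-based hard-phase start and a symmetric
  perturbation of the pooled frequency) with a deterministic, label-invariant
  tie-break; an acceptance test checks the EM solution against an exhaustive
  0.001-step grid search.
- Mixtures overfit balanced segments: when the two haplotypes are truly
  equal, assigning each locus's larger allele frequency to the larger
  component inflates the estimated separation, so homozygous deletions and
  double gains would be reported as asymmetric. Final segment fits therefore
  compare the mixture against the constrained one-parameter model
  `p_a = p_b` by BIC and report the pooled estimate unless the mixture
  improves the log-likelihood by more than `0.5·log T`. Empirically the
  statistic is ≤ 2 for truly balanced spiked events and ≥ 7 for asymmetric
  events from 20% purity up, so the threshold separates the regimes cleanly.
  The segmentation scan itself always optimizes the unconstrained
  likelihood.

## Segmentation and model selection

Change-points are proposed by greedy binary segmentation: the split with the
largest log-likelihood gain is applied recursively, yielding a nested
sequence of candidate models with `K = 0, 1, 2, …` change-points
(`max_K = 15`). The number of change-points is chosen by a modified BIC for
change-point models, which penalizes both the number and the configuration
of the change-points:

    penalty(K) = max( 1.5·K·log T + 0.5·Σ_k log(ℓ_k / T),  K·log T )

where `ℓ_k` are segment lengths; `penalty(0) = 0`. The floor term keeps the
penalty from collapsing for very short segments. The penalty multiplier
defaults to 1.0; with the study's coverage model this yields zero spurious
change-points in 200 of 200 simulated null chromosomes (the acceptance suite
requires ≥ 95%).

Scanning every candidate split with a full EM fit is O(T²) EM runs per
split level and is far too slow at 10⁴–10⁵ loci. Instead, for intervals
with more than 128 candidate positions, the scan maximizes a folded
two-stream binomial profile likelihood computed from cumulative sums
(O(1) per candidate), then refines the winner with true EM gains in a ±10
window. A unit test verifies that this matches the exhaustive EM scan on
small intervals, and another that the greedy result matches an exact dynamic
program on well-separated signals.

Defaults: `min_seg = 5` loci, EM tolerance 1e-6, 200 iterations (40 during
scanning, with a single start; final segment fits always use the full
multi-start EM).

## Event classification

Each segment's fitted `(p_a, p_b)` are mapped to minor/major allelic ratios
(1 = unchanged). A haplotype is *lost* when its ratio is below `1 - δ` and
*gained* above `1 + δ`, giving six types: gain/normal, gain/gain,
normal/loss, loss/loss, balanced gain/loss (copy-neutral LOH, the loss
`1 - minor` and gain `major - 1` agree within `balance_tol = 0.1`) and
unbalanced gain/loss.

Two band half-widths are used for different purposes:

- `δ = 0.2` is the default *reporting* filter for high-confidence calls.
- `δ = 0.1` is used when *scoring detection* in the sensitivity simulator.
  This is deliberate and fixed a priori: a homozygous deletion at 15% purity
  has true ratios 0.85, inside the 0.2 band, so the wider band would veto
  events the segmentation localizes perfectly well. Detection still demands
  a correctly-typed call with ≥ 50% reciprocal overlap.

## Event-specific purity

For a mutation carried by fraction `f` of cells, a haplotype present in `c`
copies per aberrant cell has ratio `f·c + (1 - f)`. Two types identify `f`
directly: normal/loss (`f = 1 - minor`) and balanced gain/loss
(`f` estimated from both sides, `1 - minor` and `major - 1`, averaged; their
discrepancy is reported as a consistency diagnostic). Gains confound `f`
with the integer copy count and are excluded. Because ratios are relative to
the average ploidy through the library totals, the aberrations themselves
rescale every ratio by a common factor (about 2.5% for a deletion spanning
10% of the loci at 50% purity) — a systematic error invisible to resampling.
Purity estimation therefore divides event ratios by a *baseline*: the
locus-weighted mean ratio of segments classified normal (diploid anchoring).
Standard errors come from a locus-level bootstrap (200 resamples, refitting
the mixture each time).
Events are grouped by single-linkage clustering in purity space, and
pairwise clonal nesting `H ⊆ G` is flagged admissible only when
`f_H ≤ f_G` in every sample within 2 SE (a pigeonhole argument on cell
fractions; full tree reconstruction is out of scope).

## Spike-in sensitivity simulator

Synthetic chromosomes follow the Poisson model above: T = 10,000 loci,
44× per-sample coverage, lognormal site bias (sd 0.3) and allelic biases
(sd 0.2), Bernoulli(1/2) phase. One 1000-locus event with known haplotype
copies and purity is spiked in; lower coverages (22×, 11×) are produced by
binomial thinning, which preserves the Poisson form. For each type and
coverage, the detection threshold is the smallest purity on a 5–100% grid
(step 5) at which at least 2 of 3 seeded replicates yield a correctly-typed
call with ≥ 50% reciprocal overlap.

The simulator is an idealization: real data add mapping artifacts,
genotyping errors in the normal, overdispersion, and uneven SNV spacing.
The QC filters (coverage bounds, mask intervals) exist for those, but the
measured thresholds characterize the statistical model, not any particular
sequencing pipeline.

## Limitations

- Allelic ratios are *relative* to the average ploidy through the totals
  `M, N`; with at-loci totals, large aberrant fractions compress all ratios
  slightly (library-wide totals can be supplied instead).
- Integer ASCN and whole-genome ploidy are not resolved; only relative
  haplotype ratios and event-specific purities are.
- Segmentation assumes independent loci; linked read or long-range phase
  information is not used.
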