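# Methods

## Feature construction

A placement covers 645 consecutive segregating sites: 128 windows of 10
SNPs, each sharing 5 SNPs with its neighbor (window *i* starts at SNP
5·*i*). SNP-delimited windows make the feature vector invariant to local
SNP density, at the cost of a variable physical footprint. Sites are
pre-filtered to minor allele count ≥ 3, which suppresses the part of the
site frequency spectrum where sequencing/simulation mismatch is worst;
windows therefore never contain monomorphic columns (asserted
defensively in `featurize`).

Per window, nine statistics in fixed row order: π̂ (mean pairwise
Hamming distance over all C(n,2) haplotype pairs — exact rational
arithmetic, testable against enumeration), H1 = Σpᵢ²,
H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ², H2/H1 with H2 = H1 − p₁², and the five
largest haplotype frequencies (zero-padded when fewer than five distinct
haplotypes exist). Two-dimensional features, when enabled, are the mean,
variance, skewness and kurtosis of pairwise r² between the 64
alternating non-overlapping windows (ids 0, 2, 4, …): all w_a·w_b
cross-window SNP pairs per ordered pair, and the C(10,2) = 45 distinct
within-window pairs on the diagonal, giving 64·65/2 = 2,080 unique
evaluations per moment, mirrored by symmetry. Moments are population
(biased) moments; kurtosis is non-excess (m₄/m₂²); a zero-variance pair
set reports (mean, 0, 0, 0). These conventions are choices — no
authority fixes them — and are frozen by tests.

Standardization is per (statistic, window) cell: training-set mean and
population SD, SD guarded to 1 (with a logged warning) for
zero-variance cells. Within cross-validation, standardization is
re-estimated inside each training fold to avoid leakage; the final
model freezes full-training-set moments. Granularity per cell matches
the functional-data convention of centering each curve coordinate;
per-statistic global standardization is the main alternative and would
change only scale profiles, not ranks.

## Wavelet representation

Curves of length p = 2^J are analysed with an orthonormal discrete
wavelet transform, Haar or Daubechies least-asymmetric (symlet), with
**periodic** boundary handling — the only mode that yields an exactly
orthonormal p→p map, hence exact Parseval and invertibility (tested at
1e-10). The symlet order defaults to 8 vanishing moments, a standard
choice for smooth reconstructions, and is configurable. The coefficient
segment is laid out fathers-first (2^{j0} of them) then mothers coarse
to fine, within level by location; regardless of the truncation level
j₀ the segment length is exactly p, so truncation changes the basis,
never the dimension. Candidate truncation levels are {0,…,J−2} — six at
p = 128. Two-dimensional blocks use the separable row-then-column
transform (W ⊗ W), flattened row-major.

## Penalized functional regression

With an orthonormal basis, the functional inner product
∫β(t)f(t)dt collapses to the Euclidean inner product of coefficient
vectors, so classification is a multinomial logit in ξ (symmetric
parameterization, no reference class) and parameter prediction a
multi-response linear model, both under the elastic-net penalty
λ(γ‖ζ‖₁ + (1−γ)‖ζ‖₂²).

Solvers are scikit-learn's. The penalty above is mapped exactly onto
sklearn's parameterization: for the classifier, l1_ratio = γ/(2−γ) and
C = 1/((2−γ)·n·λ) (the 2−γ factor absorbs sklearn's ½ on the quadratic
term; lbfgs at γ = 0, saga otherwise); for the predictor,
MultiTaskElasticNet with alpha = λ(2−γ)/(2n) and the same l1_ratio,
which makes the ℓ1 term a grouped (L2,1) lasso across responses — one λ
shared by all responses, consistent with jointly learning them — and
exact closed-form Ridge (alpha = λ) at γ = 0.

Model selection: stratified (classifier) or plain (predictor) 10-fold
CV over the (γ, j₀) grid, with a descending log-spaced λ path per
combination anchored at the glmnet-style smallest all-zero λ. The
winning λ uses the minimum-CV-error rule (not one-SE), matching
selection by highest fraction of correct classifications; ties prefer
larger λ (the path is scanned from the regularized end), then smaller
j₀ (smoother coefficient functions), then larger γ (sparser). The
winner is refit on the full training set. Fits at the extremes of the λ
path are allowed to stop at the iteration cap — only the refit winner
needs full convergence — so convergence warnings are suppressed inside
the path search.

At γ = 0 the fit is invariant to the orthonormal wavelet rotation, so
wavelet-domain ridge predictions equal raw-domain ridge predictions;
this is verified against independent direct fits and is deliberately
*not* true at γ > 0 — sparsity in the wavelet domain is the method's
point.

Responses s and f are log₁₀-scaled (their generative priors are
log-uniform) and T is log-scaled by default (configurable); all are
standardized to mean 0, SD 1 on the training set. Predictions are
back-transformed to the natural scale. Out-of-range inputs are not
clipped at prediction time — accuracy degrades outside the training
envelope — but a warning is logged when the input coefficient norm
exceeds 1.5× the training maximum.

## Scan and reporting

The placement slides one window (5 SNPs) per iteration; the classified
SNP is the median of the 5-SNP overlap between the two central windows
(0-based SNP offset 322 of the placement; an even overlap takes the
lower median). A non-neutral argmax is demoted to neutral when its
probability is ≤ 0.7 (ties break to neutral). Parameter predictions are
computed for every anchor when a predictor is supplied but reported
only on non-neutral calls unless `emit_all` is set. Regions shorter
than 645 filtered SNPs yield no records and a logged notice. Gene
summaries return the in-interval record with maximal non-neutral
probability, ties to the smallest position. Calibration tables use
sliding probability windows of width 0.05 at step 0.001 (the final
window closed so probability 1.0 is counted).

## Synthetic fixtures

The generators are explicitly not population-genetic simulations: no
coalescent, no recombination, no demography. They exist to make every
pipeline stage testable with known ground truth.

Haplotype fixtures build columns over a spatial "diversity profile":
baseline columns cycle five distinct square-wave templates of the
haplotype index at ~25% derived frequency (period five, so every
10-SNP window of a noiseless flat fixture carries the same column
multiset and identical haplotype spectra; heterozygosity sits below the
0.5 ceiling so crests have headroom). Inside a central Gaussian trough
(depth ∈ [0,1], width in SNPs) the leading round(0.9·n·depth)
haplotypes share a swept all-derived haplotype — low π, high H12 —
while the remainder keep template alleles so flanking diversity
survives; crest positions (two flanking Gaussian bumps at ±2.2 widths)
inject random intermediate-frequency columns that raise π above
baseline, the qualitative signature of adaptive introgression. Every
emitted column keeps minor allele count ≥ 3 (carrier count capped at
n−6; a repair pass restores any column degraded by flip noise), so the
MAC filter is a no-op on fixture output. Default sizes — 50 haplotypes,
645 SNPs, depth 0.9, width 80 SNPs — give one full placement with the
trough centered on the classified SNP.

Curve fixtures are class templates plus iid Gaussian noise, with
baseline statistic levels typical of a moderately diverse 10-SNP window
and trough/crest loading vectors encoding how each statistic responds.
When a response map is supplied, two latent amplitudes
u₁, u₂ ~ U(0.7, 1.3) scale the trough and crest components and the
responses are affine in (u₁, u₂) — an exactly linear ground truth in
curve space, enabling parameter-recovery tests with a known optimum.

The missing-data generator places ten contiguous non-overlapping blocks
of round(0.03·S) SNPs each by seeded rejection sampling (error after
10,000 failed placements), removing 30% of sites in total.

What passing these tests shows: the statistics, transform, solvers,
selection logic and scan mechanics are correct, and the models recover
structure they can represent. What they do not show: performance under
realistic linkage, demography, or background selection — that depends
on the user's training simulations.

## Numerical and testing notes

- Tolerances: orthonormality and round-trips at 1e-10; probability sums
  at 1e-12; oracle equivalence of ridge fits at 1e-4 (iterative logit)
  and 1e-6 (closed-form ridge).
- Permutation nulls are evaluated as the cross-validated held-out
  metric *within* the permuted dataset. Evaluating a permuted fit
  against the true labels is not a valid null on separable fixtures:
  the fit amplifies the permutation's chance overlap with the truth
  into a systematically right-or-wrong rule, making that statistic
  bimodal rather than binomial around chance.
- ms positions given as fractions are mapped to bp by rounding, with
  ties bumped +1 bp to preserve strict monotonicity. Mask intervals are
  BED-convention (0-based half-open); SNP positions 1-based.
- Recovery tests and the acceptance script use p = 16 curves and
  60–100 observations with reduced (γ, j₀) grids — sizes at which the
  full CV machinery runs in seconds while exercising every code path;
  the full grid (11 γ × 6 levels) is the library default.
- Known limitations: no cross-population statistics; dyadic p only (no
  padding); no built-in simulation of realistic genealogies; the
  1-based-window message convention and symmetric multinomial
  parameterization are fixed.
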