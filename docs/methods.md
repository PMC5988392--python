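# Methods

## Connectivity

Per-run connectivity is the matrix of pairwise Pearson correlations
between region time series, Fisher r-to-z transformed
(z = arctanh r, variance-stabilizing for averaging). Correlations are
clipped at ±(1 − 1e−7) before the transform so degenerate
near-duplicate regions stay finite; at realistic time-series lengths
the clip is never active. Run matrices are averaged (unweighted) to a
subject matrix and subject matrices to the group mean. Inputs must be
complete — there is no pairwise-complete mode — and an exactly constant
region time series is a hard error naming the region.

**Diagonal convention.** arctanh(1) is infinite, so the diagonal is set
to exactly 0 before any decomposition. This is the single largest
interpretive choice in the package: the decomposed object then
describes off-diagonal covariance structure only, and the eigenvalues
of a planted rank-K matrix are deflated by approximately
−Σₖλₖ/R (a near-uniform shift; see "Numerical behavior" below).

## Spectral decomposition and matching

For a symmetric matrix the singular value decomposition coincides with
the eigendecomposition up to signs, so `decompose` uses the symmetric
eigendecomposition, ranks components by |eigenvalue|, reports the
singular value |λ| and retains the eigenvalue's sign separately so the
matrix reconstructs exactly at full rank. Negative eigenvalues —
possible once the diagonal is zeroed — are thereby ranked by magnitude.
Loading columns carry a canonical sign (largest-magnitude entry
positive) before any matching.

Ten group components are retained by default; twenty subject
components are computed per subject and each group component k is
matched to the subject component maximizing |spatial Pearson r|
(matching is with replacement by default, since a one-to-one
constraint is not forced by the method; a greedy without-replacement
switch exists, and signed-r matching is available). Ties break toward
the lower subject index for determinism. The matched subject
eigenvalue is the subject's synchrony score for that network, and the
scaled eigenvalue divides by the eigenvalue matched to group
component 1, making scaled element 1 identically 1. The matched-index
table is written out so users can detect matching collisions.

Group reliability of the sign-aligned subject maps is a one-sample
t-test per region × component, Bonferroni familywise-corrected over
all region × component tests at α = 0.05. Zero-variance nonzero-mean
loadings are treated as infinitely reliable (t = ∞, p = 0). The
subcortical sign table summarizes the reliable loading sign per
structure/hemisphere/component, with "ns" below threshold.

## Behavior screening

Spearman rank correlation (average ranks for ties) accommodates
non-normal score distributions; p-values use the large-sample t
approximation, and 95% CIs come from a seeded percentile bootstrap
over paired resamples (default 1,000 resamples; a Fisher-z analytic CI
would be a straightforward switch but percentile bootstrap makes no
distributional assumption). A result is *significant* only when its CI
excludes zero **and** its p survives multiple-comparison correction
over the full measure × component family — Benjamini–Hochberg by
default, Bonferroni as a switch. Scaled-eigenvalue screening excludes
component 1 (identically 1). Minimum sample size is 5 pairs (the
point at which ranks are meaningful; the large-sample p is of course
crude there and the bootstrap is preferred).

## Interaction model

For k screened components, all 2^k subsets are enumerated in
(size, lexicographic) order; the empty subset is the intercept slot,
so the 2^k count decomposes into one unpenalized intercept plus
2^k − 1 candidate product features. Feature S is Πₖ∈S λₖ per subject.
Features are standardized to zero mean / unit SD using training
statistics only; the LASSO penalty is selected by seeded 10-fold CV
under the minimum-MSE rule, and coefficients are reported
back-transformed to the original feature scale. Evaluation is the
Pearson correlation between predicted and measured scores in the
held-out partition (Spearman is a one-line switch); a fully shrunk
model yields constant predictions and an explicitly flagged undefined
r rather than an exception.

Screening, standardization and penalty selection consume training rows
only; the test partition is untouched until evaluation (enforced by a
poisoning test). The 70/30 split is a seeded uniform partition,
emitted in the report for exact reuse.

Which eigenvalue form enters the products follows the screened form:
unscaled screening → unscaled products; for the union mode used for
flexibility-style targets, component 1 enters unscaled and components
2+ enter scaled.

## Synthetic cohorts

The generator emulates the study's data structure with the minimal
model under which the eigen-analysis is well-posed and recoverable:

- **Connectivity**: Cᵢ = Σₖ λᵢₖ wₖ wₖᵀ + Eᵢ in Fisher-z space, diagonal
  zeroed; Eᵢ symmetric with i.i.d. N(0, σ_noise) off-diagonal entries
  (default σ_noise = 0.05, a visually plausible off-diagonal jitter at
  desk scale).
- **Loadings** wₖ: K random vectors smoothed along the region index
  (Gaussian kernel, σ = 2 regions, circular boundary) and
  orthonormalized by QR. Smoothing gives spatial structure and
  overlapping support — most regions load on several components — and
  exact orthogonality makes planted-vs-recovered comparisons exact,
  although real component maps are only orthogonal post hoc.
- **Subject spectra**: λᵢₖ = gₖ·exp(sₖ zᵢₖ), zᵢₖ ~ N(0,1) — log-normal
  around a strictly decreasing group spectrum gₖ = 6.0·0.82^(k−1),
  guaranteeing positivity. The log-scale SD grows with component order
  (sₖ = 0.08 + 0.012(k−1)), reproducing the qualitative pattern that
  between-subject variability increases down the component hierarchy.
  No empirical estimate of this dispersion exists, so these defaults
  are calibration choices, exposed in the configuration.
- **Time series** (alternative output): X = W·diag(√λ)·S + σ_noise·E
  with independent standard-normal S, E per run.
- **Behavior**: yᵢ = intercept + Σₖ βₖλᵢₖ + Σ_S γ_S Πₖ∈S λᵢₖ + ε.
  All-zero weights give pure-noise null measures. Target correlation
  strengths are planted analytically, not tuned: a Spearman target ρ
  maps to Pearson via r = 2 sin(πρ/6) (exact under a Gaussian copula;
  the log-normal eigenvalues at these σ are near-normal) and the
  residual SD is solved in closed form so each planted component's
  marginal correlation equals the target. Product terms are planted by
  signal-to-noise ratio using the exact log-normal product SD.

The default cohort is desk-scale with the study's shape: 200 subjects,
60 regions, K = 10, 4 runs, 240 timepoints, and a 12-measure battery
mirroring a standard cognition battery: fluid intelligence couples
positively to components 3–10 (marginal Spearman ≈ 0.12, the reported
correlation band), cognitive flexibility and processing speed couple
negatively to the global component 1 — which simultaneously induces
their positive correlations with scaled eigenvalues 2–10, since
scaling divides by λ₁ — working/episodic memory and language
comprehension carry weak couplings, and the remaining six measures are
null.

**What the generator does not emulate**: hemodynamics, autocorrelated
noise, head motion, spatial geometry beyond 1-D smoothness, missing
data, and non-orthogonal/overcomplete network maps. Passing recovery
tests therefore demonstrates that the pipeline's estimators are
correct and calibrated under the stated generative model — not that
real fMRI satisfies that model.

## Numerical behavior and problem sizes

- **Diagonal deflation bound.** With diag(C) = 0, first-order
  perturbation gives λ̂ₖ ≈ λₖ − wₖᵀ D wₖ where D = diag(Σλwwᵀ); for
  delocalized loadings wₖᵀDwₖ ≈ Σⱼλⱼ/R. Zero-noise recovery error is
  therefore ~Σλ/(R·λ_min) relative. The spectral-recovery experiment
  runs at R = 400, K = 3, spectrum (5, 4, 3.2) — bound ≈ 1%, observed
  worst-case error < 2% — because at the desk-scale default R = 60,
  K = 10 the deflation itself is ~10–50% of the smaller eigenvalues
  and recovery of the raw spectrum is not meaningful at that
  tolerance.
- **LASSO convergence.** Nested eigenvalue products are strongly
  collinear; coordinate descent cannot converge tightly at the
  unpenalized end of the path in any reasonable budget. The CV alpha
  grid therefore stops at 1e−2 of the null-support penalty
  (`eps=1e-2`), with max_iter = 10,000 and tol = 1e−3; CV never
  selects the unstable extreme on such designs. Support monotonicity
  along the penalty path holds on well-conditioned designs but can be
  violated by drop/re-add events on collinear ones — an intrinsic
  property of the LASSO path, not a solver artifact.
- **Sizes used in tests and the acceptance script** (package choices):
  recovery and calibration cohorts use spectra drawn directly from the
  truth (the connectivity stage has its own recovery tests); ρ
  recovery uses 40 replicate n = 600 cohorts per level, support
  recovery 50 fits at n = 600 with 256 candidate subsets, null
  calibration 100 cohorts at n_test = 230, and the
  fluid-intelligence prediction analog 20 cohorts of n = 830 (split
  600/230) with population multiple correlation 0.25 planted across
  components 3–10.
- **Degenerate inputs**: constant targets, constant correlation
  inputs, zero-variance loadings and degenerate spectra raise typed
  errors; a fully shrunk model flags undefined r instead of raising.
- **Determinism**: every stochastic step draws from a stream derived
  from (master seed, stage tag) via CRC32 hashing, so identical
  configurations reproduce byte-identical artifacts.

## Known limitations

- Screening power at the planted default effect size (Spearman 0.12,
  n = 600) is intentionally in the partial-power regime: per-cohort
  recall of the planted 8-component block is roughly 2–6 of 8. This
  mirrors an effect-size regime where a single cohort's selected set
  is unstable — a caution that applies equally to real screens at
  r ≈ 0.1.
- With-replacement matching can assign one subject component to
  several group components when subject spectra are nearly degenerate;
  collisions are visible in the matched-index table.
- The selected-subset count of the LASSO depends on the CV fold seed
  and penalty grid; the package reports the count rather than
  asserting any particular value.
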