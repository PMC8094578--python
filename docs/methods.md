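# Methods

This note documents the statistical procedures implemented in `gammafs`,
the conventions and defaults chosen where several were defensible, what the
synthetic generators do and do not emulate, and the known limitations.

## The separability score

For a labeled sample with `K` classes and `p` features, each class `k` is
represented by the ellipsoid of its sample covariance matrix (denominator
`n − 1`; the eigendecomposition uses `numpy.linalg.eigh`, eigenvalues sorted
descending, round-off negatives clamped to zero, eigenvector signs fixed so
the first non-negligible component is positive — making results reproducible
across LAPACK builds). For a class pair, the score is the gap between the
class centres minus the two centre-to-border distances along the mean–mean
axis, divided by the normalisation `α = √(Σλ₁) + √(Σλ₂)`; the total is the
sum over all unordered pairs. Because the covariance eigenbasis is
orthonormal, the basis inverse needed for the border distance is taken as
the transpose (cheaper and numerically safer than a matrix inverse;
orthonormality is asserted to 1e-10 in tests).

Numerical edge cases, all deterministic:

* **Zero eigenvalue** in a border-distance term: if the direction has a
  component (>1e-12) along a null axis the term is +∞ and the border
  distance is 0 (the ellipsoid has no extent there); a 0/0 term is skipped.
  Both choices are the continuous limit λ → 0.
* **Coincident class centres** (gap ≤ 1e-12): the mean–mean direction is
  undefined; the first eigenvector of the first class is used. The numerator
  is then ≤ 0 for any direction, so the overlap sign is preserved.
* **Two point-mass classes** (α < 1e-12): raised as
  `DegenerateGeometryError` rather than returning ±∞ — the score is simply
  undefined there.
* Classes with fewer than 2 observations raise `DegenerateClassError`.

In one dimension the score reduces to `(|Δμ| − (s₁+s₂)) / (s₁+s₂)`, which
the tests use as a closed-form oracle; a literal, independently written
transcription of the defining formulas (explicit covariance loop,
`numpy.linalg.eig`, explicit matrix inverse) serves as a second oracle on
random instances.

## HRV features

A tachogram (all intervals in ms, one per beat) passing the quality filter
(no interval < 200 ms — misdetected R peak — and none > 3 s — undetected R
peak; series are excluded, never repaired) is mapped to 32 features:

* `m_0..m_10`, `sd_0..sd_10`: mean and sample SD (n−1) of the order-0..10
  successive differences, **on the seconds scale**;
* `SDANN, SDNNidx, SDSD, SDNN, RMSSD, pNN50, IRRR, HRV.index, TINN, MADRR`,
  **on the milliseconds scale**.

The units split follows the conventional reporting scales of these
quantities (mean RR ≈ 0.8 s; SDNN tens of ms) and is fixed in the feature
contract. Conventions for the measures the literature leaves open:

* **SDANN / SDNNidx** use 5-s windows (appropriate to 1-min records, where
  the classical 5-min windows would be empty): windows accumulate intervals
  until cumulative time ≥ 5 s; a final partial window is kept if it has ≥ 2
  intervals; a series yielding a single window gets SDANN = 0 with a warning.
* **pNN50** counts |successive difference| > 50 ms, as a percentage.
* **IRRR** is Q3 − Q1 with linearly interpolated (type-7) quantiles.
* **HRV.index / TINN** use a histogram with 7.8125 ms bins (1/128 s, the
  standard HRV sampling-grid convention) aligned at 0. HRV.index is the
  total count over the modal bin count. TINN is the base width `M − N` of
  the least-squares triangular fit whose peak is pinned at the modal bin
  centre and height, with `N`, `M` grid-searched over bin edges on either
  side. Both are convention-dependent: values from other toolkits will
  differ unless binning matches.

`extract_feature_vector` needs ≥ 12 intervals so the order-10 difference
still has two points.

## Selection, stability, evaluation

* **Bootstrap ranking**: B = 150 replicates by default; resampling is
  stratified by class (plain resampling can annihilate a rare class — AF
  prevalence in realistic cohorts is a few percent; `stratify=False`
  restores plain resampling with bounded redraws). Each feature is scored
  alone; the default scorer is the 1-D γ, with an orientation-free empirical
  AUC (`max(AUC, 1−AUC)`) as built-in baseline. The scorer registry accepts
  callables, so tree-ensemble importances can be plugged in without adding a
  dependency. Features are ranked by median score, descending; ties are
  broken by the fixed feature order so every ranking is a total order.
* **Stability**: the Kuncheva index of the replicate top-p′ sets,
  `(2/ω(ω−1)) Σ_{i<j} (|Sᵢ∩Sⱼ|p − p′²)/(p′(p−p′))`, bounded in [−1, 1],
  expectation 0 under random selection; p′ = p returns 0 by convention
  (every run trivially selects everything), p′ = 0 is rejected.
* **Evaluation**: linear-kernel soft-margin SVM with the regularization
  constant fixed at C = 1 (no tuning, no class weighting, no resampling of
  the minority class). Features are standardized *inside* each training
  fold; the raw features span five orders of magnitude (sd_10 ~ 10⁴ ms vs
  m_1 ~ 10⁻² s), which would otherwise dominate the linear kernel, and
  fitting the scaler per fold avoids leakage. Schemes: stratified 5-fold CV
  × 10 repeats (mean ± sd over the 50 fold evaluations) and, for a held-out
  set, B = 1000 bootstrap replicates of the validation data under a model
  fitted once per subset (median and IQR). Metrics: accuracy, sensitivity
  (positive class 1 = AF), specificity, and MCC with the usual zero-factor
  → 0 convention.

All stage seeds derive from one root seed by hashing the stage name, so
adding a stage never shifts the randomness of the others and every output is
bitwise reproducible from the root seed.

## Synthetic generators

The Gaussian generator draws labeled multivariate-normal class clouds; two
fixed 2-D scenarios (one separated, γ ≈ +0.26, one overlapping, γ ≈ −0.24)
expose their exact means and covariances so the population score can be
computed ellipsoid-directly as a deterministic anchor, and an
"informative features" preset (unit-variance classes differing by a chosen
effect size on the first k features) supports ranking-recovery experiments.

The tachogram simulator is a deliberate caricature, not a cardiac model.
Sinus rhythm = per-series base interval (850 ± 80 ms between series) + a
respiratory sinusoid (amplitude 35 ms ± 70% between series, period ≈ 4 s)
+ band-limited beat-to-beat jitter (AR(1), sd 15 ms, smoothness
heterogeneous across series) + a slow AR(1) drift (step 8 ms, ρ = 0.98)
standing in for low-frequency vasomotor variability. AF = serially
independent Gaussian draws (800 ms location, 150 ms spread, both
heterogeneous between series) — "irregularly irregular". Both rhythms get
R-peak localization error (sd 9 ms per series, ± 70%): white noise on beat
*times*, hence lag-1 anticorrelated on the intervals, which is amplified one
extra order by every successive difference exactly as detector noise is in
real recordings. All intervals are clipped into (200, 3000) ms so every
simulated series passes the quality filter by construction; clipping (not
rejection) keeps generation O(n) and its bias is negligible at the default
spreads. The AF spread must exceed 3× the NSR jitter (validated), keeping
the short-lag sd contrast of real AF/NSR cohorts.

The between-series heterogeneity is the load-bearing design choice: with a
homogeneous cohort nearly every feature separates the rhythms perfectly and
importance rankings degenerate to noise. With it, the long-range measures
(sd_0, SDNN, pNN50) inherit the respiration-depth and drift heterogeneity
while the short-lag difference features stay tight within class, so the
γ ranking concentrates on `sd_1..sd_4` — the qualitative pattern reported
for real rhythm cohorts. What the simulator does **not** emulate: ectopic
beats, non-Gaussian AF interval distributions, atrioventricular-node
physiology, circadian structure, or any dependence between consecutive AF
intervals. Passing tests therefore demonstrate correctness and the expected
qualitative behaviour of the pipeline, not clinical-grade AF-detector
performance.

## Problem sizes and defaults

The package defaults are the full study conditions (B = 150 ranking
replicates, 5×10 CV, B = 1000 validation replicates). The test and
acceptance runs use a 200-recording simulated cohort (100 NSR + 100 AF),
10⁵-point draws for the scenario sign checks, 1000 random 1-D instances for
the closed-form oracle, 200 instances for brute-force equivalence, 500 for
the invariance sweep, 2000 random collections for the consistency-index
chance correction, and 20 generator seeds for ranking recovery — sizes at
which every stochastic check is comfortably stable.

## Limitations

* The γ-metric summarises each class by one ellipsoid: multimodal or
  strongly non-elliptical classes can score as overlapping even when a
  non-linear classifier would separate them. No shrinkage or regularized
  covariance estimation is offered; with fewer observations than features in
  a class the sample covariance is singular and zero eigenvalues follow the
  degenerate-path rules above.
* Ranking is univariate: redundant features rank together, and
  complementary-but-individually-weak features rank low (no multivariate
  forward search over subsets is performed).
* TINN and HRV.index are histogram-convention-dependent by nature; treat
  absolute values as comparable only within one binning convention.
* The simulated cohort is far easier to classify than hospital data; the CV
  accuracy of 1.0 in the worked example says the pipeline works, not that AF
  detection is solved.
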