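# Methods

`ramanmuscle` implements the analysis chain used to quantify exercise-induced
muscle pathology in the dystrophin-null (*mdx*) mouse from in vivo fiber-optic
Raman spectra, together with a synthetic-data generator that reproduces the
structure of such a study so every stage can be validated by parameter
recovery. This note records the model, the defaults and why they were chosen,
the numerical decisions, and what the synthetic validation does and does not
demonstrate.

## The measurement and its structure

An intramuscular fiber-optic probe yields, per acquisition, intensity versus
wavenumber shift (cm⁻¹). Spectra are dominated by a broad tissue-fluorescence
background several times the height of the Raman bands, plus the optical
fiber's silica contribution below 900 cm⁻¹. The biological information lives
in the fingerprint region, 900–1800 cm⁻¹: α-helical protein bands (938, 1300,
amide I near 1654 cm⁻¹), phenylalanine (1000 cm⁻¹), and protein/phospholipid
CH₂ deformation (1444 cm⁻¹).

The design is hierarchical: four spectra per mouse (medial and lateral
gastrocnemius, both hindlimbs), 15 mice per group (exercised vs unexercised),
and for each exercised mouse a continuous covariate — the distance it chose to
run over 48 h of wheel access (mean ≈ 6.5 km, observed range 0.4–21.2 km).
Human dystrophic biopsy spectra form a third, smaller cohort (3 subjects,
several probe placements each) with no distance covariate.

## Preprocessing

Fixed stage order: **window → smooth → baseline-subtract → normalize**.

1. **Interpolation/windowing.** Linear interpolation onto a uniform grid over
   900–1800 cm⁻¹ (default step 1 cm⁻¹, 901 points). Linear interpolation is
   monotone and cannot overshoot; values are never extrapolated — a native
   axis not covering the window is an error, not a guess.
2. **Savitzky-Golay smoothing**, order 2, 9-point window. Interior points use
   the standard sliding least-squares polynomial; the first/last 4 points are
   refit on the window truncated at the array edge and evaluated in place.
   The filter is exact on polynomials up to its order, so genuine band shapes
   at this resolution are barely distorted while pixel noise is suppressed.
3. **airPLS baseline removal** (adaptive iteratively reweighted penalized
   least squares). Each sweep solves the weighted Whittaker problem
   min Σᵢ wᵢ(xᵢ−zᵢ)² + λ Σ(Δ²z)², then sets the weight of points above the
   baseline (Raman peaks) to zero and grows the weights of points below
   exponentially with iteration count and residual size, anchoring the two
   endpoints. Iteration stops when the 1-norm of the negative residuals drops
   below `tol·‖x‖₁` or at `max_iter`. Defaults λ = 1e5, tol = 1e-3,
   max_iter = 30 follow the algorithm's published recommendations; on a
   cubic fluorescence background with 14 cm⁻¹-wide unit-height bands the
   corrected signal recovers the injected peaks with RMSE < 2 % of the peak
   height. The solver uses a symmetric banded Cholesky factorization
   (`scipy.linalg.solveh_banded`; the penalty matrix is pentadiagonal), so a
   full cohort preprocesses in well under a second.
   Note the affine equivariance of the smoother holds exactly only at fixed
   sweep count: the stopping rule is scaled by ‖x‖₁, which an affine offset
   changes.
4. **SNV normalization**: per spectrum, subtract the mean and divide by the
   sample standard deviation (n−1 denominator), removing multiplicative
   scatter/coupling differences between probe placements. A spectrum with
   (numerically) zero spread is rejected as degenerate rather than divided
   by ~ε.

## PCA-fed LDA

Processed spectra are mean-centered and decomposed by PCA (full SVD; up to
min(n−1, p) components are computed). The first 10 PC score columns are
screened with per-PC two-sample Welch t-tests under Benjamini–Hochberg FDR
control at Q = 0.01; the rejected set feeds a two-class Fisher discriminant,
w ∝ S_w⁻¹(μ₂−μ₁), with the pooled within-class covariance S_w (a ridge of
1e-8·tr(S_w)/dim is added only if S_w is numerically singular, and logged).
The discriminant weights are back-projected through the PCA loadings to give
the **LDF loading**, a pseudo-spectrum whose positive bands associate with
the exercised group.

Decisions worth noting:

* **Welch rather than pooled-variance t** for screening: costs essentially
  nothing when variances are equal and is robust when they are not.
* **Screening happens at the spectrum level** (4 per mouse), deliberately;
  the hierarchical correction is applied once, at the final inference stage.
  Screening therefore sees pseudo-replicated data — acceptable for variable
  selection, not for inference, which is why the nested test exists.
* **Empty-selection fallback**: if no PC survives FDR, the single smallest-p
  PC is used so the pipeline completes, and a loud warning is logged. The
  fallback has a real cost under a true null: the end-to-end p-value then
  behaves like the minimum of 10 p-values, so ≈ 1−0.99¹⁰ ≈ 10 % of null runs
  reach p < .01 (measured 9 % over 200 null seeds). Any end-to-end
  "significance" obtained through the fallback path should be treated as
  exploratory; the pipeline's null-batch test pins this behavior.
* **Sign conventions** make fits bit-reproducible: each PCA loading's
  largest-magnitude element is positive; the LDF direction gives the second
  (exercised) group the higher mean score; scores are centered on the grand
  mean; weights are unit norm.

## Nested inference

The final group comparison is a one-way nested ANOVA with mouse as the random
factor: the between-group mean square is tested against the
between-mouse-within-group mean square on (1, S−2) degrees of freedom. With a
balanced design this is numerically identical to a two-sample t-test on
per-mouse mean scores (t² = F); unbalanced designs (missing acquisitions) are
handled by the general spectrum-level sums of squares, not by collapsing.
The intraclass correlation reported alongside (from the variance components,
with the unweighted-means n₀ for unbalanced data) quantifies how strongly the
four spectra of a mouse agree — on default synthetic cohorts it is ≈ 0.99,
which is exactly why spectrum-level inference would be invalid.

The distance association collapses scores to one mean per exercised mouse and
reports the Pearson r, r², two-sided p (t transform, n−2 df) and the
least-squares line. Collapsing first matters: on unbalanced data the
spectrum-level correlation differs, and a regression test guards the
collapse-then-correlate order. Tests are two-sided throughout.

## Windowed cosine similarity

Cohort mean spectra (of the SNV-processed rows) are compared window by
window: half-open intervals [low, low+100) from 900 cm⁻¹, the last window
closed at 1800 cm⁻¹, nine windows in all. Per window the cosine of the angle
between the two mean sub-vectors is reported. Cosine is scale-invariant,
which suits SNV-processed spectra whose absolute scale is already arbitrary.
No significance test is attached to similarity differences; none is defined
for this procedure, and the profiles are reported descriptively.

## The synthetic generator

Each subject's noiseless spectrum is
baseline(ν) + silica(ν) + Σ peaks(ν; subject effects), and each of its
spectra adds i.i.d. Gaussian noise. Components:

* **Peak library**: Gaussian bands; base muscle bands at 938, 1000, 1300,
  1444 cm⁻¹ and amide I at 1657 cm⁻¹ (amp 1.0, FWHM 25 cm⁻¹ — the dominant
  band); weaker exercise-responsive bands at 904, 930, 1025, 1045, 1057,
  1062, 1095, 1220, 1610, 1641 cm⁻¹ and α-helix bands at 951, 961 cm⁻¹.
  Sharp bands use FWHM 10–18 cm⁻¹, typical of dispersive tissue Raman.
* **Effects** (applied in the exercised and human groups): ×1.6 amplitude on
  the up-bands, ×0.5 on 951/961, and a fixed −4 cm⁻¹ shift of amide I
  (1657 → 1653 cm⁻¹), the α-helix→β-sheet signature of necrotic muscle. The
  1600–1700 cm⁻¹ band amplitudes were chosen so that the group-mean amide I
  maximum falls exactly on 1657/1653 on the 1 cm⁻¹ grid — the nearby 1610
  and 1641 cm⁻¹ bands must stay weak enough not to drag the composite
  maximum; this was verified on noiseless population means when the defaults
  were frozen.
* **Effect magnitude per subject**: u_s·(1 + β·d_s/6.5) with log-normal
  subject scatter u_s (σ = 0.2) and running distance d_s; β defaults to 0.5.
  The amide shift does not scale (a structural transition, not a graded
  amplitude), so the exercised-mean peak position stays crisp. Distances are
  log-normal (σ_log = 0.9, matching the ~50-fold observed spread), clipped
  to [0.4, 21.2] km, with the log-normal location solved numerically so the
  clipped mean equals the configured 6.5 km.
* **Baseline**: degree-3 polynomial in the normalized coordinate, ≈ 5–6×
  the tallest Raman band, plus a silica bump (850 cm⁻¹, FWHM 80) that the
  900 cm⁻¹ window cut removes — both exist precisely so the windowing and
  airPLS stages have real work to do.
* **Noise**: additive i.i.d. Gaussian, σ = 0.02 in peak units (SNR ≈ 50
  against amide I), plausible for 40 s of averaged in vivo acquisition. No
  Poisson shot noise, cosmic rays, detector drift, or wavelength-calibration
  error are modeled.

**What passing tests show — and don't.** Recovery of injected bands, the
amide maxima, correlation with the distance covariate and the
exercised-closer-to-human similarity ordering demonstrate that the *analysis
chain* is correct and sensitive under a faithful, favorable data-generating
model. They do not establish instrument-level realism: real spectra have
correlated noise, imperfect baselines, overlapping unmodeled bands and
between-session drift, so effect sizes measured here do not transfer to real
cohorts.

## Problem sizes and runtime

Defaults are desk scale: 120-spectrum cohorts preprocess in ≈ 0.15 s and the
whole pipeline runs in well under a second, so the test suite can afford
2000-replicate Monte-Carlo calibrations of the nested test and the FDR
screen, 20-seed recovery sweeps, and a 40-seed end-to-end null batch. The
nested-test power-monotonicity property is checked on simulated score sets
(400 replicates per effect level) rather than full pipeline runs, since the
property concerns the test itself.

## Known limitations

* Two-group LDA only; no multi-class extension, no cross-validated
  classification accuracy (the analysis quantifies discrimination and
  association, not held-out prediction).
* The FDR-screen fallback inflates end-to-end type-I error under a pure null
  (see above); interpret pipeline significance accordingly.
* Cosine-similarity profiles carry no inferential statement.
* The generator's human cohort is a synthetic stand-in sharing the exercised
  effect set; it emulates the *direction* of the mouse-vs-human comparison,
  not human tissue spectra.
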