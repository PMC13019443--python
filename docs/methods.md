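# Methods

## Problem setting

Spatially offset Raman spectroscopy (SORS) measures bone through intact
soft tissue by displacing the collection zone laterally from the
excitation spot; photons collected at larger offsets have, on average,
travelled deeper. Even so, a transcutaneous finger spectrum at a 6-mm
offset is a mixture dominated by skin, adipose and fluorescence. The
package's core method treats bone-signal recovery as supervised
regression: given paired training examples of transcutaneous spectra
(predictors, 6-mm offset) and exposed-bone spectra of the same subject and
anatomical site (responses, 3-mm offset), learn a linear map and apply it
to new subjects' transcutaneous measurements.

## PLS2 reconstruction model

Both matrices are mean-centered (no variance scaling — the wavenumber
channels share units and an explicit intercept absorbs the centering).
Multi-response partial least squares extracts latent components
sequentially; each X-weight direction maximizes covariance with the
(deflated) response under orthogonality constraints. The implementation of
record is SIMPLS (de Jong 1993): the weight vector of component *a* is the
dominant left singular vector of the deflated cross-product matrix
`S = Xcᵀ Yc`, scores are normalized, and `S` is deflated against an
orthonormal basis of X-loadings. A NIPALS variant is available behind a
flag; the two coincide for single-response problems and are cross-checked
against each other and against an external NIPALS implementation in the
tests. At full rank both reduce to the minimum-norm least-squares fit,
which the test suite verifies against a pseudoinverse oracle.

Prediction uses the augmented coefficient matrix `B̃` (intercept stacked on
`B`): `Ŷ = [1 | X] B̃`. Numerical guards: deflation vectors with norm below
1e−12 terminate extraction early (capping the component count with a
warning); constant predictor columns center to zero and thus carry zero
weight — an implicit column drop, warned about rather than silently
accepted; a fully constant X raises a degeneracy error.

### Choice of the number of components

The default for bone-spectrum reconstruction is A = 10 latent components,
fixed across all leave-one-subject-out folds for stability. A grouped
K-fold selector (folds defined by subject identity, K = 5 by default) is
provided for choosing A on new data; it minimizes the pooled held-out RMSE
over all response channels and breaks ties toward the smaller rank
(parsimony).

### Cross-validation protocol

Evaluation is leave-one-subject-out: every spectrum of one subject forms
the test fold while all other subjects' spectra train the model. Repeated
measurements of one specimen are strongly dependent, so subject-wise
splitting is the only honest protocol here; the acceptance suite
instruments the per-fold fits to prove no subject ever appears on both
sides, and separately verifies that a deliberately leaked variant scores
higher than the honest pipeline (so leakage would be detectable, not
silent).

## Spectral model and preprocessing

The working wavenumber axis is 800–1800 cm⁻¹ with 499 evenly spaced
points — the fingerprint region covering all bands the metrics use. This
range is a documented package convention; files on other axes are accepted.

Preprocessing is deliberately generic, since the method operates on
already-calibrated spectra: a fluorescence baseline is removed by an
iteratively reweighted polynomial fit (default degree 5, 20 iterations;
points above the current fit are clipped to it so the polynomial hugs
local minima and leaves peaks intact), and band normalization (unit
maximum inside a window) is available for display. Normalization is never
applied to PLS inputs by default — Pearson correlation, the reconstruction
score, is affine-invariant anyway, so the reported correlations do not
depend on display scaling.

## Raman bone-quality metrics

Five per-spectrum quantities: PO₄³⁻/CO₃²⁻ (mineral quality) and three
mineral-to-matrix ratios (PO₄³⁻/Amide III, PO₄³⁻/CH₂, PO₄³⁻/Amide I), plus
the CH₂ full width at half maximum (organic-matrix heterogeneity, cm⁻¹).
Band windows (cm⁻¹): PO₄ 930–980, CO₃ 1050–1100, Amide III 1215–1300, CH₂
1400–1500, Amide I 1595–1720 — standard bone-Raman assignments, fully
configurable. A band value is computed above a local linear baseline drawn
through the window-edge intensities; the default quantification is the
trapezoidal area (more noise-robust than peak height, which remains
available). FWHM interpolates the two half-maximum crossings linearly on
the grid after the same local baseline removal.

Group summaries aggregate to one value per subject before any class
statistic and report mean ± SEM with SEM = SD/√N (ddof = 1; a
single-subject class reports SD = SEM = 0 by convention). Class
comparisons default to a two-sided Mann–Whitney U test computed *exactly*
by enumerating all group assignments with mid-rank tie handling — the
group sizes here (≤ 11 per class) make enumeration instant, and the exact
test needs no normality assumption; a tie-corrected normal approximation
takes over for large groups, and Welch's t-test is available by flag. No
multiple-testing correction is applied; p-values are reported per metric.

## T-score prediction and WHO classification

One representative spectrum per subject (midshaft of the second digit's
proximal phalanx, position MM00, by convention) predicts the subject's
distal-radius DXA T-score via PLS regression under LOSO. The model rank is
searched over 1–15: for each candidate a full LOSO pass yields a pooled
RMSE_CV, the reported rank minimizes it (smallest-rank tie-break), and the
reported Pearson r and RMSE_CV come from that rank's held-out predictions.
Rank selection by pooled RMSE_CV (rather than re-selecting per fold) is
the package's default because it yields a single reportable model
complexity; per-fold reselection is a one-line loop on the same API.

WHO classes from predicted T-scores: Normal (T > −1), Osteopenia
(−2.5 < T ≤ −1, a band exactly 1.5 T-score units wide), Osteoporosis
(T ≤ −2.5); the boundary values −1 and −2.5 belong to the sicker class.
Per-class precision, sensitivity and specificity come from one-vs-rest
reductions of the 3×3 confusion matrix; accuracy uses the full cohort
denominator (TP+TN)/N. An undefined ratio (0/0, e.g. precision of a class
never predicted) is reported as null with a warning, never silently as 0.
ROC analysis uses the negated predicted T-score as the decision score
(higher = more diseased) — a continuous score is required to trace a
curve, and the predicted T-score is the natural one; the AUC equals the
Mann–Whitney U statistic normalized by n₁n₂ with half credit for ties,
verified exhaustively against pair enumeration in the tests.

## Synthetic cohort generator

Real paired cadaveric data are not publicly deposited, so the generator
produces cohorts with the structural features the pipeline relies on, with
known ground truth:

- **Bone spectra**: Gaussian bands at PO₄³⁻ 960/σ8, CO₃²⁻ 1070/σ10,
  Amide III 1250/σ25, CH₂ 1450/σ15, Amide I 1665/σ30 (center/σ in cm⁻¹).
  Mineral amplitudes scale linearly with T-score (PO₄ slope 0.085 per
  T-score unit, CO₃ 0.045, floored at 5% of nominal), so every
  mineral-to-matrix ratio *and* PO₄/CO₃ fall from Normal toward
  Osteoporosis; matrix-band widths inflate by 3% per negative T-score
  unit, so CH₂ FWHM rises as bone quality degrades. The slopes are
  generator conventions chosen to give clearly ordered but overlapping
  class distributions; only the ordering is load-bearing.
- **Soft tissue**: strong CH₂ (1450) and Amide I (1660), a lipid band
  (1300) and broad collagen features.
- **Mixing**: a transcutaneous spectrum is `f·bone + (1−f)·soft` plus a
  random quadratic fluorescence baseline and additive Gaussian noise
  (σ = 0.01 in units of the nominal phosphate peak height, i.e. ~1% shot
  noise after preprocessing). Bone fractions f(0 mm) = 0.05,
  f(3 mm) = 0.20, f(6 mm) = 0.40: the 6-mm channel is informative but
  soft-tissue dominated, as in practice; the values are conventions — no
  quantitative per-offset mixing fractions exist to calibrate against.
- **T-scores**: drawn per class from normal distributions truncated to
  the class's WHO interval, with class means ± SD anchored to the donor
  demographics (Normal 0.05 ± 0.45, Osteopenia −1.63 ± 0.38, Osteoporosis
  −4.19 ± 0.90); truncation keeps labels consistent with the WHO rule by
  construction. Default class sizes are 6/4/11 (total 21), matching the
  transcutaneous cadaveric cohort.
- **Randomness**: one global seed fans out through independent per-subject
  substreams (`numpy` SeedSequence spawning), so enlarging a cohort never
  perturbs earlier subjects, and identical seeds give bit-identical
  cohorts.

What the generator does **not** emulate: photon-migration physics (the
offset-depth relation is reduced to the monotone bone-fraction map),
detector artefacts, cosmic rays, inter-site anatomical variation beyond
lognormal amplitude jitter (subject-level σ = 0.08, site-level σ = 0.02),
skin pigmentation, and any nonlinearity between composition and T-score.
Passing tests therefore demonstrate that the pipeline recovers known
structure through realistic linear mixing, baselines and noise — not that
it would achieve the same numbers on human measurements.

## Problem sizes and numerical conventions

The default test and acceptance workloads use the 21-subject cohort with
three sites per subject (63 paired rows, 499 spectral points), 10 latent
components for reconstruction, and rank search 1–15 for T-score
regression; property suites use small random instances (≤ 12×8) where
exact oracles (pseudoinverse least squares, exhaustive pair enumeration,
exact rank enumeration) are cheap. Tolerances: score orthogonality and
internal consistency at 1e−8 relative; the full-rank OLS equivalence at
1e−5 relative (accumulated SVD round-off on ill-conditioned draws);
band-shape closed forms at grid resolution (~2 cm⁻¹ spacing). Ties in
rank selection and class comparisons break as documented above.

## Known limitations

- The reconstruction is linear; strongly nonlinear tissue effects would
  need kernel or learned extensions, which are out of scope.
- Exact Mann–Whitney enumeration is exponential in group size; it is
  gated to C(n₁+n₂, n₁) ≤ 20 000 and falls back to the asymptotic test.
- The confusion-matrix worked example fixes the unique matrix consistent
  with the published per-class table; on synthetic cohorts the pipeline's
  own matrices vary with seed and noise.
- `subtract_baseline` assumes a smooth (polynomial) background; structured
  backgrounds (etaloning, spikes) are out of scope.
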