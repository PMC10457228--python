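# Methods note

This note records the models implemented in `ramanmap`, the assumptions
behind them, the default parameters and why they were chosen, and what
the synthetic generator does and does not capture.

## Spectral model and water estimation

A preprocessed high-wavenumber spectrum is treated as a non-negative
mixture of a tissue CH-stretching profile and a water OH-stretching
band. The water mass fraction is estimated by the band-ratio method:

    ρ = A_OH / A_CH,   w = ρ / (ρ + R)

with A_OH the trapezoidal band area over 3350–3550 cm⁻¹, A_CH over
2910–2966 cm⁻¹, and R an instrument calibration constant (default 1.0,
configurable in `AnalysisConfig`). The estimate is clipped to [0, 1];
a non-positive CH area yields NaN and invalidates the pixel. Estimates
strictly above 0.88 are physically implausible for tissue and are
discarded as outliers (a value of exactly 0.88 is retained). Water maps
are smoothed with a 3×3 neighborhood average restricted to valid
pixels — invalid pixels are never imputed, and edge pixels average their
in-bounds neighbors.

Assumptions: the OH band in the 3350–3550 cm⁻¹ window is dominated by
water; the CH band in 2910–2966 cm⁻¹ is dominated by protein/lipid; both
areas scale linearly with concentration; R is constant across the map.

Tumor vs non-cancerous water values are compared with a two-sided
Mann-Whitney/Wilcoxon rank-sum test. The exact null distribution is used
when both groups have ≤ 10 tie-free observations, otherwise the normal
approximation with tie correction and no continuity correction. The
reported AUC is U/(n₁n₂), the probability (counting ties half) that a
random tumor pixel has higher water than a random non-cancerous pixel.

## Preprocessing

* **Cosmic-ray removal.** A channel is spike-suspect when it exceeds
  the rolling median (window 9, mirror padding) by more than 8 local
  rolling MADs of the residual. Suspect runs of at most 2 channels are
  replaced by linear interpolation of their neighbors; wider structures
  are left untouched because genuine Raman bands span more channels.
  A *local* MAD is used because shot noise is heteroscedastic across the
  spectrum; a global scale misfires near strong bands. Spike-free input
  is a fixed point and the operation is idempotent.
* **Background subtraction.** An iteratively clamped degree-3
  polynomial (fit over the full 2500–4000 cm⁻¹ range). After each fit,
  points more than one residual standard deviation above the fit are
  clamped to fit + dev before refitting; iteration stops when dev
  stabilizes (30 iterations, relative tolerance 1e-8). Clamping at
  fit + dev rather than at the fit itself avoids the systematic
  low bias of the naive scheme, whose fixed point cuts into peaks.
* **Quality gate.** Pixels whose mean intensity over 2700–3100 cm⁻¹ is
  below 5% of the overall mean are excluded. The overall mean is pooled
  over the valid tissue pixels of the whole dataset by default
  (`gate_scope="dataset"`); a per-map variant is available. The gate is
  applied after background subtraction so it measures Raman signal, not
  autofluorescence.

**Known limitation.** A full-range degree-3 baseline cannot be fully
orthogonal to the very broad OH band, so it absorbs a small,
nearly uniform slice of it: after preprocessing, water estimates carry a
systematic offset of about −0.04 with a spread of ~0.014, while the
pixel *ranking* against ground truth remains essentially perfect
(Spearman ≈ 0.99998 on noise-free maps). The downstream analyses
(rank-sum test, AUC, classification) are rank-based or
scale-standardized and are unaffected by this offset; absolute water
values should be interpreted with it in mind.

## CH-stretching classification

Spectra are restricted to 2800–3100 cm⁻¹ and corrected by EMSC: each
spectrum s is least-squares fit as

    s ≈ Σ_k d_k u^k + b·m + Σ_i c_i g_i

with reference m (mean model-set spectrum in the window), a linear
baseline in the scaled abscissa u, and a pure-water interferent g (the
OH band tail inside the window). The corrected spectrum
(s − baseline − Σ c_i g_i)/b is invariant to multiplicative scaling and
to adding any multiple of the interferent — this is what makes the
CH-region analysis independent of the water signal, verified to
< 1e-8 RMS. A fitted b below 1e-8 means the spectrum carries no signal
resembling the reference; such pixels raise `DegenerateSpectrumError`
(or are flagged invalid in batch mode). Corrected spectra are smoothed
with a Savitzky-Golay filter, order 3, window 11.

Classification is PCA-LDA: mean-centered PCA (no autoscaling) followed
by the Fisher discriminant direction w ∝ S_w⁻¹(μ₁ − μ₀) on the first p
component scores, oriented so tumor scores are higher. Scores are
standardized by the midpoint of the class means and the pooled
within-class standard deviation, so held-out scores from different
cross-validation folds live on a comparable scale before pooling. If
the within-class scatter matrix is singular, a small ridge
(1e-8 · trace/p) is added.

The component count p is chosen by leave-one-map-out cross-validation:
every map is held out in turn, the model is refit on the rest, held-out
scores are pooled, and the pooled AUC per candidate p (1 … 20 by
default) is maximized, ties broken toward the smallest p. Holding out
by *map* (and splitting model/test by *patient*) prevents within-map
and within-patient leakage. Folds whose training arm loses a class are
skipped with a warning; if the pooled held-out labels end up
single-class the selection is refused rather than silently reported.
The final model is refit once on the full model set at the chosen p and
evaluated a single time on the test maps; any patient overlap between
training and test raises an error.

ROC curves are built with one point per distinct score under the
score ≥ threshold → tumor rule, ties grouped, endpoints (0,0) and (1,1),
trapezoidal AUC (equal to the Mann-Whitney statistic). The operating
point maximizes the Youden index J = sensitivity + specificity − 1, with
ties resolved toward higher specificity, then lower threshold. The
false-positive breakdown reports, for each non-cancerous tissue type
present in the test set, the fraction of its spectra scored as tumor;
absent types are omitted rather than reported as zero.

## Synthetic generator

Each pixel spectrum is built from Gaussian CH bands (2850, 2885, 2930,
2960, 3060 cm⁻¹) with tissue-specific weights and a water OH band
(Gaussian, center 3400 cm⁻¹, FWHM 260 cm⁻¹). Components are scaled so
the CH profile has band area (1 − w) and the OH band area w·R inside the
respective quantification windows, which makes the band-ratio estimator
invert the model *exactly* on noise-free input — the generator and the
estimator are a matched forward/inverse pair by construction. The CH
profile is truncated above 3250 cm⁻¹ and the OH band below 3000 cm⁻¹ so
neither leaks into the other's quantification window, while the OH tail
still overlaps the 2800–3100 cm⁻¹ analysis window and gives the EMSC
water interferent real interference to remove.

Tissue realism: five non-tumor classes (connective, gland, cartilage,
muscle, necrosis) differ in their CH band weights; the tumor base
profile is exactly the centroid of the non-tumor weights, shifted by
δ · (less lipid CH₂, more protein CH₃ and olefinic =CH). δ = 0 is
therefore a genuine null in which no linear discriminant separates
tumor from the pool in expectation. Water fractions are drawn per pixel
from tissue-specific normals, all near 0.75 with large overlap (tumor
0.755 ± 0.055 vs e.g. connective 0.740 ± 0.060), yielding a pooled
water AUC around 0.56 — a statistically real but clinically weak
difference. Per-pixel band-weight jitter (5%), map-level weight scaling
(3%), signal-dependent shot noise (SNR 25), a smooth positive degree-3
autofluorescence background, and rare 1–2-channel cosmic rays (2 per
1000 spectra) complete the noise model. Map label geometry is generated
as smoothed random blobs; cohorts assign maps to patients round-robin so
the default 25 model + 9 test maps come from 17 + 5 disjoint patients.

Calibration of the defaults: the water statistics were fixed first from
the target pooled AUC (≈ 0.56); δ was then scanned under the full study
shape and frozen at 0.5, where the validation AUC across seeds is
0.79–0.92 (mean ≈ 0.86) — a moderate separation that keeps the
water-vs-CH ordering qualitative rather than trivial — and the chosen
PC count stays well above 1.

Limitations: bands are ideal Gaussians (no Fermi resonance shoulders or
asymmetry); water appears as a single OH band with fixed shape (no
bound/free water distinction, no NH contribution); the autofluorescence
is a smooth polynomial; spectra are clipped at zero, so at very low SNR
the noise is not strictly Gaussian; and the annotation masks are exact
(no histopathology registration error). Absolute water values inherit
the ≈ −0.04 baseline offset discussed above.

## Numerical choices

* Trapezoidal integration for band areas; abscissas rescaled to [−1, 1]
  for all polynomial fits (conditioning).
* EMSC solved by `numpy.linalg.lstsq` per batch; design matrix rank is
  checked at construction.
* PCA via scikit-learn (deterministic full SVD at these sizes); in
  cross-validation the PCA is fit once per fold at the maximum p and
  truncated per candidate, which is mathematically identical to
  refitting per p and far cheaper.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence.spawn`, one independent stream per map;
  identical seeds reproduce results and stage hashes bit-for-bit.
* JSON model serialization is text-only; HDF5 is used only for map
  containers.
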