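# Methods

## Scope and model

`ftirquant` implements single-response partial least squares (PLS1)
calibration of mid-IR absorbance spectra against analyte concentrations,
with the preprocessing operators standard in chemometric practice. The
underlying physical model is Beer–Lambert additivity: the absorbance of a
dried extract film is, to first order, a linear superposition of
concentration-weighted pure-component profiles plus a matrix background,
corrupted by additive baseline drift, a multiplicative scatter factor and
detector noise. Preprocessing removes the nuisance terms; PLS resolves
the overlapping component profiles.

All concentrations are in **mg per 500 µl extract aliquot** throughout
(the unit in which reference values and SEP are reported). Wavenumber
axes are stored ascending internally and written descending (IR display
convention); one canonical in-memory order avoids sign errors in
derivative spectra.

## Preprocessing operators

* **Offset correction**: subtract each spectrum's mean intensity from
  every point. Removes constant offsets even when only a narrow window
  is retained downstream; idempotent.
* **Linear baseline** (`baseline_linear`): subtract, per spectrum, the
  piecewise-linear function through the spectrum's values at ≥2 anchor
  wavenumbers (snapped to the nearest grid points; default anchors are
  the region endpoints). This is a documented, deterministic stand-in
  for the interactive baseline tools of commercial packages, whose
  algorithms are unpublished; a reproducible pipeline cannot depend on
  an interactive step.
* **Savitzky–Golay** (`savgol`): local least-squares polynomial
  smoothing/differentiation. Window default 9 points, polynomial order
  default 3 (cubic supports first and second derivatives; the classic
  chemometric choice), derivative ∈ {0, 1, 2}, scaled by the grid
  spacing to per-cm⁻¹ units. Requires a uniform grid (relative spacing
  tolerance 1e-9). Edges are computed from asymmetric polynomial fits
  rather than truncated, and the half-window of columns at each end is
  flagged; flagged columns are dropped from the final design matrix by
  default (`drop_edges`) so edge artifacts never enter calibration while
  matrix width changes stay explicit.
* **SNV**: per-spectrum standardization (subtract row mean, divide by
  the **sample** standard deviation, n−1 denominator — the convention is
  pinned so results are reproducible across implementations). Removes
  multiplicative scatter from particle-size/dispersion effects. A
  constant spectrum has no defined SNV and raises an error.
* **Region selection**: keep grid columns inside a union of
  (high, low) cm⁻¹ windows, bounds inclusive, order preserved. Typical
  windows: 2000–650, 1500–980, 1500–900 cm⁻¹. The analyte-to-window
  pairing is configurable per analyte; the default used in examples and
  tests is 1500–900 cm⁻¹ for all four properties.

Default step order: baseline/offset → derivative → SNV → region
selection. Derivatives amplify noise which SNV then renormalizes, and
cutting regions last keeps filter edge effects outside the kept windows.
Any other order can be configured per recipe.

## PLS1 (NIPALS)

Columns are mean-centered, never autoscaled: spectra share units and SNV
has already normalized the rows, so unit-variance scaling would only
inflate noise wavelengths. With a single response the NIPALS weight per
component is closed form (w ∝ Xᵀy), so there is no iterative loop, no
convergence tolerance and no random initialization anywhere — models are
bit-reproducible. X is deflated after each component; the regression
vector is b = W(PᵀW)⁻¹q in centered variable space.

Numerical details:

* Component extraction stops early if the residual covariance ‖Xᵀy‖
  falls below 1e-12 of the first component's (response exhausted, e.g.
  noiseless low-rank data); remaining components would only amplify
  round-off. The effective count is recorded in `n_components_`.
* `_coef_for(k)` reconstructs the regression vector for any component
  count k ≤ n_components_ from the stored W, P, q. Because components
  are nested under deflation, these coefficients are **bit-identical**
  to refitting from scratch with `n_components=k` (the cross-validation
  exploits this; contiguous array copies keep BLAS results independent
  of memory layout).
* Negative concentration predictions are returned as-is and flagged
  (`below_zero_flags`); clipping would bias SEP and hide diagnostics.

## Model selection and quality metrics

* **SEP** = √(Σ(ŷᵢ−yᵢ)²/n) on pooled held-out predictions. The
  denominator is **n**, not n−1 — pinned and documented so reported
  values are unambiguous.
* **Cross-validation**: leave-one-out by default (deterministic, the
  classic choice at these sample sizes); k-fold available with a
  mandatory seed. Each fold is fitted once at the maximal component
  count and evaluated at every smaller count (exactly equivalent to
  refitting, see above), and SEP is computed once per count on the
  pooled held-out residuals.
* **Optimal LV count**: the smallest count attaining the minimal SEP
  (ties break toward fewer components, guarding against overfitting).
* **Explained variance** (R²·100) and **Pearson r** are computed on the
  cross-validated predictions by default — the honest figure for
  predictive use; training-reconstruction metrics are available via
  `training_metrics=True`.
* **QC gate**: strictly `SEP% < 15` (SEP as percent of the property
  mean) yields `QUANTIFY`; at or above the limit the model is
  `ESTIMATE_ONLY`. The boundary is pinned strict: 14.999 → QUANTIFY,
  15.0 → ESTIMATE_ONLY.
* **Declaration comparison**: predicted total content, converted from mg
  per aliquot to mg per dose by an explicitly supplied factor (the unit
  bridge depends on extraction bookkeeping and is never guessed), as a
  percentage of the declared content; the "conforms" band defaults to
  ±20 % and is configurable.

## Synthetic data generator

Each simulated spectrum is

    x(ν) = g · [ Σ_k c_k s_k(ν) + m·M(ν) + α + β·ν ] + ε(ν)

with invented pure-component profiles s_k (5–6 Gaussian/Lorentzian bands
per analyte in 1800–900 cm⁻¹, deliberately overlapping pairwise within
1500–900 cm⁻¹ — overlap is the phenomenon PLS must resolve), a
matrix background M (broad and sharp sugar/protein-like features), and
per-sample draws of matrix strength m, drift (α, β), scatter g and
Gaussian noise ε. The default grid is 4000–650 cm⁻¹ at 2 cm⁻¹ (a typical
FT-IR working resolution; configurable).

The sampling plan emulates a standard-addition calibration: per
replicate, `n_base` unspiked base aliquots (base levels jittered ±35 % to
mimic different preparations), single-standard spikes of each analyte at
each volume of a 0.244 mg mL⁻¹ stock, and three two-analyte
"fractionated" aliquots emulated by zeroing one analyte (only the
concentration structure matters to calibration, not the chromatography
that would produce it). Sample count =
`n_replicates·(n_base + 3·n_volumes + 3)`; the default design
5·(4 + 3·20 + 3) = **335** samples, 25–500 µl spikes in 25 µl steps.
Ground-truth concentrations are exact (no reference-measurement error),
separating method error from reference error in tests.

Default noise model (all artifact choices, stated once and frozen):
noise SD 0.0015 AU, drift intercept ±0.01 AU, drift slope ±5·10⁻⁶
AU/cm⁻¹, scatter 0.97–1.03, matrix strength 0.95–1.05.

Two generator-design constraints deserve emphasis because they encode
the method's own validity conditions rather than free parameters:

* **Matrix dominance.** The analytes are minor constituents (~10 % of
  the absorbance); the matrix dominates every spectrum's variance. This
  is both physically realistic for a dry extract film and required for
  SNV to act as an approximately linear correction — when analyte bands
  dominate the row variance, SNV couples the scale of each spectrum to
  its own analyte content and linear calibration degrades. The residual
  analyte-to-matrix ratio ambiguity after SNV is the dominant error
  source in the simulation, which is why per-aliquot matrix variation is
  kept at ±5 %.
* **In-domain validation.** Held-out samples (`generate_prediction_set`)
  are supplement-like: a jittered base extract plus one random standard
  spike, so every held-out concentration vector lies inside the
  calibrated domain. A calibration must never be asked to extrapolate;
  drawing all three analytes independently at their maxima would produce
  total loads ~2× beyond anything calibrated.

An optional red-clover-like **interferent** (bands riding on the analyte
windows, concentration drawn uncorrelated with the analytes) models
co-formulated extracts. `interference_sweep` measures mean
cross-validated SEP% of the total-isoflavone model across seeds at
increasing interferent levels on a scaled-down design (37 samples,
10-seed averages; defaults 0, 0.3, 0.6 mg-per-500 µl-equivalent —
loads comparable to a co-formulated extract). PLS absorbs a spectrally
distinct interferent at low levels by spending latent variables on it;
degradation becomes substantial once the interferent rivals the analyte
signal, which is the mechanism by which a supplement containing a second
isoflavone source can deviate from its declaration.

### What the simulator does and does not show

Passing the closed-loop tests demonstrates that the implementation
correctly recovers known concentrations from data satisfying the
method's assumptions (linear mixing, multiplicative scatter, smooth
drift, matrix-dominated spectra, in-domain prediction). It does **not**
demonstrate performance on real instrument data, which additionally has
non-Gaussian baselines, water-vapor and CO₂ lines, ATR penetration-depth
dispersion, detector nonlinearity and reference (HPLC) error — none of
which are modeled. Real calibrations should expect SEP% several times
larger than the simulation's.

## Problem sizes

Test-suite and acceptance-script runs use the full 335-sample default
design with leave-one-out cross-validation and up to 12 latent variables
(a few seconds per analyte), 60 held-out samples, and 10-seed
interference sweeps on the 37-sample reduced design — sizes chosen so a
complete run stays interactive on a laptop while the LV-selection curve
is well resolved.

## Known limitations

* The JCAMP-DX support is a deliberate 4.24 subset: AFFN-encoded
  `(X++(Y..Y))`, uniform grids, factors applied — no DIFDUP/PAC/SQZ
  compression.
* The linear anchored baseline is a stand-in for proprietary interactive
  baseline correction; no asymmetric-least-squares or polynomial
  baselines are provided.
* No outlier diagnostics (leverage, Q residuals), no per-prediction
  uncertainty intervals, no PLS2/O-PLS variants, no replicate-aware CV.
* The two-level QC verdict (QUANTIFY / ESTIMATE_ONLY) encodes the
  common practice of still using above-limit models for rough estimates;
  the 15 % limit itself is the conventional regulatory threshold, not a
  statistically derived quantity.
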