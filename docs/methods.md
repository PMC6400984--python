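# Methods

This note documents the models, numerical choices and limitations of
`paddysma`. Everything quantitative stated here is computed by the
test suite or the example scripts; nothing is asserted beyond what the
code reproduces.

## Radiometric calibration

The empirical-line model assumes a per-band affine sensor response,
`ρ_λ = DN_λ·Gain_λ + Offset_λ`. Gains and offsets are the ordinary
least-squares solution of nominal reflectance on panel-mean DN over
the calibration panels (≥ 2 required; four by default, nominals 0.06,
0.24, 0.48, 1.0 treated as wavelength-constant, with per-band nominal
tables accepted through `CalibrationTargetSet`). The panel statistic
is the arithmetic mean of the DNs in the panel rectangle, matching the
least-squares formulation on representative panel values.

Calibrated reflectance is **not clipped** to [0, 1]. With noisy DNs,
clipping would bias band ratios (hence every VI) and the unmixing
residuals; instead `calibration_qc` reports the out-of-range fraction
per band. Each band is fitted independently.

## Band resampling of endmember spectra

Continuous spectra are reduced to camera bands by averaging over the
closed interval center ± width/2 (± 5 nm for the 10-nm bands). The
average is the exact trapezoid integral of the piecewise-linear
spectrum, so it is linear in the spectrum, exact for linear segments,
and correct on non-uniform grids. No spectral-response-function
weighting is applied: the bands are treated as ideal flat 10-nm
windows. A coverage gap raises an error naming the offending band.
All six bands enter unmixing by default (900 nm is used by no VI);
`EndmemberLibrary.subset_bands` exposes band subsets for sensitivity
analysis.

## FCLS unmixing

Per pixel, abundances minimize `‖ρ − Eᵀa‖₂` subject to `a ≥ 0` and
`Σa = 1`. The sum-to-one constraint is imposed by augmenting the
design with a weighted row `δ·1ᵀa = δ`, `δ = 10³·max|E|`, and solving
the augmented problem with the Lawson–Hanson non-negative
least-squares active-set algorithm (`scipy.optimize.nnls`); the
residual slack in the sum (order δ⁻²) is removed by renormalizing.
Correctness is gated on optimality, not on solver identity: tests
verify the attained objective never exceeds the minimum of an
exhaustive simplex-grid search (step 0.01 for 3 endmembers, 0.05 for
6 — the one-sided bound is valid at any grid resolution) and that the
solution matches the sum-to-one-only least-squares solution whenever
that solution is feasible. Degenerate pixels whose NNLS solution is
identically zero fall back to the uniform simplex center. Reflectance
values outside [0, 1] are passed to the solver unmodified; constraints
apply to abundances only. Pixels are independent — no spatial
regularization.

Plot-level abundance is the arithmetic mean of per-pixel abundances
over the plot rectangle (not the unmixing of the mean spectrum),
mirroring how plot-level reflectance and VIs are averaged; leaf and
panicle abundances sum their top and bottom layers, `Abd_L = TL + BL`,
`Abd_P = TP + BP`, `Abd_L-P = Abd_L − Abd_P`.

## Vegetation indices

The registry holds the ten tested indices over ρ490…ρ800. Two
deliberate conventions:

* **VARI** is implemented as the green–red normalized difference,
  `(ρ550 − ρ670)/(ρ550 + ρ670)`, without the blue term of the
  canonical atmospherically-resistant formulation — matching the
  variant this analysis convention uses.
* Indices are computed **per pixel first**, then averaged over the
  plot rectangle. Pixels whose denominator magnitude is below 1e-9
  (e.g. MTCI where ρ720 ≈ ρ670 on soil) are masked and excluded from
  the plot mean; the invalid fraction is reported per plot.

## Yield statistics

Yield screening uses the Shapiro–Wilk test (reject normality at
p < 0.05), Pearson correlation with two-sided t-test flags (** p<0.01,
* p<0.05), and simple linear regression reporting
`adjusted R² = 1 − (1−R²)(n−1)/(n−2)`, `RMSE = √(Σresid²/n)` and the
F-test p (identical to the slope t-test for one predictor). No
multiple-testing correction is applied across the VI × mode grid;
flags are per test. Plot exclusion is manual (`exclude_plots`),
default none.

LOOCV aggregates follow the convention `Coef = mean Coefᵢ`,
`R² = mean Rᵢ²`, `RMSE = √(mean Eᵢ²)`. **Rᵢ² is the training
coefficient of determination of fold i** — with a single held-out
sample no validation R² exists — so the aggregate R² is optimistic;
the held-out RMSE is the honest error measure. The full-data F-test p
is reported alongside the CV aggregates, labelled as such.

## Synthetic scenes

The generator emulates the study design so every stage has ground
truth: 24 plots = 8 nitrogen levels × 3 replicates, randomly placed on
a 4 × 6 grid of 150 × 120 px rectangles (18 000 px each) separated by
soil ridges, four uniform calibration panels, DN noise sd 2, per-band
gains ~0.001 and small offsets.

**Endmember spectra** are smooth PCHIP curves through fixed anchors
with seeded smooth multiplicative jitter (≤ ~1.5%), encoding the
qualitative orderings of measured paddy spectra: leaf blue ≈ 0.07 vs
panicle ≈ 0.05, panicle red above leaf red, leaf NIR well above
panicle NIR, bottom layers darker than top everywhere (BL NIR > BP
NIR), and wet soil below dry soil at all wavelengths. The jitter
amplitude is far below every inter-endmember margin, so the orderings
hold for every seed. Two structural choices matter downstream:

* BL is *not* a scaled copy of TL — its NIR is relatively darker — so
  the top/bottom leaf balance moves red-edge indices.
* Panicles depress absolute NIR and raise red, but their red-edge
  chromatic ratio is set to the canopy mean (NDRE(TP) = NDRE(BP) ≈
  0.45). Early-heading panicles are still green; the consequence is
  that NDRE responds to canopy greenness rather than to panicle
  fraction, while the panicle signal reaches yield through the
  abundance terms. This is what makes VI·(Abd_L − Abd_P) the
  correctly specified predictor by construction.

**Abundances.** Per plot with nitrogen index u = level/7: panicle
share `p(u) = 0.005 + 0.155·u²` (population mean ≈ 0.06, range within
0.00–0.33), soil share 0.01 inside plots, leaf the remainder
(population mean ≈ 0.93, range within 0.64–1.00). A greenness latent
`C = 0.60 + 0.10·u + N(0, 0.05)` (clipped to [0.40, 0.90]) splits
leaf into TL = C·leaf and BL = (1−C)·leaf; panicle splits 0.7/0.3
top/bottom. Per-pixel abundances are the softmax of log plot means
plus spatially smoothed Gaussian fields (sd 0.25, smoothing σ = 2 px),
which guarantees non-negativity and exact sum-to-one while producing
between- and within-plot heterogeneity. Ridges are soil-dominated
(DS/WS ≈ 0.55/0.40). Panel rectangles are overwritten with their flat
nominal reflectance after mixing.

**Yield.** `yield = β₀ + β₁·C·(Abd_L − Abd_P) + ε` with β₀ = −0.32,
β₁ = 7.0, ε ~ N(0, 0.15), chosen once so the yield population has
mean ≈ 3.6 and CV ≈ 12% on the study's scale (the source reports no
yield units; values are treated as unitless on that 2.7–4.5 scale).
Yield is driven by greenness times the leaf–panicle balance, not by
panicle abundance alone, so the abundance-weighted index family has a
recoverable target.

All stochastic draws derive from one `numpy` Generator seeded by the
scene config; a scene is a pure function of its configuration.

### What the generator does not emulate

Linear mixing is exact in the synthetic scenes (no multiple
scattering, BRDF, shadowing or co-registration error), endmember
spectra are spatially invariant, DN noise is Gaussian and band
independent, and there is no NIR saturation. Consequences worth
knowing: plot-level abundance recovery (MAE ≈ 0.01 at DN noise sd 2,
bias-dominated by the non-negativity constraint acting on near-zero
panicle/soil abundances) is an upper bound on real-data performance;
and plain NDVI can rank above the abundance-weighted indices on
synthetic scenes because the saturation that weakens NDVI over dense
real canopies is absent. Passing tests demonstrate the pipeline's
correctness and the qualitative panicle-correction mechanism, not
field-level accuracy.

## Problem sizes used in tests

Unit and property tests run on reduced scenes (24 plots of 24 × 20 or
40 × 30 px) whose plot-mean statistics are converged far below the
effect sizes involved; the end-to-end abundance-recovery check runs
one full default scene (24 × 18 000 px, ~534k pixels unmixed in a few
seconds via the active-set solver), and the correlation-pattern check
runs the full pipeline on 20 seeded scenes at 40 × 30 px per plot.

## Known limitations

* The FCLS solver loops per pixel in Python around a C active-set
  kernel (~10 µs/pixel); very large mosaics would want a blocked or
  multi-process driver.
* With six endmembers in six bands the soil pair (DS, WS) is close to
  collinear; the sum-to-one constraint keeps the split identifiable,
  but per-pixel DS/WS estimates are the noisiest planes. Leaf and
  panicle aggregates are robust to this.
* Raster outputs are plain multi-band float32 TIFFs with JSON metadata
  in the description tag — adequate for the analysis, but without
  georeferencing tags.
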