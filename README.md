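# paddysma

Spectral mixture analysis and abundance-weighted vegetation indices for
UAV-based rice yield estimation.

## The problem

Rice yield can be estimated from canopy reflectance, but at heading
stage the panicles emerging into the sensor's field of view mix their
spectra into every pixel and weaken the usual vegetation-index (VI)
regressions. `paddysma` implements the full analysis chain that
addresses this for six-band (490/550/670/720/800/900 nm, 10 nm wide)
multispectral imagery of small nitrogen-trial plots:

1. **Empirical-line calibration** — per-band affine DN→reflectance
   models `ρ_λ = DN_λ·Gain_λ + Offset_λ` fitted by least squares over
   ground panels of nominal reflectance 0.06 / 0.24 / 0.48 / 1.0.
2. **Fully constrained least-squares (FCLS) unmixing** — each pixel
   spectrum is decomposed as `ρ_λ = Σᵢ Abdᵢ·ρ_λ(i) + e` over six
   endmembers (top/bottom-layer leaf TL/BL, top/bottom-layer panicle
   TP/BP, dry/wet soil DS/WS) with `0 ≤ Abdᵢ ≤ 1` and `Σ Abdᵢ = 1`.
   Endmember references come from continuous field spectra averaged
   over each camera band.
3. **Vegetation indices** — the ten standard indices (NDVI, NDRE,
   GNDVI, SR, CI_rededge, CI_green, MTCI, EVI, EVI2, VARI) computed per
   pixel and averaged over each plot rectangle.
4. **Abundance-weighted yield models** — plot leaf abundance
   `Abd_L = TL+BL`, panicle abundance `Abd_P = TP+BP`, and the four
   predictor families VI, VI·Abd_L, VI·Abd_P and VI·(Abd_L−Abd_P),
   screened by Pearson correlation, fitted by simple regression
   (adjusted R², RMSE, p), and finalized with leave-one-out
   cross-validation aggregated as `Coef = mean Coefᵢ`, `R² = mean Rᵢ²`,
   `RMSE = √(mean Eᵢ²)`.

Because the original field campaign data are not public, the package
ships a first-class **synthetic scene generator** that reproduces the
study design — 24 plots (8 nitrogen levels × 3 replicates), ~18 000
pixels per plot rectangle, calibration panels, seeded endmember
spectra, and yields with population mean ≈ 3.6 and CV ≈ 12% — with
exact ground truth for every stage, so the entire pipeline is testable
end to end.

It is intended for researchers in crop phenotyping / agricultural
remote sensing who want a tested, scriptable reference implementation
of FCLS-based abundance correction for yield regression.

## Worked example

`examples/04_yield_model.py` runs the whole chain (simulate →
calibrate → unmix → indices → aggregate → fit) on one synthetic scene
and prints:

```
predictor grid (sorted by adjusted R^2):
    predictor      r  adjusted_r2  rmse
         NDVI  0.865        0.736 0.262
  GNDVI*Abd_L  0.747        0.537 0.346
   NDRE*Abd_L  0.744        0.534 0.348
GNDVI*Abd_L-P  0.697        0.462 0.373
 NDRE*Abd_L-P  0.696        0.460 0.374
   NDVI*Abd_L  0.690        0.453 0.376
 NDVI*Abd_L-P  0.671        0.425 0.386
   NDVI*Abd_P -0.644        0.389 0.398
   NDRE*Abd_P -0.641        0.385 0.399
  GNDVI*Abd_P -0.641        0.384 0.399
         NDRE  0.379        0.104 0.482
        GNDVI  0.348        0.081 0.488

LOOCV of NDRE*(Abd_L-P), K=24 folds:
  mean coefficients (slope, intercept): (8.917, 0.287)
  mean training R^2: 0.484
  held-out RMSE:     0.399  (11.0% of the mean yield scale)
```

Reading the numbers: leaf-weighted indices correlate positively with
yield and panicle-weighted ones negatively — the signature of panicle
contamination — and weighting NDRE by `Abd_L − Abd_P` lifts its
adjusted R² from 0.10 to 0.46 on this seed, with a cross-validated
error near 11% of mean yield. (Plain NDVI ranks high here because the
synthetic canopy does not reproduce the NIR saturation that limits
NDVI on real paddies; see `docs/methods.md`.)

The other examples demonstrate individual stages: endmember libraries
and pixel unmixing (`01`), calibration recovery (`02`), and abundance
maps vs ground truth (`03`).

A thin CLI mirrors the stages:

```sh
paddy-unmix simulate --seed 1 --out scene/
paddy-unmix calibrate --image scene/dn.tif --panels scene/panels.json --out refl.tif
paddy-unmix unmix --image refl.tif --library scene/endmember_library.csv --out abund.tif
paddy-unmix run --seed 1 --out run/      # everything, with a manifest
```

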