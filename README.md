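# ftirquant

Quantification of an active pharmaceutical ingredient (API) directly from
powder ATR-FTIR spectra, using first-derivative band areas — with the full
ICH Q2-style method-validation workflow and a synthetic-spectrum simulator
for testing every stage without instrument data.

The reference application is diclofenac sodium in tablet formulations: the
carboxylate CO-stretch band at 1550–1605 cm⁻¹ is proportional to drug
content in a KBr dispersion, so a univariate calibration on that band's
area quantifies tablets in minutes with no solvents.

**Who it is for:** analytical/QC chemists running derivative
spectrophotometry assays, and developers who need a small, fully seeded
pipeline (ingest → derivative → band area → calibration → validation
report) they can test end to end.

## Method

1. **Ingest** — spectra from JCAMP-DX (`##XYDATA=(X++(Y..Y))`, AFFN/SQZ) or
   two-column CSV; axes normalized to ascending cm⁻¹; %transmittance
   converted to absorbance, A = 2 − log₁₀(T%).
2. **Derivative** — Savitzky–Golay first derivative (default window 9
   points, polynomial order 2) on a uniform grid (default 1 cm⁻¹).
   Differentiation removes constant baselines and sharpens overlap.
3. **Response** — trapezoidal area of |dA/dν| over the band window
   [1550, 1605] cm⁻¹. The *absolute* integral is used because the signed
   integral of a derivative over a fully enclosed band is ≈ 0 by the
   fundamental theorem of calculus.
4. **Calibration** — ordinary least squares Y = S·X + b over standards
   (default design 0.2, 0.4, 0.6, 0.8, 1.0 %w/w); concentration by inverse
   prediction X = (Y − b)/S.
5. **Validation** — LOD = 3.3σ/S and LOQ = 10σ/S (σ = residual standard
   deviation S_y/x by default), % recovery vs claimed content, intra/
   inter-day %RSD, a selectivity score from the residual band area after
   subtracting the scaled pure-API trace, and a robustness harness over
   perturbed processing settings.

## Worked example

```python
from ftirquant import (
    default_ds_profile, generate_calibration_series, simulate_tablet_spectrum,
    first_derivative, band_area, fit_calibration, predict_concentration,
    lod, loq,
)

cfg = default_ds_profile()                      # DS/KBr matrix, noise 0.002 AU
series = generate_calibration_series(cfg)       # five standards, 0.2–1.0 %w/w
points = [(c, band_area(first_derivative(s))) for c, s in series]
model = fit_calibration(points)
print(f"Y = {model.slope:.4f}X {model.intercept:+.4f}  r2 = {model.r_squared:.6f}")
print(f"LOD = {lod(model):.5f} %w/w   LOQ = {loq(model):.5f} %w/w")

tablet, truth = simulate_tablet_spectrum(cfg, 0.5, seed=7)
est = predict_concentration(model, band_area(first_derivative(tablet)))
print(f"tablet: true {truth.concentration:.3f} %w/w, estimated {est:.4f} %w/w")
```

Output:

```
Y = 1.3634X -0.0005  r2 = 0.999998
LOD = 0.00184 %w/w   LOQ = 0.00559 %w/w
tablet: true 0.500 %w/w, estimated 0.5018 %w/w
```

The slope is the band-area response per %w/w of drug; r² near 1 confirms
Beer–Lambert linearity of the absolute derivative area; the tablet estimate
recovers the simulated 0.5 %w/w content to ~0.4% relative.

The same pipeline runs from a shell:

```bash
ftirquant simulate --seed 42 --tablet 0.5 --out run/
ftirquant calibrate --design run/design.csv --out run/model.txt
ftirquant quantify --window 1550:1605 run/tablet.jdx
ftirquant validate --model run/model.txt --accuracy accuracy.csv
```

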