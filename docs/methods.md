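# Methods

## The quantification model

The assay treats the area of one infrared absorption band as a univariate
concentration response. For an analyte dispersed in an IR-transparent KBr
matrix, absorbance at each wavenumber is proportional to analyte
concentration (the Beer–Lambert analog for diffuse powder sampling), so any
linear functional of the absorbance band — including the area of its first
derivative magnitude — is linear in concentration:

    Y = S·X + b,   X in %w/w,   Y in derivative-absorbance · cm⁻¹ units.

Differentiation is applied before integration for two reasons: a first
derivative annihilates constant baseline offsets exactly and suppresses
slowly varying drift, and it sharpens band structure so that a window can
isolate the analyte band from neighboring absorptions. The price is that
the *signed* integral of a derivative over a window that encloses the whole
band is f(hi) − f(lo) ≈ 0. A usable scalar response therefore integrates
|dA/dν| (the band's total variation over the window, ≈ 2× peak height for
a unimodal band). Absolute-value integration is symmetric under window
placement and is the package default; signed and positive-lobe modes are
kept for sensitivity analysis.

## Processing parameters

| parameter | default | units | rationale |
|---|---|---|---|
| band window | [1550, 1605] | cm⁻¹ | carboxylate CO-stretch band of the sodium salt |
| SG window | 9 | points | standard smoothing/derivative compromise at 1 cm⁻¹ grid |
| SG polynomial | 2 | — | quadratic: exact for lines/parabolas, robust to noise |
| derivative order | 1 | — | the method's defining transform |
| resample step | 1 | cm⁻¹ | finer than the 16 cm⁻¹ instrument resolution, so interpolation adds no information |
| channel policy | use_absorbance | — | absorbance is the additive (Beer–Lambert) channel; %T is converted first |
| area mode | absolute | — | see above |
| σ for LOD/LOQ | residual S_y/x | response units | the only σ computable from the calibration itself; intercept-SE and explicit (blank) alternatives selectable |

Savitzky–Golay smoothing attenuates derivative extrema slightly: for a
Gaussian band with σ = 10 cm⁻¹ on a 1 cm⁻¹ grid, the peak derivative is
attenuated by 3.9% at window 9 / poly 2 and by 1.1% at window 5. This
attenuation is common to standards and samples at fixed settings, so it
cancels in calibration; it matters only when comparing derivative
amplitudes across different filter settings.

Reported recovery percentages are **truncated** (not rounded) to two
decimals, matching the reporting convention of the recovery tables this
workflow mirrors; full precision is kept internally and a rounding-mode
flag (`truncate2` / `round2` / `full`) controls presentation only.

## The simulator

`simulator` synthesizes absorbance spectra on the 700–2000 cm⁻¹ instrument
range (1 cm⁻¹ grid) as

    A(ν) = c · Σ analyte bands + Σ excipient bands + baseline + ε,

with Gaussian or Lorentzian band shapes, a linear baseline (offset 0.01 AU,
drift 5·10⁻⁶ AU/cm⁻¹), and additive i.i.d. Gaussian noise (default sd
0.002 AU — chosen so that the five-standard calibration lands in the
r² ≳ 0.999 regime typical of a well-behaved derivative assay). The default
analyte profile places the dominant band at 1577 cm⁻¹ (σ = 12, 0.75 AU per
%w/w) mid-window, with minor bands at 1453 and 745 cm⁻¹; the excipient
matrix (carbohydrate C–O at 1030/1100, residual water bend at 1650, ester
carbonyl at 1745 cm⁻¹) deliberately keeps all fixed bands outside the
analysis window, mirroring a formulation whose excipients do not absorb in
the carboxylate stretch region. Calibration standards are generated
without excipient bands (pure analyte in KBr), as in the real workflow.

Ground truth (true concentration, noiseless in-window analyte area) travels
as a sidecar record and is never written into the spectrum file, so it
cannot leak into the pipeline under test.

What the simulator does **not** model: wavelength-dependent ATR penetration
depth, instrument line-shape convolution, scattering/sloping artifacts
beyond a linear baseline, heteroscedastic or correlated noise, and
atmospheric CO₂/H₂O interference. Passing simulation-based tests therefore
demonstrates correctness of the *computational* pipeline under the stated
noise model, not robustness to every instrumental artifact of real powders.

## Study sizes and seeded experiments

- **Tablet recovery**: 200 replicates; each simulates a fresh five-standard
  calibration plus a 0.5 %w/w tablet and requires the inverse prediction
  within ±2% relative error. With 0.002 AU noise the observed success rate
  is 100%.
- **LOD–noise scaling**: noise levels 0.001/0.002/0.004 AU, 200 replicates
  per level; the per-level mean LOD is compared against a zero-intercept
  proportional fit. Deviations run 1–4%. The proportionality constant is
  3.3/S times the pipeline's noise-transfer gain (spectral AU → response
  units), which depends on the SG filter and window width and is not 1.
- **Selectivity**: computed on noiseless spectra, because the score is a
  band-overlap diagnostic — the absolute-area integral of an independent
  noise difference has a nonzero mean that would otherwise contaminate the
  tail-leakage bound. Clean tablets score ~5·10⁻⁴; an interferent at the
  band center with 30% of the analyte's amplitude scores ~0.3. Reports flag
  scores above 0.05 as non-selective (an order of magnitude above clean-
  matrix leakage, well below any meaningful interference).

## Numerical conventions and edge cases

- Axis convention is strictly ascending cm⁻¹ everywhere internally;
  descending instrument exports are reversed on ingest, and duplicate
  wavenumbers are an error (never averaged — they indicate an acquisition
  fault).
- JCAMP-DX support is the `##XYDATA=(X++(Y..Y))` table with AFFN and SQZ
  encodings; DIF/DUP compression and multi-block files are rejected with a
  clear message. In the tokenizer, `e/E` between digits (or before a sign)
  is an AFFN exponent, not the SQZ pseudo-digit ±5 — SQZ streams are scaled
  integers and carry no exponents.
- `resample_uniform` preserves both endpoints; when the span is not an
  exact multiple of the requested step, the actual step is the nearest
  divisor of the span (recorded in metadata).
- The derivative requires a uniform grid and refuses non-uniform input with
  a pointer to resampling, rather than silently using a mean step.
- OLS diagnostics (r², residual σ) are computed from residual sums of
  squares so noiseless collinear designs give exactly r² = 1, σ = 0.
- Inverse prediction returns negative concentrations as-is with a
  below-range warning; clipping would bias recovery statistics.
- %RSD is undefined (None) at mean 0 rather than infinite.
- All stochastic experiments are seeded; per-replicate seeds derive from
  one entry seed via `numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

- Univariate calibration only: no PLS/PCR, no peak-height mode, no
  weighted or nonlinear regression.
- Second- and higher-order derivatives can be computed but are not a
  validated mode of the package.
- The validation suite compares against its own calibration; statistical
  comparison to an orthogonal reference method (HPLC/UV) is out of scope.
- Recovery uncertainty intervals are not computed; replicate %RSD is the
  only dispersion measure reported.
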