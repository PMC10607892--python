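# nirpulse

Noise-robust pulse-wave estimation from two-band near-infrared (NIR) face
video, for researchers working on camera-based vital-sign monitoring
(remote photoplethysmography) in dark environments.

## The problem and the method

Under NIR illumination (~780-1000 nm), light reflected from facial skin
carries two absorbing components: **hemoglobin** (dermal blood, pulsating
with each heartbeat) and **shade** (illumination/geometry, affecting both
wavelength bands equally and essentially constant in time). In *density
space* — the negative logarithm of normalized pixel values — the
components mix linearly:

    v = F r + n

where `v` is the 2-vector of band densities per frame, `r = (hemoglobin,
shade)`, `F` the 2×2 system matrix (spectral transmittance × illumination
× sensor sensitivity, lumped), and `n` additive sensor (thermal) noise.

The conventional separation inverts the system, `r = F⁻¹ v`. Because
hemoglobin absorbs weakly and similarly at the two NIR bands, `F` is
nearly singular and the inversion amplifies sensor noise drastically —
the extracted pulse wave drowns. The Wiener (linear MMSE) estimator uses
the second-order statistics of the components (`Rrr = ⟨r rᵀ⟩`, built from
the hemoglobin fluctuation range with the shade fixed) and of the noise
(`Rnn = ⟨n nᵀ⟩`, measured from a static artificial-skin patch imaged
alongside the face):

    r̃ = G v,   G = Rrr Fᵀ (F Rrr Fᵀ + Rnn)⁻¹

`G` minimizes the ensemble mean squared error `⟨(r − r̃)ᵀ(r − r̃)⟩` and
reduces to `F⁻¹` as the noise vanishes.

The hemoglobin track then passes through the standard chain: smoothness-
priors detrending, zero-phase Butterworth bandpass on [0.75, 4.0] Hz,
upper-peak detection, and heart rate `HR = 60 / mean RR interval`.
Evaluation metrics: Pearson correlation against a reference pulse-meter
signal, spectral SNR (`20·log₁₀` of 0.5–15 Hz vs >15 Hz magnitude), and
the absolute error rate of heart rate, `AER = |HR_gt − HR_est| / HR_gt ×
100`.

Because no public recordings exist for this setup, the package includes a
first-class synthetic session generator (`nirpulse.synthetic`) that
reproduces the assumed statistical structure — periodic hemoglobin
pulsation, fixed shade, Gaussian sensor noise, quantized 16-bit counts, a
constant-reflectance patch, and a clean pulse-meter reference on its own
clock — so the whole pipeline is testable end to end.

## Worked example

```python
from nirpulse import SyntheticConfig, RunConfig, run_pipeline, metrics_table

result = run_pipeline(RunConfig(synthetic=SyntheticConfig(seed=1), seed=1))
print(metrics_table(result).round(3).to_string(index=False))
```

prints

```
      method      stage  correlation  snr_db  snr_unbounded  aer_percent  hr_estimated  hr_reference
conventional        raw        0.112  -0.835          False          NaN           NaN           NaN
conventional  detrended        0.114  -1.060          False          NaN           NaN           NaN
conventional bandpassed        0.377  63.087          False        0.596        72.429          72.0
      wiener        raw        0.404  19.531          False          NaN           NaN           NaN
      wiener  detrended        0.784   5.746          False          NaN           NaN           NaN
      wiener bandpassed        0.971  74.646          False        0.044        71.968          72.0
```

The session simulates a 30 s recording at 66.5 fps (1995 frames) with a
1.2 Hz pulse (72 bpm). Reading the table: the conventional raw pulse sits
at the noise floor (≈ −1 dB spectral SNR, correlation ≈ 0.1 with the
reference), while the Wiener raw pulse already shows a dominant cardiac
peak (+19.5 dB). After detrending and bandpass filtering the Wiener path
tracks the reference closely (correlation 0.97) and recovers the heart
rate to 0.04% (72.0 vs 71.97 bpm); the conventional path's heart rate is
usable here only because filtering concentrates what little pulse
survives — across seeds and pulse rates its AER averages tens of percent
while the Wiener path stays below 1%.

The same pipeline runs from frames on disk: `simulate` writes a synthetic
two-band TIFF stack with a JSON manifest (band files, frame rate, ROI
layout, reference CSV), and `estimate` processes it:

```sh
nirpulse simulate --out session/ --seed 1
nirpulse estimate --manifest session/manifest.json --out results/ --seed 1
```

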