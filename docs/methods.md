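# Methods

This note documents the model, the numerical choices, and what the
synthetic study conditions do and do not establish.

## Observation model

A two-band NIR camera observes facial skin whose reflectance is governed
by two absorbing components. Per frame, with pixel means normalized by
the sensor full scale and mapped to densities `v = −log(count /
max_value)` (counts clipped below at `floor_count = 1` so zero counts
stay finite), the model is `v = F r + n`:

- `r = (hemoglobin, shade)` in density units. Hemoglobin pulsates with
  blood volume; shade — the lumped illumination/geometry term — scales
  both bands equally and is treated as constant over a 30 s recording.
- `F` is the 2×2 system matrix. Its shade column is `(1, 1)` by
  construction; its hemoglobin column holds the relative effective blood
  absorbance at the two selected bands. `F` is configuration, not
  estimation: the true matrix for a given camera/illuminant must be
  supplied by the user. The shipped default, hemoglobin column
  `(0.77, 0.65)` for the 800/930 nm pair, is a documented placeholder
  whose weak band contrast (determinant 0.12) reflects the physical
  regime that motivates the method: hemoglobin absorption differs little
  between NIR bands, so plain inversion amplifies noise by
  `‖F⁻¹‖ ≈ √2/det(F) ≈ 12` per density unit.
- `n` is i.i.d. zero-mean Gaussian sensor (thermal) noise, the only
  noise modelled. Illumination fluctuation and motion are out of scope.

Normalizing counts before the log makes densities dimensionless and
non-negative; the additive constant this choice introduces is removed by
detrending downstream.

## Estimators

Conventional: `r = F⁻¹ v`, computed by a linear solve (never an explicit
inverse); matrices with condition number above 1e12 are rejected.

Wiener: `G = Rrr Fᵀ (F Rrr Fᵀ + Rnn)⁻¹`, the linear estimator minimizing
the ensemble MSE given second moments of signal and noise. One `G` is
built per session and applied to every frame.

- `Rrr = ⟨r rᵀ⟩` uses raw second moments, not mean-centred covariance.
  The ensemble draws the hemoglobin value uniformly over a configured
  range with the shade fixed (maximum-entropy choice over a bounded
  interval; an empirical-samples mode exists). A degenerate range yields
  the exact rank-one moment matrix.
- The hemoglobin range should describe the *pulsatile* fluctuation the
  estimator must preserve, not slow drift: drift is removed by
  detrending afterwards, and folding it into the prior inflates the
  assumed hemoglobin variance, which makes the estimator admit noise to
  track a component that is discarded anyway (measured: the pulse-band
  SNR advantage collapses from ~12× to ~1×). On synthetic sessions the
  pipeline therefore defaults to the generator's known pulse range
  (`rrr mode "session-truth"`, the matched-model case); on real
  recordings the observed range of the conventional estimates is used
  (`mode "conventional"`), with the caveat that noise inflates that
  range, or an explicit range can be given.
- `Rnn` is `σ²I` (analytic) or the average of sampled `n nᵀ` (the
  default, mirroring the measurement procedure); σ comes from the
  artificial-skin patch: the sample standard deviation (n−1 denominator)
  of the patch ROI-mean series per band, the larger of the two bands
  selected. σ is estimated on the density-transformed patch series so
  `Rnn` shares units with `v`; a raw-count mode exists for comparison.
- The data-driven form `G = Rrv Rvv⁻¹` is implemented only as a test
  oracle against the model-based formula.

With `Rnn = 0` and full-rank `Rrr`, `G = F⁻¹` exactly; the pipeline
paths coincide on noise-free sessions.

## Signal chain

- Detrending: smoothness-priors method — subtract the trend
  `(I + λ² D₂ᵀD₂)⁻¹ x` (`D₂` the second-difference operator), solved
  sparsely. The trend filter's cutoff is `f_c ≈ (fs/2π)·λ^(−1/2)`.
  Default `λ = 1200`, giving `f_c ≈ 0.3 Hz` at 66.5 fps: safely below
  the 0.75 Hz bandpass edge while still removing sub-0.1 Hz drift. A
  smaller λ (e.g. 300 → cutoff 0.6 Hz) measurably attenuates a 0.9 Hz
  fundamental (−18%) and distorts low-heart-rate waveforms, which is why
  the default is larger than typically quoted for 4 Hz-resampled HRV
  series; λ is configurable.
- Bandpass: zero-phase Butterworth on [0.75, 4.0] Hz. `order` (default
  4) is the *total* zero-phase order: a design of order `order/2` run
  forward and backward. The residual mean left by finite-record boundary
  transients is subtracted, since a band-limited output has no DC.
- Peak detection: local maxima gated by robust amplitude thresholds —
  height ≥ `median + 0.3·(q95 − median)` and topographic prominence ≥
  `0.7·(q95 − median)` — then greedy selection by height (earlier index
  wins ties) with a minimum separation (default 0.25 s = the bandpass
  upper-edge period). Both gates are equivariant under positive affine
  rescaling; setting them to 0 recovers plain local maxima. True upper
  peaks span the full waveform amplitude and pass easily; noise bumps on
  the systolic shoulder or in the troughs do not. The pipeline
  additionally adapts the separation to `0.6 / f_dom`, where `f_dom` is
  the dominant passband frequency — successive beats cannot be closer
  than ~0.6 cardiac periods, which excludes the secondary maximum the
  waveform's second harmonic places ~T/4 after each peak.
- Heart rate: `60 / mean RR` over the whole recording; undefined (and
  reported as NaN by the pipeline) with fewer than two peaks.

## Metrics

- Spectral SNR: `20·log₁₀(rss(0.5–15 Hz) / rss(>15 Hz))` on the DFT
  magnitude after a light Tukey edge taper (α = 0.1, configurable; 0
  restores the plain DFT). The taper matters: for a detrended and
  zero-phase-filtered finite record, the >15 Hz band is otherwise
  dominated by boundary-transient leakage with only a few effective
  degrees of freedom, so the metric measures edge artifacts rather than
  noise (per-seed swings of ±7 dB were observed without it). The DC bin
  and 0–0.5 Hz belong to neither band. A noise band below `1e−5` of the
  signal band (the taper's own leakage floor is ~`5e−7`) is reported as
  unbounded.
- Correlation: plain Pearson coefficient after resampling the reference
  (linear interpolation) onto the camera frame grid at zero lag.
- AER: `|HR_gt − HR_est| / HR_gt × 100` (%).
- Peak contrast (diagnostic): peak-to-median spectral magnitude within
  0.5–15 Hz; pure noise sits near the Rayleigh level (~1–3), a clean
  pulse gives ≫10.

## Synthetic study conditions

The generator emulates: hemoglobin `0.30 + 0.005·w(t)` density units,
with `w` a unit-amplitude two-harmonic waveform (relative amplitudes
1.0, 0.35) at fundamental `f0` (default 1.2 Hz), plus a slow drift
(amplitude 0.01, 0.05 Hz) standing in for vasomotor/respiratory trends;
shade 0.50; sensor noise σ = 0.0025 per band; 16-bit quantized counts;
30 s at 66.5 fps (1995 frames); a patch at density 0.60 carrying the
same noise; a clean reference waveform at 256 Hz.

The noise calibration puts the conventional raw pulse at the spectral
noise floor (its amplitude SNR per sample is `A/(‖F⁻¹row‖σ) ≈ 0.17`,
peak-to-median ≈ 4–5, barely above the Rayleigh maximum of the noise
bins) while the Wiener estimator — operating near the matched-filter
bound `|f|·A/σ ≈ 2` — retains a dominant cardiac peak and supports
reliable peak detection. Note that with purely white sensor noise the
band-ratio SNR of a noise-dominated signal cannot fall below ≈ −1 dB at
this frame rate (the two bands hold 44% and 55% of a flat spectrum), so
strongly negative raw SNRs reported for real cameras are not reproducible
under this noise model; the *contrast* between methods is the reproduced
quantity.

What passing tests show: the estimator algebra (MSE optimality,
noise-free equivalence, convergence of sampled moments), the signal
chain's frequency-domain behaviour, and the method contrast under the
assumed model — linear mixing, temporally white Gaussian noise, static
shade, rigid face. What they do not show: robustness to motion,
illumination fluctuation, spatially varying chromophores, sensor
nonlinearity, or misspecified `F` beyond the provided mismatch knob —
real-recording performance can differ materially.

## Degenerate inputs and tie-breaks

Singular `F` or ill-conditioned `F Rrr Fᵀ + Rnn` raise errors naming the
condition number (threshold 1e12). Constant signals: zero patch noise is
legal (Rnn = 0); constant pulse signals yield empty peak sets and an
estimation error from `heart_rate`; constant inputs to correlation raise
(undefined). Equal-height peak candidates within the minimum separation
keep the earlier index. Zero counts clip to `floor_count` before the
log. All randomness flows from explicit integer seeds; identical
configurations are bit-reproducible.
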