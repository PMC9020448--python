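# Methods

## Scope and assumptions

`filmdose` models the measurement chain for absolute film dosimetry of a
narrow, quasi-monoenergetic kilovoltage photon beam, calibrated against a
polyenergetic surrogate matched by first half-value layer (HVL). The
package assumes narrow-beam (scatter-free) attenuation for all HVL work,
an in-air calibration geometry (no phantom backscatter, B_w = 1), a
single film lot per calibration curve, and red-channel-only densitometry
with consistent film-grain orientation between pre- and post-exposure
scans. None of the optics producing the converging beam is modelled.

## Beam quality

* HVL of a monoenergetic beam: ln 2 / (μ/ρ · ρ), reported in mm; all
  internal lengths are cm, converted at the API boundary only.
* Spectrum HVLs: the fluence-weighted transmission
  T(t) = Σ w_i exp(−μ(E_i)·t) is inverted by bracketed root finding
  (Brent, relative tolerance 1e−9) for T = 1/2 (first HVL) and T = 1/4
  (second HVL = t₁/₄ − t₁/₂). The bracket is capped at 50 times a crude
  HVL estimate from the fluence-weighted mean μ; a target not reached
  inside the cap is an error, not an extrapolation.
* μ/ρ(E) interpolation is log-log linear, the standard convention for
  attenuation data. The bundled aluminium table (10–300 keV, standard
  compilation values, ρ = 2.699 g/cm³) ships as CSV + JSON sidecar so it
  is inspectable and replaceable.
* Effective energy inverts the monotone map E ↦ HVL(E) by bracketed root
  finding over the table's energy range.
* N_K and water-to-air ratio interpolation versus HVL is piecewise
  **linear in HVL**. This choice reproduces the accepted interpolated
  chamber coefficient from its two bracketing calibration points
  (12.01 cGy/nC at 9.0 mm Al from 11.87 @ 6.01 mm and 12.42 @ 17.8 mm).
  Extrapolation outside the calibrated hull is always an error.
* A measured homogeneity factor of a real filtered spectrum (~0.76 for a
  heavily filtered 180 kVp beam) is treated as an external anchor: no
  surrogate tube spectrum is bundled, because HF depends on the full
  spectral shape, which is not portable knowledge.

## Film readout

* ROI: a centred square of round(side/2.54·dpi) pixels (side default
  0.5 cm). dpi is a required field of every scan — flatbed scanners are
  operated at different resolutions (72 and 75 dpi are both common) and a
  hard-coded constant would silently mis-size the ROI. When the centring
  margin is odd, the window shifts to the low index.
* ROI dispersion uses the population (n) standard deviation; at the
  ~196 pixels of a 0.5 cm ROI the distinction from n−1 is immaterial,
  and a fixed convention keeps pooled statistics exactly equal to a
  concatenated-pixel oracle.
* Repeat scans are pooled as the mean of per-scan ROI means; the pooled
  SD combines mean within-scan variance with the between-scan variance
  of the means, which for equal windows equals the SD over all pixels.
* NetOD = log10((I_pre − I_opq)/(I_post − I_opq)); I_opq is a scalar ROI
  mean of an opaque (covered-bed) scan, not a per-pixel map. SDs
  propagate by first-order Taylor expansion. A non-positive net signal
  (saturated film, or film darker than the opaque reading) is an error.
* Orientation is metadata: the orientation tag is recorded and checked
  for consistency, but no polarisation correction is applied — the
  protocol of fixed grain orientation makes one unnecessary. The
  exposure-to-readout delay is a recorded field validated against a
  configurable window (default 24 ± 2 h), not simulated film chemistry.

## Calibration

* The NetOD→dose map is a cubic through the origin fitted by unweighted
  least squares (columns x, x², x³; no intercept). Unweighted is the
  default because the calibration protocol reports no weighting; a
  1/σ²-weighted variant is available for sensitivity checks.
* The fitted validity range is [0, max fitted NetOD × 1.05]. Outside it,
  strict mode raises and lenient mode logs a warning — cubic
  extrapolation beyond the fitted range is unphysical.
* Inversion (dose → NetOD) uses bracketed root finding on the monotone
  valid branch to 1e−10; doses outside the image of the valid range are
  refused rather than extrapolated.
* Curves carry a free-text `lot` field surfaced in all outputs: film
  response is lot-specific and a curve must not be reused across lots.
* Curve comparison evaluates both curves at equal NetOD over a grid
  obtained by mapping a dose range through the first curve, and reports
  the maximum |D₁ − D₂|/mean. The function is reported rather than a
  single pass/fail number, because the dose grid over which "curves agree
  to X%" holds is itself a choice.

## Uncertainty

* Components are relative percentages with an explicit coverage factor k.
  Combination rescales to a common k then takes the root sum of squares;
  this makes "combine expanded values directly" and "combine standard
  values then expand" provably identical.
* Scanner drift is retained as an explicit 0.1% component even though
  dropping it would round to the same OD total (1.8% at k = 2):
  budgets should be conservative and list what was considered.
* Film homogeneity across equally-exposed pieces uses the sample (n−1)
  SD — the pieces are a sample of the sheet.
* Measured-dose uncertainty combines the OD term
  |dD/dx|·σ_x·2/D·100 (k = 2) with the delivered-dose budget in
  quadrature. The cubic's slope-to-value ratio falls with NetOD, so the
  relative uncertainty is largest at low dose, where the signal
  approaches background OD.

## Profiles

* TMR normalises to the series maximum (which therefore maps to exactly
  1), not to the dose at a reference depth; raw series are never smoothed
  or resampled, so measurement noise can make TMR locally non-monotonic
  and that is reported as read.
* Any polynomial summary of the TMR trend is re-fitted (configurable
  order, coefficients with standard errors), never hard-coded.
* FWHM interpolates linearly between the bracketing samples at each
  half-max crossing; profiles that do not fall below half maximum on
  both sides of the peak have no width and raise.

## Synthetic data

The generator emulates, with known ground truth:

* **Scanner** — 16-bit/channel RGB rasters at a stated dpi, an unexposed
  transmission level (default 40000 counts), a stray-light level I_opq
  (default 1000 counts), additive white pixel noise (default 80 counts,
  ~0.2% of signal, a typical flatbed figure), a smooth multiplicative
  bed field (product of two low-frequency cosines with random phase,
  spatial relative SD set so the expanded non-uniformity is 0.8% at
  k = 2), and a per-scan drift gain (0.1% at k = 2).
* **Film** — a truth calibration cubic (default: the 60 keV-equivalent
  beam's coefficients a₁ = 897.6, a₂ = −123.5, a₃ = 4639) and a
  per-piece scalar non-uniformity factor (1.6% at k = 2, matching the
  measured piece-to-piece OD spread at a fixed dose). Perturbations
  multiply NetOD; intensities follow
  I_post = I_opq + (I_unexposed − I_opq)·10^(−NetOD).
* **Beam** — an analytic surrogate: a Gaussian focal spot (default
  FWHM 3 mm lateral and longitudinal — "a few millimetres" is the stated
  regime; 3 mm is a modelling choice), exponential attenuation in water
  (μ = 0.206 cm⁻¹ at 60 keV), and an inverse-area conical convergence
  factor with 30° half-angle. `surface_dose_rate` (default 84 cGy/min)
  is the on-axis focal amplitude at zero water depth, chosen so the
  focal-spot rate at 5 cm depth is ~30 cGy/min, the regime such systems
  report. The focal-spot dose rate at depth d is therefore
  surface_dose_rate·exp(−μd), and the generator's TMR is exactly the
  normalised exponential.
* **Heterogeneity** — with/without-insert pairs built from configurable
  factors (defaults 0.87 upstream attenuation, 1.2 interface
  backscatter). The insert is characterised by its attenuation factor,
  not a material identity: bone-equivalent plastics are specified
  inconsistently in practice, and only the factor matters downstream.

What the generator does **not** emulate: energy-resolved transport,
scanner optics (lateral response, Newton rings, curl), film development
chemistry, polarisation effects, or any spatial structure of film
non-uniformity beyond a per-piece scalar plus the bed field. A green
end-to-end test therefore establishes that the *pipeline arithmetic* is
faithful and statistically calibrated against its stated noise model —
not that the noise model captures every artefact of physical film.

Determinism: every random draw flows through a named substream keyed by
(seed, label) via a CRC-32 of the label into a seed sequence, so adding a
new generator never perturbs existing outputs, and identical seeds
reproduce TIFF files byte-for-byte. In-memory pixel intensities stay
floating point (quantisation to 16-bit integers happens only when files
are written or `quantize=True` is requested), which is what makes the
noise-free round trip exact to 1e−4 cGy; file-based workflows inherit a
half-count quantisation error (~0.03 cGy at typical slopes).

## Known limitations

* No triple-channel dosimetry or lateral scanner-response correction.
* The TG-61 water-to-air ratio table is not embedded; only the value
  1.0535 for HVL 9.0 mm Al ships as a default, and other beam qualities
  need a user-supplied (HVL, ratio) table.
* HVL work assumes narrow-beam geometry; no Cu↔Al HVL conversion.
* The beam surrogate has no scatter, penumbra tails, or spectral change
  with depth; it exists to exercise the measurement pipeline.
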