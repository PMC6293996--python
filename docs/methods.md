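# Methods

## Spectral model and analysis grid

A spectrum is a pair (Raman shift in cm⁻¹, intensity in arbitrary
units). All internal analysis runs on a regular 1.0 cm⁻¹ grid, by
default spanning [100, 1300] cm⁻¹; irregular inputs (figure-digitized
traces) are linearly interpolated onto that grid and never extrapolated
— digitized traces end mid-feature, and extrapolation would fabricate
spectral content. Window boundaries are closed on both ends; duplicate
abscissa values in input files are collapsed to the mean intensity,
since digitization frequently repeats x values.

The three diagnostic windows are ν1 = [1080, 1090], ν4 = [700, 720],
and lattice = [100, 400] cm⁻¹. For *fitting* (not for membership
checks) the ν1 window is padded by ±35 cm⁻¹ and ν4 by ±10 cm⁻¹, because
a disorder-broadened ν1 (FWHM up to ~30 cm⁻¹) has most of its shape
outside an 11-point window; the fitted center must still fall inside
the nominal window to count.

## Peak model

Every band is a pseudo-Voigt: a linear mix of a Gaussian and a
Lorentzian sharing one center and one FWHM, with mixing fraction
η ∈ [0, 1]. Fits (via `lmfit`) add a constant offset and run bounded
least squares with deterministic initialization (center from detection,
height from the data, FWHM 5 cm⁻¹ for peaks / 120 cm⁻¹ for humps); no
random restarts. FWHM is read analytically from the fitted width
parameter (= 2σ in this parameterization for every η), never from
sampled points; tests verify agreement with a brute-force half-maximum
crossing search on a 0.01 cm⁻¹ oversampled rendering to < 0.05 cm⁻¹. A
center converging onto a window edge sets a boundary flag instead of
silently reporting an edge value.

## Baseline: fluorescence vs. the ordering hump

Fluorescence through tissue or seawater produces a smooth background
spanning the whole spectrum; partially ordered ACC produces a broad
hump confined below 400 cm⁻¹. Only the former is background. The
estimator models the background as a low-order polynomial (default
cubic) over the full span, fit by iteratively reweighted asymmetric
least squares: points above the current fit get weight 0.01, points
below get 0.99, for 10 passes. A full-span polynomial reproduces
linear ramps and gentle curvature essentially exactly, and it *cannot*
follow a feature localized to ~150 cm⁻¹ — so the hump's survival of
baseline subtraction is structural, not tuned.

This basis choice replaced a Whittaker-type penalized smoother during
development: with a second-difference penalty the smoother's free
boundary sags below a curved background at the span edges (breaking
peak-free-background recovery at every smoothness setting), while with
a third-difference penalty quadratics enter the penalty null space and
the estimator absorbs the parabola-like hump instead. The polynomial
basis satisfies both contracts at once: peak-free quadratic background
recovered to ~1e-14 relative, hump survival 72–86% noiseless and ≥ ~75%
at noise σ = 0.02. Its known limitation is the mirror image: a
fluorescence profile with genuinely localized curvature (sharper than a
cubic over the span) would be under-subtracted; degree is configurable.

Noise is estimated from the second difference of intensity: white noise
of scale σ has second differences of scale √6·σ, and the median
absolute deviation (×1.4826) ignores the sparse large values peaks
contribute. The estimator is unbiased within ±20% across σ ∈
[0.01, 0.2] (tested over 200 seeded replicates per level). Optional
Savitzky–Golay smoothing (9 points, order 3) exists but is off by
default — parametric fitting already regularizes.

Normalization divides by the maximum inside a reference window, by
default ν1, the band present in every calcium carbonate.

## "Distinct peak" and "hump", quantified

The lattice criterion needs a concrete meaning for *distinct*. Here: a
local maximum with prominence ≥ 5·σ_noise and fitted FWHM in
[2, 50] cm⁻¹. The 50 cm⁻¹ ceiling separates peaks from humps; the
2 cm⁻¹ floor rejects single-sample noise excursions, which are not
vibrational bands. Three implementation details matter for robustness
and are deliberate:

- Prominence is measured within a ±max_fwhm neighbourhood (scipy
  `wlen`), so a small fluctuation riding the ACC hump is judged against
  the hump's local level rather than inheriting the hump's full height
  as prominence.
- Width, by contrast, is measured on the unclipped profile, so the hump
  apex itself reads as the ~150 cm⁻¹-wide feature it is and is rejected
  by the ceiling.
- Candidates are located on a lightly smoothed copy (Savitzky–Golay,
  9 points, order 3); all parameter fits then run on the raw data. The
  subsequent fit is the final arbiter: candidates whose fitted height
  falls below the noise floor or whose fitted width is spike-narrow are
  discarded.

Candidates closer than 5 cm⁻¹ merge, keeping the more prominent. The
hump is quantified by one wide pseudo-Voigt with a FWHM floor of
80 cm⁻¹ — cleanly separated from the 50 cm⁻¹ peak ceiling so no feature
can be both — fit *without* a constant offset, because on a
baseline-subtracted residual a free offset can dive negative and
manufacture hump height out of pure noise. The region verdict is
`distinct_peaks` iff any fitted peak survives, else `broad_hump_only`
if the hump height clears 5·σ_noise, else `featureless`.

## Decision tree

1. No acceptable ν1 fit → `indeterminate` with `low_snr` (no carbonate
   signature at all).
2. Lattice verdict `distinct_peaks` → crystalline. Phase from template
   matching over the crystalline templates; if the best match is
   calcite *and* FWHM(ν1) > 20 cm⁻¹, the call is `high_mg_calcite` —
   disorder-broadened calcite, the crystalline phase that mimics ACC in
   width.
3. No distinct lattice peaks and FWHM(ν1) > 20 → `acc`; without a Mg
   measurement the result carries `mg_unknown_ambiguity`, since width
   alone cannot separate ACC from high-Mg calcite; with Mg ≥ 4 mol%
   supplied the call becomes `high_mg_calcite` instead.
4. No distinct lattice peaks and FWHM(ν1) ≤ 20 → `indeterminate`. A
   narrow ν1 without lattice modes is contradictory evidence; the
   classifier refuses to over-claim from ν1 position alone.

The 20 cm⁻¹ threshold is applied as a strict inequality, with a 1e-4
cm⁻¹ guard absorbing least-squares round-off when a fitted width lands
numerically on the boundary. The 4 mol% Mg threshold is the
conventional low/high-Mg calcite boundary; both are configurable.
`crystalline` is true exactly when the lattice verdict is
`distinct_peaks`.

Template matching scores the fraction of observed lattice centers
within ±10 cm⁻¹ of a template center, averaged with the fraction of
template centers matched; when both sides have a ν4 band its agreement
joins the average as a third binary term. Ties break toward the
smaller mean center offset. The ±10 cm⁻¹ tolerance accommodates
reported scatter and Mg-induced shifts. ν4 is evidence but never
required — digitized traces often cover only the lattice region.
Vaterite and monohydrocalcite are not in the template set and are out
of scope.

## Overlay comparison

Query and reference are resampled to a shared 1 cm⁻¹ grid inside the
comparison window (default the lattice window, the diagnostic zoom),
each scaled by its tallest in-window feature (max |intensity|, making
the score invariant to positive rescaling), and compared by residual
RMS and Pearson correlation. Rankings order by correlation, ties by
RMS. Digitized traces are resampled, never smoothed, before
comparison.

## Synthetic data: what it emulates and what it does not

The generator renders template spectra as sums of height-parameterized
pseudo-Voigts (η = 0.5) plus, per request, a linear or quadratic
background (amplitude in ν1-height units across the span) and additive
white Gaussian noise (σ as a fraction of ν1 height). Noise is drawn
before the background is added, so a seed's noise realization is
independent of the background choice. Identical synthesis specs give
bit-identical arrays; batch replicates derive per-replicate seeds from
one master seed.

Template constants: calcite lattice modes 150/280 cm⁻¹, ν4 712, ν1
1086 (FWHM 5); aragonite lattice 152/206, ν4 705, ν1 1085 (FWHM 4);
high-Mg calcite = calcite's peak set with ν1 FWHM 24 and slightly
broadened lattice modes; ACC ν1 1085 with FWHM 28 and a lattice hump at
200 cm⁻¹ (FWHM 150, height 0.15 of ν1), no ν4, no lattice peaks. The
anchored constants are the window memberships, the calcite 150/280
positions, the >20 cm⁻¹ disorder threshold (ACC at 28, high-Mg calcite
at 24, both above it; crystalline phases well below); the remaining
centers, widths, and relative heights are package conventions
consistent with the RRUFF reference spectra for aragonite (R080142) and
calcite (R150075).

Not emulated: Poisson/shot noise, cosmic-ray spikes, instrument
response and wavenumber calibration error, the aragonite ν4 doublet
fine structure (a single merged band is fitted; only window membership
is used), and realistic fluorescence shapes beyond low-order
polynomials. Passing tests therefore demonstrate correctness of the
decision logic and estimators under the stated noise model, not
instrument-grade robustness on arbitrary hardware.

## Problem sizes and determinism

Stochastic checks use seeded generators throughout: classifier
robustness runs 200 replicates per phase in the test suite and 50 per
phase in the acceptance script, at noise σ = 0.02 with random
fluorescence ramps of 0.5–3 ν1 heights; peak-center recovery uses 200
crystalline spectra at σ up to 0.05; detector false-positive sweeps use
90–100 seeds per scenario. The acceptance script's lattice-supremacy
sweep covers ν1 FWHM 5–60 in steps of 5 plus the boundary-adjacent
widths {19, 20, 21, 24, 28}; the test suite sweeps every integer. All
reported quantities are recomputed at run time from freshly generated
spectra.
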