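"""Background separation, noise estimation, smoothing, and normalization.

Raman measurements taken in seawater or through biological tissue carry a
smooth, broad fluorescence background.  That background must be removed
before band shapes are interpreted, but the removal must not also eat the
broad <400 cm^-1 "hump" that partially ordered amorphous calcium
carbonate produces: the hump is spectral content, not background.

The baseline model here is a low-order polynomial (default cubic) fit
over the full spectrum span by iteratively reweighted asymmetric least
squares.  A full-span polynomial captures the monotone ramps and gentle
curvature characteristic of fluorescence exactly, while it cannot bend
into a feature localized to a ~150 cm^-1-wide region — so an ordering
hump survives subtraction by construction rather than by a tuned
smoothness penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import GridError, InsufficientDataError, DomainError
from .spectra_io import Spectrum, SpectralWindow, NU1_WINDOW, crop

__all__ = [
    "BaselineModel",
    "estimate_baseline",
    "subtract_baseline",
    "estimate_noise_sigma",
    "normalize",
    "smooth",
    "DEFAULT_DEGREE",
    "DEFAULT_ASYMMETRY",
    "DEFAULT_ITERATIONS",
]

#: Polynomial degree of the fluorescence model.  Cubic covers the linear
#: ramps and gentle quadratic curvature seen through tissue/seawater with
#: one spare order; it cannot express a localized spectral hump.
DEFAULT_DEGREE = 3
#: Weight given to points above the baseline; points below get 1 - this.
DEFAULT_ASYMMETRY = 0.01
DEFAULT_ITERATIONS = 10


@dataclass
class BaselineModel:
    """A smooth baseline aligned to a spectrum grid."""

    baseline: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    shift: np.ndarray | None = None


def _require_regular(s: Spectrum, min_points: int) -> None:
    if len(s) < min_points:
        raise InsufficientDataError(f"need >= {min_points} points, got {len(s)}")
    if s.grid_step() is None:
        raise GridError("spectrum is not on a regular grid; resample() it first")


def estimate_baseline(
    s: Spectrum,
    degree: int = DEFAULT_DEGREE,
    asymmetry: float = DEFAULT_ASYMMETRY,
    iterations: int = DEFAULT_ITERATIONS,
) -> BaselineModel:
    """Estimate the smooth fluorescence background of a spectrum.

    Fits a polynomial of ``degree`` by iteratively reweighted asymmetric
    least squares: points above the current baseline get weight
    ``asymmetry``, points below get ``1 - asymmetry``, so peaks barely
    pull the fit up and the polynomial settles on the signal-free
    envelope.  On a peak-free smooth input the fit reproduces the input;
    on a flat-zero input it returns zero; it is exactly scale-equivariant.

    Parameters
    ----------
    degree : polynomial order of the background model (>= 1).
    asymmetry : weight in (0, 1) for points above the baseline.
    iterations : number of reweighting passes.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must be in (0, 1)")
    _require_regular(s, min_points=32)
    x, y = s.shift, s.intensity
    # Chebyshev-style rescaling of the abscissa for conditioning
    t = (x - x[0]) / (x[-1] - x[0]) * 2.0 - 1.0
    vand = np.polynomial.polynomial.polyvander(t, degree)
    w = np.ones_like(y)
    z = y.copy()
    for _ in range(iterations):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(vand * sw[:, None], y * sw, rcond=None)
        z = vand @ coef
        w = np.where(y > z, asymmetry, 1.0 - asymmetry)
    return BaselineModel(
        baseline=z,
        method="asym-poly",
        params={"degree": degree, "asymmetry": asymmetry, "iterations": iterations},
        shift=s.shift.copy(),
    )


def subtract_baseline(s: Spectrum, b: BaselineModel) -> Spectrum:
    """Return the spectrum minus the baseline; negative residuals are
    permitted (they are noise, not an error)."""
    if b.baseline.size != len(s) or (
        b.shift is not None and not np.array_equal(b.shift, s.shift)
    ):
        raise GridError("baseline grid does not match spectrum grid")
    return s.with_intensity(s.intensity - b.baseline, baseline_subtracted=b.method)


def estimate_noise_sigma(s: Spectrum) -> float:
    """Robust white-noise scale from the second difference of intensity.

    The second difference of a smooth signal is near zero while white
    noise of scale sigma has second differences of scale sqrt(6)*sigma;
    the median absolute deviation (scaled by 1.4826 for normality) makes
    the estimate insensitive to the sparse large values contributed by
    peaks.
    """
    if len(s) < 32:
        raise InsufficientDataError("need >= 32 points to estimate noise")
    d2 = np.diff(s.intensity, 2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def normalize(s: Spectrum, w: SpectralWindow = NU1_WINDOW) -> Spectrum:
    """Divide intensities by the maximum within ``w`` (default: the nu1
    window, the strong band present in every calcium carbonate) so the
    tallest in-window point equals 1."""
    seg = crop(s, w)
    if len(seg) < 3:
        raise InsufficientDataError(
            f"normalization window [{w.lo}, {w.hi}] contains {len(seg)} points, need >= 3"
        )
    peak = float(seg.intensity.max())
    if peak <= 0:
        raise DomainError(
            f"maximum intensity in window [{w.lo}, {w.hi}] is {peak}; cannot normalize"
        )
    return s.with_intensity(s.intensity / peak, normalized_on=w.name or (w.lo, w.hi))


def smooth(s: Spectrum, window: int = 9, order: int = 3) -> Spectrum:
    """Optional Savitzky-Golay smoothing; off by default in the pipeline
    because parametric peak fitting already regularizes."""
    _require_regular(s, min_points=window)
    return s.with_intensity(
        savgol_filter(s.intensity, window, order), smoothed=(window, order)
    )
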