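"""Peak detection, pseudo-Voigt fitting, and lattice-region summary.

The discriminating measurements for carbonate phase identification are
(i) the full width at half maximum (FWHM) of the nu1 symmetric-stretch
band, and (ii) whether the lattice-mode region below 400 cm^-1 contains
*distinct* peaks (crystalline), only a broad hump (partially ordered
amorphous material), or nothing.  "Distinct" is quantified here as a
local maximum with prominence of at least ``min_snr`` times the noise
scale and a fitted FWHM no wider than ``max_fwhm`` (default 50 cm^-1);
anything wider is treated as a hump, which is quantified separately by a
wide pseudo-Voigt with a FWHM floor of 80 cm^-1, cleanly separated from
the peak ceiling so no feature can be counted as both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit.models import ConstantModel, PseudoVoigtModel
from scipy.signal import find_peaks, peak_prominences, peak_widths, savgol_filter

from .exceptions import DomainError, FitError
from .preprocess import estimate_noise_sigma
from .spectra_io import LATTICE_WINDOW, SpectralWindow, Spectrum, crop

__all__ = [
    "PeakFit",
    "LatticeRegionSummary",
    "detect_peaks",
    "fit_peak",
    "fit_hump",
    "summarize_lattice_region",
    "DEFAULT_MIN_SNR",
    "DEFAULT_MAX_PEAK_FWHM",
    "DEFAULT_MIN_HUMP_FWHM",
]

#: Prominence threshold for a "distinct" peak, in units of the noise sigma.
DEFAULT_MIN_SNR = 5.0
#: Widest feature still counted as a distinct peak (cm^-1); wider is a hump.
DEFAULT_MAX_PEAK_FWHM = 50.0
#: Narrowest credible peak (cm^-1): single-sample spikes are noise, not bands.
DEFAULT_MIN_PEAK_FWHM = 2.0
#: FWHM floor of the hump model (cm^-1), separated from the peak ceiling.
DEFAULT_MIN_HUMP_FWHM = 80.0
#: Candidates closer than this (cm^-1) are merged, keeping the more prominent.
_MERGE_DISTANCE = 5.0


@dataclass
class PeakFit:
    """Parameters of one fitted pseudo-Voigt peak.

    ``fwhm`` is computed analytically from the fitted width parameter
    (both the Gaussian and Lorentzian components share the same FWHM in
    this parameterization), never read off sampled points.  ``eta`` is
    the Lorentzian fraction: 0 is pure Gaussian, 1 pure Lorentzian.
    """

    center: float
    height: float
    fwhm: float
    eta: float
    rmse: float
    window: SpectralWindow
    boundary: bool = False  # fitted center pinned to a window edge


@dataclass
class LatticeRegionSummary:
    """What the <400 cm^-1 lattice-mode region contains.

    verdict is ``distinct_peaks`` exactly when ``peaks`` is non-empty;
    otherwise ``broad_hump_only`` when a wide component rises above the
    detection floor, else ``featureless``.
    """

    peaks: list[PeakFit] = field(default_factory=list)
    hump_height: float | None = None
    hump_center: float | None = None
    verdict: str = "featureless"


def detect_peaks(
    s: Spectrum,
    w: SpectralWindow,
    noise_sigma: float,
    min_snr: float = DEFAULT_MIN_SNR,
    max_fwhm: float = DEFAULT_MAX_PEAK_FWHM,
    min_fwhm: float = DEFAULT_MIN_PEAK_FWHM,
) -> list[float]:
    """Find candidate distinct-peak centers in a window.

    Local maxima of the baseline-subtracted intensity whose prominence is
    at least ``min_snr * noise_sigma`` and whose half-maximum width lies
    in [``min_fwhm``, ``max_fwhm``]; returned in ascending shift order.
    Prominence is measured within a window of twice ``max_fwhm`` around
    each maximum so that a narrow fluctuation riding a broad hump is
    judged against the hump's local level, not against the far-away
    background.  A noiseless spectrum (noise_sigma 0) falls back to a
    small floor relative to the in-window dynamic range so numerically
    flat spectra yield nothing.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    seg = crop(s, w)
    y = seg.intensity
    # candidates come from a lightly smoothed copy: a genuine band keeps
    # its prominence, while a one-sample noise excursion does not; the
    # parametric fits that follow always run on the raw data
    if y.size >= 9:
        y = savgol_filter(y, 9, 3)
    step = np.median(np.diff(seg.shift))
    ptp = float(y.max() - y.min())
    floor = max(min_snr * noise_sigma, 1e-3 * ptp, 1e-12)
    wlen = max(int(round(2.0 * max_fwhm / step)), 3)
    idx, props = find_peaks(y, prominence=floor, wlen=wlen)
    if idx.size == 0:
        return []
    # prominence is judged locally (wlen) so a fluctuation on a hump is
    # measured against the hump, but width is measured on the unclipped
    # profile so the hump apex itself reads as the wide feature it is
    full_prom, lb, rb = peak_prominences(y, idx)
    widths = peak_widths(
        y, idx, rel_height=0.5, prominence_data=(full_prom, lb, rb)
    )[0] * step
    keep = (widths <= max_fwhm) & (widths >= min_fwhm)
    idx, prom = idx[keep], props["prominences"][keep]
    centers = seg.shift[idx]
    # merge candidates closer than _MERGE_DISTANCE, keeping the more prominent
    order = np.argsort(prom)[::-1]
    chosen: list[tuple[float, float]] = []
    for i in order:
        c = centers[i]
        if all(abs(c - c0) > _MERGE_DISTANCE for c0, _ in chosen):
            chosen.append((float(c), float(prom[i])))
    return sorted(c for c, _ in chosen)


def _pseudo_voigt_model(prefix: str = "p_"):
    return PseudoVoigtModel(prefix=prefix) + ConstantModel(prefix="c_")


def fit_peak(
    s: Spectrum,
    w: SpectralWindow,
    init_center: float,
    init_fwhm: float = 5.0,
    min_fwhm: float = 0.0,
    max_fwhm: float | None = None,
    with_offset: bool = True,
) -> PeakFit:
    """Least-squares fit of a single pseudo-Voigt plus constant offset.

    The fit runs on the points inside ``w`` (at least 7 required) with the
    center bounded to the window; FWHM comes analytically from the fitted
    width parameter.  A center that converges onto a window edge sets the
    ``boundary`` flag rather than raising.
    """
    if not (w.lo <= init_center <= w.hi):
        raise DomainError(
            f"init_center {init_center} outside window [{w.lo}, {w.hi}]"
        )
    seg = crop(s, w)
    if len(seg) < 7:
        raise DomainError(
            f"window [{w.lo}, {w.hi}] holds {len(seg)} points; need >= 7 to fit"
        )
    x, y = seg.shift, seg.intensity
    offset0 = float(np.median(y))
    height0 = float(np.interp(init_center, x, y) - offset0)
    if height0 <= 0:
        height0 = max(float(y.max() - offset0), 1e-6)
    sigma0 = max(init_fwhm / 2.0, 1e-3)
    model = _pseudo_voigt_model()
    params = model.make_params()
    params["p_center"].set(value=init_center, min=w.lo, max=w.hi)
    # lmfit's pseudo-Voigt shares FWHM = 2*sigma between both components
    params["p_sigma"].set(
        value=sigma0,
        min=max(min_fwhm / 2.0, 1e-4),
        max=(max_fwhm / 2.0) if max_fwhm else np.inf,
    )
    params["p_fraction"].set(value=0.5, min=0.0, max=1.0)
    params["p_amplitude"].set(value=height0 * sigma0 * np.pi, min=0.0)
    # a baseline-subtracted residual has no offset to absorb; fixing it
    # prevents a spurious offset/bump decomposition of pure noise
    params["c_c"].set(value=offset0 if with_offset else 0.0, vary=with_offset)
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(
            f"pseudo-Voigt fit did not converge in [{w.lo}, {w.hi}]",
            init_center=init_center,
            window=w,
        )
    p = result.params
    center = float(p["p_center"].value)
    fwhm = float(2.0 * p["p_sigma"].value)
    offset = float(p["c_c"].value)
    height = float(result.eval(x=np.array([center]))[0] - offset)
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    edge_tol = max(1e-4 * w.width, 1e-6)
    boundary = (center - w.lo) < edge_tol or (w.hi - center) < edge_tol
    return PeakFit(
        center=center,
        height=height,
        fwhm=fwhm,
        eta=float(p["p_fraction"].value),
        rmse=rmse,
        window=w,
        boundary=boundary,
    )


def pseudo_voigt(x, center, fwhm, height, eta):
    """Height-normalized pseudo-Voigt profile (shared-FWHM mixing).

    Used for rendering fitted or template peaks; equals ``height`` at the
    center and falls to half of it at center +/- fwhm/2 for every eta.
    """
    x = np.asarray(x, dtype=float)
    half = fwhm / 2.0
    lor = 1.0 / (1.0 + ((x - center) / half) ** 2)
    gau = np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)
    return height * (eta * lor + (1.0 - eta) * gau)


def fit_hump(
    s: Spectrum,
    w: SpectralWindow = LATTICE_WINDOW,
    min_fwhm: float = DEFAULT_MIN_HUMP_FWHM,
) -> PeakFit:
    """Fit one wide pseudo-Voigt (FWHM >= ``min_fwhm``) to quantify a
    broad component, e.g. the ordering hump of partially ordered ACC."""
    seg = crop(s, w)
    init_center = float(seg.shift[np.argmax(seg.intensity)])
    init_center = min(max(init_center, w.lo), w.hi)
    return fit_peak(
        s, w, init_center, init_fwhm=max(120.0, min_fwhm), min_fwhm=min_fwhm,
        with_offset=False,
    )


def summarize_lattice_region(
    s: Spectrum,
    noise_sigma: float | None = None,
    w: SpectralWindow = LATTICE_WINDOW,
    min_snr: float = DEFAULT_MIN_SNR,
    max_peak_fwhm: float = DEFAULT_MAX_PEAK_FWHM,
    min_hump_fwhm: float = DEFAULT_MIN_HUMP_FWHM,
) -> LatticeRegionSummary:
    """Classify the lattice-mode region of a baseline-subtracted spectrum.

    Distinct peaks are detected and fitted individually (each within a
    sub-window around its candidate center); their fitted profiles are
    subtracted and one wide pseudo-Voigt quantifies any remaining broad
    component.  The hump detection floor is ``min_snr * noise_sigma`` (or
    a small fraction of the in-window dynamic range for noiseless input).
    """
    if noise_sigma is None:
        noise_sigma = estimate_noise_sigma(s)
    centers = detect_peaks(s, w, noise_sigma, min_snr=min_snr, max_fwhm=max_peak_fwhm)
    seg_all = crop(s, w)
    height_floor = max(
        min_snr * noise_sigma,
        1e-3 * float(seg_all.intensity.max() - seg_all.intensity.min()),
        1e-12,
    )
    peaks: list[PeakFit] = []
    for c in centers:
        sub = SpectralWindow(max(c - 30.0, w.lo), min(c + 30.0, w.hi), w.name)
        try:
            pk = fit_peak(s, sub, c, init_fwhm=5.0, max_fwhm=max_peak_fwhm)
        except (FitError, DomainError):
            continue
        # the fit is the final arbiter of distinctness: reject candidates
        # whose fitted band is below the noise floor or spike-narrow
        if pk.height < height_floor or pk.fwhm < DEFAULT_MIN_PEAK_FWHM:
            continue
        peaks.append(pk)
    residual = crop(s, w)
    y = residual.intensity.copy()
    for pk in peaks:
        y -= pseudo_voigt(residual.shift, pk.center, pk.fwhm, pk.height, pk.eta)
    resid_spec = residual.with_intensity(y)
    ptp = float(y.max() - y.min()) if y.size else 0.0
    floor = max(min_snr * noise_sigma, 1e-3 * ptp, 1e-9)
    hump_height = None
    hump_center = None
    try:
        hump = fit_hump(resid_spec, w, min_fwhm=min_hump_fwhm)
        if hump.height >= floor:
            hump_height = hump.height
            hump_center = hump.center
    except (FitError, DomainError):
        pass
    if peaks:
        verdict = "distinct_peaks"
    elif hump_height is not None:
        verdict = "broad_hump_only"
    else:
        verdict = "featureless"
    return LatticeRegionSummary(
        peaks=peaks,
        hump_height=hump_height,
        hump_center=hump_center,
        verdict=verdict,
    )
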