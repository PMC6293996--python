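"""Overlay comparison of a query spectrum against references.

Mirrors the visual method of overlaying a digitized trace on reference
spectra: both are resampled to a common 1 cm^-1 grid inside a window
(default the 100-400 cm^-1 lattice region, the diagnostic zoom),
normalized on the window's tallest feature, and compared pointwise by
residual RMS and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DomainError
from .spectra_io import LATTICE_WINDOW, SpectralWindow, Spectrum, resample

__all__ = ["OverlayReport", "overlay_score", "rank_references"]

#: Minimum number of shared grid points for a meaningful comparison.
_MIN_OVERLAP = 10


@dataclass
class OverlayReport:
    reference: str
    residual_rms: float
    pearson_r: float
    window: SpectralWindow


def _common_grid(query: Spectrum, reference: Spectrum, w: SpectralWindow, step: float = 1.0):
    lo = max(w.lo, query.span[0], reference.span[0])
    hi = min(w.hi, query.span[1], reference.span[1])
    if hi - lo < (_MIN_OVERLAP - 1) * step:
        raise DomainError(
            f"insufficient overlap between spectra inside [{w.lo}, {w.hi}]"
        )
    q = resample(query, step, lo, hi)
    r = resample(reference, step, lo, hi)
    return q.intensity, r.intensity


def _normalize_on_max(y: np.ndarray) -> np.ndarray:
    peak = float(np.abs(y).max())
    if peak == 0:
        raise DomainError("spectrum is identically zero inside the window")
    return y / peak


def overlay_score(
    query: Spectrum, reference: Spectrum, w: SpectralWindow = LATTICE_WINDOW
) -> OverlayReport:
    """Compare two baseline-subtracted spectra inside a window.

    Both are resampled onto a shared 1 cm^-1 grid and scaled by the
    tallest in-window feature (max |intensity|), making the report
    invariant to positive rescaling of either input.
    """
    yq, yr = _common_grid(query, reference, w)
    yq = _normalize_on_max(yq)
    yr = _normalize_on_max(yr)
    residual_rms = float(np.sqrt(np.mean((yq - yr) ** 2)))
    if np.std(yq) == 0 or np.std(yr) == 0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(yq, yr)[0, 1])
    name = reference.meta.get("name") or reference.meta.get("source", "")
    return OverlayReport(str(name), residual_rms, pearson, w)


def rank_references(
    query: Spectrum,
    references: list[Spectrum],
    w: SpectralWindow = LATTICE_WINDOW,
) -> list[OverlayReport]:
    """Score the query against each reference, best first.

    Ordered by descending Pearson correlation, ties broken by ascending
    residual RMS.
    """
    if not references:
        raise ConfigError("reference list is empty")
    reports = [overlay_score(query, ref, w) for ref in references]
    reports.sort(key=lambda r: (-r.pearson_r, r.residual_rms))
    return reports
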