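"""Phase classification of carbonate Raman spectra.

The decision procedure encodes two facts about calcium carbonates:

* Amorphous calcium carbonate (ACC) has no crystal lattice, so it cannot
  produce distinct lattice-mode peaks below 400 cm^-1.  Any spectrum
  with distinct lattice peaks is crystalline, whatever its nu1 width —
  lattice evidence always outranks the width criterion.
* ACC's disorder broadens the nu1 band (FWHM > 20 cm^-1), but Mg
  substitution broadens calcite's nu1 the same way, so a broad nu1
  without lattice peaks is ACC only up to an ambiguity that knowledge of
  the Mg content resolves.

The resulting tree: an acceptable nu1 fit is required (no carbonate
signature otherwise); distinct lattice peaks give a crystalline call
with the phase chosen by template matching (a broad nu1 on a calcite
match is read as disorder-broadened, i.e. high-Mg calcite); no lattice
peaks plus a broad nu1 gives ACC, flagged ambiguous unless the Mg
content is supplied; and a narrow nu1 with no lattice evidence is
contradictory, so the classifier refuses to call a phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, CoverageError, DomainError, FitError
from .peak_analysis import (
    DEFAULT_MIN_SNR,
    LatticeRegionSummary,
    PeakFit,
    fit_peak,
    summarize_lattice_region,
)
from .preprocess import estimate_baseline, estimate_noise_sigma, normalize, subtract_baseline
from .spectra_io import LATTICE_WINDOW, NU1_WINDOW, NU4_WINDOW, SpectralWindow, Spectrum, crop
from .templates import BUILTIN_TEMPLATES, MineralTemplate

__all__ = [
    "ClassificationThresholds",
    "ClassificationResult",
    "classify_spectrum",
    "match_templates",
    "format_report",
    "DEFAULT_THRESHOLDS",
]

#: Padding added to the nu1/nu4 windows for *fitting* so the wings of a
#: disorder-broadened band are sampled; the fitted center must still fall
#: inside the nominal window.
_NU1_FIT_PAD = 35.0
_NU4_FIT_PAD = 10.0
#: Absolute guard (cm^-1) when comparing a fitted FWHM against the
#: amorphous threshold, absorbing least-squares round-off at the boundary.
_FWHM_GUARD = 1e-4


@dataclass(frozen=True)
class ClassificationThresholds:
    """Tunable decision constants.

    acc_fwhm_min: nu1 FWHM (cm^-1) strictly above which a band counts as
    amorphous-broad.  mg_threshold: mol% MgCO3 at or above which calcite
    counts as high-Mg (the conventional low/high-Mg boundary).
    """

    acc_fwhm_min: float = 20.0
    nu1_window: SpectralWindow = NU1_WINDOW
    nu4_window: SpectralWindow = NU4_WINDOW
    lattice_window: SpectralWindow = LATTICE_WINDOW
    template_tolerance: float = 10.0
    min_snr: float = DEFAULT_MIN_SNR
    mg_threshold: float = 4.0

    def __post_init__(self):
        if self.acc_fwhm_min <= 0:
            raise ValueError("acc_fwhm_min must be positive")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class ClassificationResult:
    """A phase call with its per-criterion evidence."""

    phase: str  # aragonite | calcite | high_mg_calcite | acc | indeterminate
    crystalline: bool | None
    evidence: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)

    def to_dict(self) -> dict:
        def _peak(p):
            if p is None:
                return None
            return {
                "center": round(p.center, 4),
                "height": round(p.height, 6),
                "fwhm": round(p.fwhm, 4),
                "eta": round(p.eta, 4),
                "rmse": round(p.rmse, 6),
                "boundary": p.boundary,
            }

        ev = dict(self.evidence)
        out = {
            "phase": self.phase,
            "crystalline": self.crystalline,
            "flags": sorted(self.flags),
            "nu1": _peak(ev.get("nu1")),
            "nu4": _peak(ev.get("nu4")),
        }
        lat = ev.get("lattice")
        if lat is not None:
            out["lattice"] = {
                "verdict": lat.verdict,
                "peaks": [_peak(p) for p in lat.peaks],
                "hump_height": lat.hump_height,
                "hump_center": lat.hump_center,
            }
        if "template_scores" in ev:
            out["template_scores"] = [
                {"name": n, "score": round(sc, 4)} for n, sc in ev["template_scores"]
            ]
        return out


def match_templates(
    lattice_peaks: list[PeakFit],
    templates: list[MineralTemplate],
    tolerance: float = 10.0,
    nu4: PeakFit | None = None,
) -> list[tuple[str, float]]:
    """Score observed peak centers against each template.

    The score averages the fraction of observed lattice centers within
    ``tolerance`` of some template center with the fraction of template
    centers matched by some observation; when both the observation and
    the template have a nu4 band, its agreement joins the average as a
    third term.  Ties break toward the template with the smaller mean
    |center offset|.  Returns (name, score) ranked descending.
    """
    if not lattice_peaks:
        raise DomainError("need at least one fitted lattice peak to match")
    if not templates:
        raise ConfigError("no templates to match against")
    observed = np.array([p.center for p in lattice_peaks])
    ranked = []
    for t in templates:
        tc = np.array(t.lattice_centers, dtype=float)
        if tc.size == 0:
            frac_obs = 0.0
            frac_tmpl = 0.0
            mean_delta = np.inf
        else:
            d = np.abs(observed[:, None] - tc[None, :])
            frac_obs = float(np.mean(d.min(axis=1) <= tolerance))
            frac_tmpl = float(np.mean(d.min(axis=0) <= tolerance))
            mean_delta = float(d.min(axis=1).mean())
        parts = [frac_obs, frac_tmpl]
        if nu4 is not None and t.nu4_center is not None:
            parts.append(1.0 if abs(nu4.center - t.nu4_center) <= tolerance else 0.0)
        score = float(np.mean(parts))
        ranked.append((t.name, score, mean_delta))
    ranked.sort(key=lambda r: (-r[1], r[2], r[0]))
    return [(name, score) for name, score, _ in ranked]


def _fit_band(s, window, pad, noise_sigma, min_snr, span):
    """Fit one internal-mode band in a padded window; None if too weak."""
    w = SpectralWindow(max(window.lo - pad, span[0]), min(window.hi + pad, span[1]), window.name)
    try:
        seg = crop(s, window)
    except DomainError:
        return None
    init = float(seg.shift[np.argmax(seg.intensity)])
    try:
        pk = fit_peak(s, w, init, init_fwhm=5.0)
    except (FitError, DomainError):
        return None
    return pk


def classify_spectrum(
    s: Spectrum,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    mg_mol_percent: float | None = None,
    preprocess: bool = False,
    templates: dict[str, MineralTemplate] | None = None,
    noise_sigma: float | None = None,
) -> ClassificationResult:
    """Classify one spectrum as a carbonate phase.

    The spectrum must cover the lattice through nu1 windows.  With
    ``preprocess=True`` the fluorescence baseline is estimated and
    subtracted and the result normalized on the nu1 window first;
    otherwise the input is assumed baseline-subtracted already.
    """
    th = thresholds
    templates = templates if templates is not None else BUILTIN_TEMPLATES
    lo, hi = s.span
    missing = [
        w.name
        for w in (th.lattice_window, th.nu1_window)
        if w.lo < lo or w.hi > hi
    ]
    if missing:
        raise CoverageError(
            f"spectrum span [{lo}, {hi}] does not cover windows: {missing}",
            missing=missing,
        )
    if preprocess:
        base = estimate_baseline(s)
        s = subtract_baseline(s, base)
        s = normalize(s, th.nu1_window)
    if noise_sigma is None:
        noise_sigma = estimate_noise_sigma(s)

    evidence: dict = {}
    flags: set = set()

    # (1) nu1: the universal carbonate band; nothing acceptable -> no call
    nu1 = _fit_band(s, th.nu1_window, _NU1_FIT_PAD, noise_sigma, th.min_snr, (lo, hi))
    nu1_ok = (
        nu1 is not None
        and not nu1.boundary
        and th.nu1_window.lo <= nu1.center <= th.nu1_window.hi
        and nu1.height >= max(th.min_snr * noise_sigma, 1e-9)
    )
    evidence["nu1"] = nu1
    if not nu1_ok:
        flags.add("low_snr")
        if nu1 is not None and nu1.boundary:
            flags.add("boundary_fit")
        return ClassificationResult("indeterminate", None, evidence, flags)
    if nu1.boundary:
        flags.add("boundary_fit")

    broad_nu1 = nu1.fwhm > th.acc_fwhm_min + _FWHM_GUARD

    # nu4 is supporting evidence, never required (truncated traces may
    # lack it entirely)
    nu4 = None
    if th.nu4_window.lo >= lo and th.nu4_window.hi <= hi:
        nu4 = _fit_band(s, th.nu4_window, _NU4_FIT_PAD, noise_sigma, th.min_snr, (lo, hi))
        if nu4 is not None and (
            nu4.boundary
            or nu4.height < max(th.min_snr * noise_sigma, 0.005 * nu1.height)
            or not (th.nu4_window.lo <= nu4.center <= th.nu4_window.hi)
        ):
            nu4 = None
    evidence["nu4"] = nu4

    # (2) lattice region: the crystallinity arbiter
    lattice = summarize_lattice_region(
        s, noise_sigma, w=th.lattice_window, min_snr=th.min_snr
    )
    evidence["lattice"] = lattice

    if lattice.verdict == "distinct_peaks":
        crystalline_templates = [
            t for t in templates.values() if t.lattice_peaks and t.hump is None
        ]
        scores = match_templates(
            lattice.peaks, crystalline_templates, th.template_tolerance, nu4=nu4
        )
        evidence["template_scores"] = scores
        best = scores[0][0]
        phase = "calcite" if best == "high_mg_calcite" else best
        if broad_nu1 and phase == "calcite":
            # distinct calcite lattice + disorder-broadened nu1: the
            # crystalline phase that mimics ACC in width
            phase = "high_mg_calcite"
        return ClassificationResult(phase, True, evidence, flags)

    # (3) no distinct lattice peaks
    if broad_nu1:
        if mg_mol_percent is None:
            flags.add("mg_unknown_ambiguity")
            phase = "acc"
        elif mg_mol_percent >= th.mg_threshold:
            phase = "high_mg_calcite"
        else:
            phase = "acc"
        return ClassificationResult(phase, False, evidence, flags)

    # (4) narrow nu1 but no lattice evidence: contradictory; refuse to call
    return ClassificationResult("indeterminate", False, evidence, flags)


def format_report(result: ClassificationResult, source: str = "") -> str:
    """Stable line-oriented text report for one classification."""
    d = result.to_dict()
    lines = []
    if source:
        lines.append(f"source: {source}")
    lines.append(f"phase: {d['phase']}")
    lines.append(f"crystalline: {d['crystalline']}")
    lines.append(f"flags: {','.join(d['flags']) if d['flags'] else '-'}")
    if d["nu1"]:
        p = d["nu1"]
        lines.append(
            f"nu1: center={p['center']:.2f} fwhm={p['fwhm']:.2f} height={p['height']:.4f}"
        )
    if d["nu4"]:
        p = d["nu4"]
        lines.append(
            f"nu4: center={p['center']:.2f} fwhm={p['fwhm']:.2f} height={p['height']:.4f}"
        )
    lat = d.get("lattice")
    if lat:
        lines.append(f"lattice: verdict={lat['verdict']}")
        for p in lat["peaks"]:
            lines.append(
                f"lattice_peak: center={p['center']:.2f} fwhm={p['fwhm']:.2f} "
                f"height={p['height']:.4f}"
            )
        if lat["hump_height"] is not None:
            lines.append(
                f"lattice_hump: center={lat['hump_center']:.1f} "
                f"height={lat['hump_height']:.4f}"
            )
    for entry in d.get("template_scores", []):
        lines.append(f"template: {entry['name']} score={entry['score']:.4f}")
    return "\n".join(lines) + "\n"
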