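"""Synthetic Raman spectrum generator with known ground truth.

Spectra are built as sums of pseudo-Voigt bands from a mineral template
— narrow crystalline nu1/nu4/lattice peaks, a disorder-broadened nu1 for
high-Mg calcite and ACC, and for ACC a wide lattice-region hump with no
narrow peaks — plus an optional smooth fluorescence background and
additive white Gaussian detector noise.  Every true parameter is
recorded in the output metadata so recovery can be tested, and the same
spec always produces bit-identical output.

Noise is drawn before the background term is added, so the noise
realization for a given seed is independent of the background choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .peak_analysis import pseudo_voigt
from .spectra_io import DEFAULT_GRID, Spectrum
from .templates import BUILTIN_TEMPLATES, MineralTemplate, get_template

__all__ = ["SynthesisSpec", "make_template_spectrum", "make_batch", "render_template"]

#: Gaussian/Lorentzian mixing fraction used for all synthetic bands.
DEFAULT_ETA = 0.5


@dataclass(frozen=True)
class SynthesisSpec:
    """Everything needed to generate one synthetic spectrum.

    background is ``None`` / ``"none"`` for no background, or a tuple
    ``("linear", amplitude)`` / ``("quadratic", amplitude)`` where the
    amplitude is the total rise across the grid span in units of the nu1
    height.  noise_sigma is likewise a fraction of the nu1 height.
    """

    phase: str
    grid: tuple[float, float, float] = DEFAULT_GRID
    noise_sigma: float = 0.0
    background: tuple[str, float] | str | None = None
    nu1_fwhm_override: float | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ValueError(f"bad grid {self.grid}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _grid_array(grid) -> np.ndarray:
    lo, hi, step = grid
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def render_template(
    template: MineralTemplate,
    x: np.ndarray,
    nu1_fwhm_override: float | None = None,
    eta: float = DEFAULT_ETA,
) -> np.ndarray:
    """Evaluate a template's noiseless signal on a grid."""
    c1, f1, h1 = template.nu1
    if nu1_fwhm_override is not None:
        f1 = nu1_fwhm_override
    y = pseudo_voigt(x, c1, f1, h1, eta)
    for c, f, h in template.lattice_peaks:
        y = y + pseudo_voigt(x, c, f, h, eta)
    if template.nu4 is not None:
        c, f, h = template.nu4
        y = y + pseudo_voigt(x, c, f, h, eta)
    if template.hump is not None:
        c, f, h = template.hump
        y = y + pseudo_voigt(x, c, f, h, eta)
    return y


def _background_array(background, x: np.ndarray) -> tuple[np.ndarray, dict]:
    if background is None or background == "none":
        return np.zeros_like(x), {"kind": "none"}
    kind, amp = background
    t = (x - x[0]) / (x[-1] - x[0])
    if kind == "linear":
        return amp * t, {"kind": kind, "amplitude": amp}
    if kind == "quadratic":
        return amp * t**2, {"kind": kind, "amplitude": amp}
    raise ConfigError(f"unknown background kind {kind!r}")


def make_template_spectrum(spec: SynthesisSpec) -> Spectrum:
    """Generate one synthetic spectrum with true parameters in metadata."""
    if spec.phase not in BUILTIN_TEMPLATES:
        raise ConfigError(
            f"unknown phase {spec.phase!r}; known: {sorted(BUILTIN_TEMPLATES)}"
        )
    template = get_template(spec.phase)
    x = _grid_array(spec.grid)
    signal = render_template(template, x, spec.nu1_fwhm_override)
    rng = np.random.default_rng(spec.seed)
    nu1_height = template.nu1[2]
    noise = rng.normal(0.0, spec.noise_sigma * nu1_height, x.size) if spec.noise_sigma > 0 else np.zeros_like(x)
    background, bg_meta = _background_array(spec.background, x)
    y = signal + noise + background
    nu1_fwhm = spec.nu1_fwhm_override if spec.nu1_fwhm_override is not None else template.nu1[1]
    truth = {
        "phase": spec.phase,
        "nu1_center": template.nu1[0],
        "nu1_fwhm": nu1_fwhm,
        "nu1_height": nu1_height,
        "nu4_center": template.nu4_center,
        "lattice_centers": template.lattice_centers,
        "hump": template.hump,
        "eta": DEFAULT_ETA,
        "noise_sigma": spec.noise_sigma,
        "background": bg_meta,
        "seed": spec.seed,
    }
    return Spectrum(x, y, {"synthetic": True, "truth": truth})


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds from one master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def make_batch(
    phase: str,
    n: int,
    seed: int,
    noise_sigma: float = 0.0,
    background=None,
    grid=DEFAULT_GRID,
    nu1_fwhm_override: float | None = None,
) -> list[Spectrum]:
    """Generate ``n`` replicate spectra with seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i, child in enumerate(derive_seeds(seed, n)):
        spec = SynthesisSpec(
            phase=phase,
            grid=grid,
            noise_sigma=noise_sigma,
            background=background,
            nu1_fwhm_override=nu1_fwhm_override,
            seed=child,
        )
        s = make_template_spectrum(spec)
        s.meta["replicate"] = i
        out.append(s)
    return out
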