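"""Reading, writing, and regridding of Raman spectra.

A spectrum is a pair of aligned arrays: Raman shift (cm^-1, strictly
increasing) and intensity (arbitrary units).  Sources are two-column
whitespace- or comma-separated text files, including RRUFF-style exports
with ``#`` comment headers and irregular traces produced by figure
digitization.  All downstream analysis assumes a regular grid, obtained
with :func:`resample`; the package default is a 1.0 cm^-1 grid over
[100, 1300] cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, FormatError, InsufficientDataError

__all__ = [
    "Spectrum",
    "SpectralWindow",
    "NU1_WINDOW",
    "NU4_WINDOW",
    "LATTICE_WINDOW",
    "DEFAULT_GRID",
    "read_two_column",
    "write_csv",
    "resample",
    "crop",
]

#: Minimum number of points for a usable spectrum.
MIN_POINTS = 8

#: Default analysis grid: (lo, hi, step) in cm^-1.
DEFAULT_GRID = (100.0, 1300.0, 1.0)


@dataclass(frozen=True)
class SpectralWindow:
    """A closed spectral interval [lo, hi] in cm^-1 with a label."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, x) -> np.ndarray:
        return (np.asarray(x) >= self.lo) & (np.asarray(x) <= self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def padded(self, pad: float) -> "SpectralWindow":
        return SpectralWindow(self.lo - pad, self.hi + pad, self.name)


#: Symmetric C-O stretch of carbonate: the strongest band in every
#: calcium carbonate, found between 1080 and 1090 cm^-1.
NU1_WINDOW = SpectralWindow(1080.0, 1090.0, "nu1")

#: In-plane C-O bend; its position separates calcite from aragonite.
NU4_WINDOW = SpectralWindow(700.0, 720.0, "nu4")

#: Lattice (external) modes: inter-molecular vibrations present only in
#: crystalline phases, below 400 cm^-1.
LATTICE_WINDOW = SpectralWindow(100.0, 400.0, "lattice")


@dataclass
class Spectrum:
    """Paired Raman shift / intensity arrays with provenance metadata.

    Invariants enforced at construction: shift strictly increasing, both
    arrays finite, equal length.  Files must supply at least
    :data:`MIN_POINTS` rows; derived spectra (e.g. narrow crops) may be
    shorter, down to 2 points.
    """

    shift: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("shift and intensity must be 1-D arrays")
        if self.shift.size != self.intensity.size:
            raise ValueError(
                f"length mismatch: {self.shift.size} shifts vs "
                f"{self.intensity.size} intensities"
            )
        if self.shift.size < 2:
            raise InsufficientDataError(
                f"spectrum needs >= 2 points, got {self.shift.size}"
            )
        if not np.all(np.isfinite(self.shift)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum contains non-finite values")
        if not np.all(np.diff(self.shift) > 0):
            raise ValueError("shift values must be strictly increasing")

    def __len__(self) -> int:
        return self.shift.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.shift[0]), float(self.shift[-1])

    def grid_step(self) -> float | None:
        """Return the grid step if the grid is regular, else None."""
        d = np.diff(self.shift)
        step = d[0]
        if np.allclose(d, step, rtol=1e-6, atol=1e-9):
            return float(step)
        return None

    def with_intensity(self, intensity, **meta) -> "Spectrum":
        new_meta = {**self.meta, **meta}
        return Spectrum(self.shift.copy(), np.asarray(intensity, dtype=float), new_meta)

    def copy(self) -> "Spectrum":
        return Spectrum(self.shift.copy(), self.intensity.copy(), dict(self.meta))


def _parse_row(line: str):
    parts = line.replace(",", " ").split()
    if len(parts) < 2:
        return None
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        return None


def read_two_column(path) -> Spectrum:
    """Read a two-column (shift, intensity) text file into a Spectrum.

    Accepts whitespace- or comma-separated columns, ``#``/``##`` comment
    lines, and a single non-numeric header row (e.g. ``shift,intensity``).
    Rows are sorted by ascending shift and duplicate shift values are
    collapsed to the mean of their intensities.
    """
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parsed = _parse_row(line)
            if parsed is None:
                # tolerate one leading header row of column names
                if not rows and not header_seen:
                    header_seen = True
                    continue
                raise FormatError(
                    f"{path}: cannot parse line {lineno}: {line!r}"
                )
            rows.append(parsed)
    if len(rows) < MIN_POINTS:
        raise InsufficientDataError(
            f"{path}: found {len(rows)} data rows, need >= {MIN_POINTS}"
        )
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # collapse duplicate shift values by mean intensity (digitized traces
    # frequently repeat x values)
    uniq, inverse, counts = np.unique(arr[:, 0], return_inverse=True, return_counts=True)
    sums = np.zeros_like(uniq)
    np.add.at(sums, inverse, arr[:, 1])
    intens = sums / counts
    return Spectrum(uniq, intens, {"source": str(path)})


def write_csv(s: Spectrum, path) -> None:
    """Write a spectrum as ``shift,intensity`` CSV with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("shift,intensity\n")
        for x, y in zip(s.shift, s.intensity):
            fh.write(f"{x:.6g},{y:.6g}\n")


def resample(s: Spectrum, grid_step: float, lo: float, hi: float) -> Spectrum:
    """Linearly interpolate a spectrum onto the regular grid lo, lo+step, ...

    Grid points outside the source span are dropped — never extrapolated,
    because digitized traces end mid-feature and extrapolating would
    fabricate spectral content.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(np.floor((hi - lo) / grid_step + 1e-9)) + 1
    grid = lo + grid_step * np.arange(n)
    src_lo, src_hi = s.span
    keep = (grid >= src_lo) & (grid <= src_hi)
    grid = grid[keep]
    if grid.size == 0:
        raise DomainError(
            f"grid [{lo}, {hi}] does not overlap spectrum span [{src_lo}, {src_hi}]"
        )
    intens = np.interp(grid, s.shift, s.intensity)
    meta = {**s.meta, "resampled": {"step": grid_step, "lo": lo, "hi": hi}}
    return Spectrum(grid, intens, meta)


def crop(s: Spectrum, w: SpectralWindow) -> Spectrum:
    """Return the points with lo <= shift <= hi (closed on both ends)."""
    mask = w.contains(s.shift)
    if not mask.any():
        raise DomainError(
            f"window [{w.lo}, {w.hi}] does not overlap spectrum span {s.span}"
        )
    meta = {**s.meta, "crop": (w.lo, w.hi)}
    return Spectrum(s.shift[mask], s.intensity[mask], meta)
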