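"""Built-in mineral templates: expected band positions and widths.

Anchored constants: calcite lattice modes near 150 and 280 cm^-1, every
nu1 center inside [1080, 1090] cm^-1, crystalline nu4 inside
[700, 720] cm^-1, all lattice modes below 400 cm^-1, and a >20 cm^-1
nu1 FWHM for disordered phases.  The remaining center/width/height
constants are package conventions consistent with the RRUFF reference
spectra for aragonite (R080142) and calcite (R150075); heights are
fractions of the nu1 height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError

__all__ = ["MineralTemplate", "BUILTIN_TEMPLATES", "get_template", "load_templates"]


@dataclass(frozen=True)
class MineralTemplate:
    """A named phase's expected peaks, used for synthesis and matching.

    lattice_peaks / nu4 / nu1 entries are (center cm^-1, FWHM cm^-1,
    height as a fraction of nu1 height).  ``hump`` describes a broad
    lattice-region component for amorphous phases, or None.
    """

    name: str
    nu1: tuple[float, float, float]
    lattice_peaks: tuple[tuple[float, float, float], ...] = ()
    nu4: tuple[float, float, float] | None = None
    hump: tuple[float, float, float] | None = None

    def __post_init__(self):
        for c, _, _ in self.lattice_peaks:
            if c > 400:
                raise ValueError(f"{self.name}: lattice center {c} above 400 cm^-1")
        if not 1080 <= self.nu1[0] <= 1090:
            raise ValueError(f"{self.name}: nu1 center {self.nu1[0]} outside [1080, 1090]")
        if self.nu4 is not None and not 700 <= self.nu4[0] <= 720:
            raise ValueError(f"{self.name}: nu4 center {self.nu4[0]} outside [700, 720]")

    @property
    def lattice_centers(self) -> list[float]:
        return [c for c, _, _ in self.lattice_peaks]

    @property
    def nu4_center(self) -> float | None:
        return self.nu4[0] if self.nu4 else None

    @property
    def nu1_center(self) -> float:
        return self.nu1[0]

    @property
    def nu1_fwhm(self) -> float:
        return self.nu1[1]


BUILTIN_TEMPLATES: dict[str, MineralTemplate] = {
    # Calcite: lattice modes at 150 and 280 cm^-1, nu4 near 712, narrow nu1.
    "calcite": MineralTemplate(
        name="calcite",
        nu1=(1086.0, 5.0, 1.0),
        lattice_peaks=((150.0, 8.0, 0.3), (280.0, 10.0, 0.5)),
        nu4=(712.0, 5.0, 0.08),
    ),
    # Aragonite: lattice doublet region ~152/206, nu4 near 705.
    "aragonite": MineralTemplate(
        name="aragonite",
        nu1=(1085.0, 4.0, 1.0),
        lattice_peaks=((152.0, 7.0, 0.35), (206.0, 9.0, 0.4)),
        nu4=(705.0, 4.0, 0.1),
    ),
    # High-Mg calcite: calcite peak set with a disorder-broadened nu1
    # (24 cm^-1, above the 20 cm^-1 amorphous criterion) and the lattice
    # peaks retained — the confound that makes Mg content necessary to
    # separate it from ACC by nu1 width alone.
    "high_mg_calcite": MineralTemplate(
        name="high_mg_calcite",
        nu1=(1087.0, 24.0, 1.0),
        lattice_peaks=((150.0, 12.0, 0.25), (280.0, 14.0, 0.4)),
        nu4=(712.0, 8.0, 0.06),
    ),
    # ACC: broad nu1 (28 cm^-1), no distinct lattice peaks, and a broad
    # ordering hump in the lattice region (center 200, FWHM 150, height
    # 0.15 of nu1).
    "acc": MineralTemplate(
        name="acc",
        nu1=(1085.0, 28.0, 1.0),
        lattice_peaks=(),
        nu4=None,
        hump=(200.0, 150.0, 0.15),
    ),
}


def get_template(name: str) -> MineralTemplate:
    try:
        return BUILTIN_TEMPLATES[name]
    except KeyError:
        raise ConfigError(
            f"unknown phase {name!r}; known: {sorted(BUILTIN_TEMPLATES)}"
        ) from None


def load_templates(path) -> dict[str, MineralTemplate]:
    """Read templates from a small structured text file.

    Line format (``#`` comments allowed)::

        name nu1=center,fwhm lattice=c1:f1:h1;c2:f2:h2 [nu4=center,fwhm,height]

    Heights default to sensible fractions when omitted.
    """
    out: dict[str, MineralTemplate] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            name = fields[0]
            kw: dict = {"name": name, "lattice_peaks": (), "nu4": None}
            for tok in fields[1:]:
                key, _, val = tok.partition("=")
                if key == "nu1":
                    parts = [float(v) for v in val.split(",")]
                    while len(parts) < 3:
                        parts.append([5.0, 1.0][len(parts) - 1])
                    kw["nu1"] = tuple(parts[:3])
                elif key == "lattice":
                    pks = []
                    for entry in val.split(";"):
                        if not entry:
                            continue
                        nums = [float(v) for v in entry.split(":")]
                        while len(nums) < 3:
                            nums.append([8.0, 0.3][len(nums) - 1])
                        pks.append(tuple(nums[:3]))
                    kw["lattice_peaks"] = tuple(pks)
                elif key == "nu4":
                    nums = [float(v) for v in val.split(",")]
                    while len(nums) < 3:
                        nums.append([5.0, 0.08][len(nums) - 1])
                    kw["nu4"] = tuple(nums[:3])
                elif key == "hump":
                    nums = [float(v) for v in val.split(",")]
                    kw["hump"] = tuple(nums[:3])
                else:
                    raise ConfigError(f"unknown template field {key!r} in {line!r}")
            if "nu1" not in kw:
                raise ConfigError(f"template {name!r} missing nu1=center,fwhm")
            out[name] = MineralTemplate(**kw)
    if not out:
        raise ConfigError(f"no templates found in {path}")
    return out
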