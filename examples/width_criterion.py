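"""Locate the amorphous decision boundary on the nu1 width axis.

Sweeps the nu1 FWHM of a lattice-featureless spectrum (an ACC-style
hump, no distinct lattice peaks) over integer widths 10-30 cm^-1 and
prints the phase call at each width.  The criterion is a strict
inequality — only widths above 20 cm^-1 are amorphous-broad — so 20 is
the largest width not called ACC; narrow-nu1 spectra without lattice
peaks are contradictory and stay indeterminate.
"""

from carbphase import classify_spectrum
from carbphase.synthetic_data import SynthesisSpec, make_template_spectrum

last_not_acc = None
for fwhm in range(10, 31):
    s = make_template_spectrum(SynthesisSpec(phase="acc", nu1_fwhm_override=float(fwhm)))
    phase = classify_spectrum(s, preprocess=True).phase
    print(f"nu1 FWHM {fwhm:2d} cm^-1  ->  {phase}")
    if phase != "acc":
        last_not_acc = fwhm
print(f"\nlargest nu1 FWHM not flagged amorphous: {last_not_acc} cm^-1")
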