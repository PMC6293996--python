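"""Round-trip a spectrum through files, like working with digitized traces.

Writes a synthetic high-Mg calcite spectrum to CSV, reads it back,
regularizes it onto the standard 1 cm^-1 analysis grid (digitized traces
have irregular knots, so resampling is always the first step), and
classifies it.  The same flow works on any two-column text export,
including RRUFF-style files with '#' headers.
"""

import tempfile
from pathlib import Path

from carbphase import classify_spectrum, format_report, read_two_column, resample, write_csv
from carbphase.synthetic_data import SynthesisSpec, make_template_spectrum

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "trace.csv"
    original = make_template_spectrum(
        SynthesisSpec(phase="high_mg_calcite", noise_sigma=0.01,
                      background=("quadratic", 1.5), seed=5)
    )
    write_csv(original, path)

    trace = read_two_column(path)
    lo, hi = trace.span
    regular = resample(trace, 1.0, lo, hi)
    result = classify_spectrum(regular, preprocess=True)
    print(format_report(result, source=path.name))
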