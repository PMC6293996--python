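"""Shared fixtures: synthetic spectra and pipeline runs reused across tests."""

import numpy as np
import pytest

from carbphase import classify_spectrum
from carbphase.synthetic_data import SynthesisSpec, derive_seeds, make_template_spectrum

PHASES = ["aragonite", "calcite", "high_mg_calcite", "acc"]

#: Study conditions for the stochastic robustness check: replicates per
#: phase, detector noise as a fraction of the nu1 height, and random
#: fluorescence ramps up to a few nu1 heights across the span.
N_REPLICATES = 200
NOISE_SIGMA = 0.02


def make_noisy_replicates(phase, n, master_seed, noise_sigma=NOISE_SIGMA):
    """n replicates of a phase with seeded noise and random ramps."""
    rng = np.random.default_rng(master_seed + 7)
    out = []
    for i, seed in enumerate(derive_seeds(master_seed, n)):
        kind = ["none", "linear", "quadratic"][i % 3]
        bg = None if kind == "none" else (kind, float(rng.uniform(0.5, 3.0)))
        out.append(
            make_template_spectrum(
                SynthesisSpec(phase=phase, noise_sigma=noise_sigma, background=bg, seed=seed)
            )
        )
    return out


@pytest.fixture(scope="session")
def noiseless_spectra():
    return {
        phase: make_template_spectrum(SynthesisSpec(phase=phase)) for phase in PHASES
    }


@pytest.fixture(scope="session")
def noiseless_results(noiseless_spectra):
    return {
        phase: classify_spectrum(s, preprocess=True)
        for phase, s in noiseless_spectra.items()
    }


@pytest.fixture(scope="session")
def noisy_phase_calls():
    """Phase calls for N_REPLICATES noisy replicates per phase.

    Computed once per session; consumed by both the classifier property
    test and the acceptance check.
    """
    calls = {}
    for phase in PHASES:
        spectra = make_noisy_replicates(phase, N_REPLICATES, master_seed=20260926)
        calls[phase] = [classify_spectrum(s, preprocess=True).phase for s in spectra]
    return calls
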