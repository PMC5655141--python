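import numpy as np
import pytest

from docklink.nmr import (
    estimate_populations,
    measure_peak_intensity,
    pair_doublets,
)
from docklink.pipeline import estimate_noise_sigma
from docklink.synthetic import (
    EnsembleGroundTruth,
    default_grid,
    default_probes,
    generate_spectrum_pair,
)


@pytest.fixture
def three_probe_truth():
    """Canonical three-doublet ensemble: p_D = 0.53, 0.03/0.4 ppm splittings."""
    return EnsembleGroundTruth(
        docked_fraction=0.53, probes=default_probes(), noise_sigma=0.0, seed=0
    )


def quantify_pair(truth: EnsembleGroundTruth):
    """Full measurement path: simulate -> measure -> pair -> estimate.

    Returns (PopulationEstimate, PairingResult).  Used by unit, property and
    acceptance tests alike so they all exercise the same code path.
    """
    full, ref = generate_spectrum_pair(truth)
    ref_peaks = [
        measure_peak_intensity(ref, (p.delta_h, p.delta_c), assignment=p.label)
        for p in truth.probes
    ]
    fl_positions = []
    for k, p in enumerate(truth.probes):
        fl_positions.append((f"pk{2 * k + 1}", p.delta_h, p.delta_c))
        fl_positions.append(
            (f"pk{2 * k + 2}", p.delta_h + p.offset_h, p.delta_c + p.offset_c)
        )
    fl_peaks = [
        measure_peak_intensity(full, (h, c), assignment=a) for a, h, c in fl_positions
    ]
    pairing = pair_doublets(fl_peaks, ref_peaks)
    noise = (
        estimate_noise_sigma(full, fl_peaks) if truth.noise_sigma > 0 else None
    )
    estimate = estimate_populations(pairing.doublets, noise_sigma=noise)
    return estimate, pairing


@pytest.fixture
def small_grid():
    """Default axes, handy for lineshape tests."""
    return default_grid()
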