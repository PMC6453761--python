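"""Shared fixtures: small geometries and cached simulations.

Session-scoped fixtures hold the expensive simulations (projection +
reconstruction) so many tests can score the same images.
"""

import numpy as np
import pytest

from abhc import materials, phantoms, simulator

#: Reference energy matching the default 120 kVp spectrum's iodine
#: response (see experiments.effective_reference_energy).
REF_120 = 61.0


@pytest.fixture(scope="session")
def small_geometry():
    return simulator.Geometry(128, 0.95, 160)


@pytest.fixture(scope="session")
def spectrum_120():
    return materials.make_spectrum(120)


@pytest.fixture(scope="session")
def cylinder_phantom():
    return phantoms.make_cylinder_phantom()


@pytest.fixture(scope="session")
def cylinder_images(small_geometry, spectrum_120, cylinder_phantom):
    """(polyenergetic water-precorrected, monoenergetic reference) pair."""
    geom = small_geometry
    ph = cylinder_phantom
    sino = simulator.project_poly(ph, spectrum_120, geom)
    sino = simulator.water_precorrect(sino, spectrum_120, REF_120)
    img = simulator.reconstruct_fbp(sino, geom, REF_120)
    mono = simulator.reconstruct_fbp(
        simulator.project_mono(ph, REF_120, geom), geom, REF_120
    )
    return img, mono


@pytest.fixture(scope="session")
def mono_cardiac_series():
    """Noise-free monoenergetic dynamic cardiac series (BH-free control)."""
    from abhc import experiments

    series, ph, ref = experiments.simulate_cardiac_series(
        "mono", n_pixels=128, n_angles=160, pixel_size_mm=0.95,
        noise_seed=None, target_snr=None,
    )
    return series, ph, ref


@pytest.fixture(scope="session")
def noisy_cardiac_series():
    """Polyenergetic 120 kVp series with Poisson noise at SNR ~9.8."""
    from abhc import experiments

    series, ph, ref = experiments.simulate_cardiac_series(
        120, n_pixels=128, n_angles=160, pixel_size_mm=0.95, noise_seed=5
    )
    return series, ph, ref
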