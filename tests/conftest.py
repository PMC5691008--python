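"""Shared fixtures: characterized synthetic scanner, phantoms, transport setups.

Session-scoped because characterization and numba compilation are the
expensive steps; every test that consumes these treats them as read-only.
"""

import numpy as np
import pytest

from ctkvdose.dose_engine import TransportSetup
from ctkvdose.geometry import VoxelPhantom
from ctkvdose.materials import get_material
from ctkvdose.source_model import (SourceModel, SpectrumField,
                                   build_fluence_grid, characterize_source,
                                   default_axial_profile)
from ctkvdose.spectrum import Spectrum
from ctkvdose.synthetic import (SyntheticScanner, make_pmma_cylinder_fixture,
                                simulate_air_dose_profiles,
                                simulate_hvl_campaign)

HVL_X_GRID = np.arange(0.0, 18.1, 2.0)


def characterize_scanner(scanner: SyntheticScanner) -> SourceModel:
    """Noiseless campaign -> characterized source model."""
    meas = simulate_hvl_campaign(scanner, HVL_X_GRID, noise_rel=0.0)
    zs = default_axial_profile(scanner.collimation_z_cm, scanner.penumbra_cm)[0]
    air_x, air_z = simulate_air_dose_profiles(scanner, HVL_X_GRID, zs)
    return characterize_source(scanner.kvp, scanner.sad_cm, meas, air_x,
                               air_z, scanner.collimation_z_cm)


@pytest.fixture(scope="session")
def scanner():
    return SyntheticScanner()


@pytest.fixture(scope="session")
def pmma_model(scanner):
    return characterize_scanner(scanner)


@pytest.fixture(scope="session")
def pmma_fixture():
    phantom, pois, names = make_pmma_cylinder_fixture()
    return phantom, pois, names


@pytest.fixture(scope="session")
def pmma_setup(pmma_model, pmma_fixture):
    return TransportSetup(pmma_model, pmma_fixture[0])


@pytest.fixture(scope="session")
def water_slab_case():
    """Static monoenergetic 60 keV beam on a homogeneous 10 cm water cube."""
    water = get_material("water")
    n = 40
    phantom = VoxelPhantom(
        origin_cm=np.array([-5.0, -5.0, -5.0]),
        spacing_cm=np.array([0.25, 0.25, 0.25]),
        material_index=np.zeros((n, n, n), dtype=np.int16),
        density=np.full((n, n, n), 1.0),
        materials=[water],
    )
    e = np.arange(1.0, 61.0)
    counts = np.zeros_like(e)
    counts[-1] = 1.0
    spec = Spectrum(kvp=60.0, energies=e, counts=counts)
    field = SpectrumField(x_positions_cm=np.array([0.0]), spectra=(spec,),
                          kvp=60.0)
    lat = np.linspace(-3.0, 3.0, 25)
    grid = build_fluence_grid((lat, np.ones_like(lat)),
                              (lat.copy(), np.ones_like(lat)))
    model = SourceModel(sad_cm=64.5, kvp=60.0, spectrum_field=field,
                        fluence_grid=grid, collimation_z_cm=6.0,
                        rotating=False)
    return model, phantom
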