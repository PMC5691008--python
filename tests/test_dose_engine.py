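"""Dose engine: deterministic primary, MC scatter, bookkeeping, metrics."""

import numpy as np
import pytest

from ctkvdose.dose_engine import (TransportSetup, compute_dose,
                                  convergence_study, percent_difference,
                                  primary_dose, scatter_dose,
                                  volume_effect_uncertainty)
from ctkvdose.geometry import VoxelPhantom
from ctkvdose.materials import get_material
from ctkvdose.source_model import (SourceModel, SpectrumField,
                                   build_fluence_grid)
from ctkvdose.spectrum import Spectrum


def static_model(e_kev=60.0, half_width=3.0):
    e = np.arange(1.0, np.floor(e_kev) + 0.5)
    counts = np.zeros_like(e)
    counts[-1] = 1.0
    spec = Spectrum(kvp=e_kev, energies=e, counts=counts)
    field = SpectrumField(x_positions_cm=np.array([0.0]), spectra=(spec,),
                          kvp=e_kev)
    lat = np.linspace(-half_width, half_width, 25)
    grid = build_fluence_grid((lat, np.ones_like(lat)),
                              (lat.copy(), np.ones_like(lat)))
    return SourceModel(sad_cm=64.5, kvp=e_kev, spectrum_field=field,
                       fluence_grid=grid, collimation_z_cm=2 * half_width,
                       rotating=False)


def box_phantom(material_name, density, n=20, spacing=0.5):
    mat = get_material(material_name)
    half = n * spacing / 2
    return VoxelPhantom(
        origin_cm=np.array([-half] * 3),
        spacing_cm=np.array([spacing] * 3),
        material_index=np.zeros((n, n, n), dtype=np.int16),
        density=np.full((n, n, n), density),
        materials=[mat],
    )


class TestPrimaryDose:
    def test_inverse_square_in_vacuum(self):
        model = static_model()
        ph = box_phantom("water", 0.0)
        pois = np.array([[0.0, 2.0, 0.0], [0.0, -3.0, 0.0]])
        d = primary_dose(model, ph, pois, n_angles=1)
        r1 = model.sad_cm - 2.0
        r2 = model.sad_cm + 3.0
        assert d[0] / d[1] == pytest.approx((r2 / r1) ** 2, rel=1e-9)

    def test_closed_form_attenuation_with_depth(self):
        model = static_model(60.0)
        ph = box_phantom("water", 1.0)
        pois = np.array([[0.0, 4.0, 0.0], [0.0, 0.0, 0.0]])  # depths 1, 5 cm
        d = primary_dose(model, ph, pois, n_angles=1)
        mu = get_material("water").linear_attenuation(60.0)
        r1 = model.sad_cm - 4.0
        r2 = model.sad_cm
        expected = np.exp(-mu * 4.0) * (r1 / r2) ** 2
        assert d[1] / d[0] == pytest.approx(expected, rel=1e-6)

    def test_rotational_symmetry_of_deterministic_sum(self, pmma_model,
                                                      pmma_fixture,
                                                      pmma_setup):
        phantom, pois, names = pmma_fixture
        ring = pois[1:5]  # the four equal-radius shallow positions
        d = primary_dose(pmma_model, phantom, ring, n_angles=360,
                         setup=pmma_setup)
        assert d.max() / d.min() - 1 < 1e-6

    def test_poi_outside_grid_rejected(self, pmma_model, pmma_fixture):
        phantom, _, _ = pmma_fixture
        with pytest.raises(ValueError):
            primary_dose(pmma_model, phantom, np.array([[100.0, 0, 0]]))


class TestScatterDose:
    def test_zero_density_phantom_scatters_nothing(self):
        model = static_model()
        ph = box_phantom("water", 0.0)
        f, m, s = scatter_dose(model, ph, np.array([[0.0, 0.0, 0.0]]),
                               5000, seed=1)
        assert f[0] == 0.0 and m[0] == 0.0

    def test_fixed_seed_is_bit_reproducible(self, pmma_model, pmma_fixture,
                                            pmma_setup):
        phantom, pois, _ = pmma_fixture
        a = scatter_dose(pmma_model, phantom, pois[:3], 5000, seed=42,
                         setup=pmma_setup)
        b = scatter_dose(pmma_model, phantom, pois[:3], 5000, seed=42,
                         setup=pmma_setup)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_result_independent_of_poi_order(self, pmma_model, pmma_fixture,
                                             pmma_setup):
        phantom, pois, _ = pmma_fixture
        f1, m1, _ = scatter_dose(pmma_model, phantom, pois[:4], 5000,
                                 seed=9, setup=pmma_setup)
        f2, m2, _ = scatter_dose(pmma_model, phantom, pois[:4][::-1], 5000,
                                 seed=9, setup=pmma_setup)
        np.testing.assert_array_equal(f1, f2[::-1])
        np.testing.assert_array_equal(m1, m2[::-1])

    def test_too_few_photons_rejected(self, pmma_model, pmma_fixture):
        phantom, pois, _ = pmma_fixture
        with pytest.raises(ValueError):
            scatter_dose(pmma_model, phantom, pois[:1], 100, seed=1)


@pytest.fixture(scope="module")
def results(pmma_model, pmma_fixture, pmma_setup):
    phantom, pois, names = pmma_fixture
    return compute_dose(pmma_model, phantom, pois, n_photons=20000,
                        seed=5, names=names, normalize_to="C",
                        setup=pmma_setup)


class TestComputeDose:
    def test_total_is_sum_of_components(self, results):
        for r in results:
            assert r.total == pytest.approx(
                r.primary + r.first_scatter + r.multi_scatter, rel=1e-12)

    def test_reference_poi_normalizes_to_one(self, results):
        assert results[0].name == "C"
        assert results[0].normalized == pytest.approx(1.0)

    def test_components_nonnegative_with_uncertainty(self, results):
        for r in results:
            assert r.primary >= 0 and r.first_scatter >= 0
            assert r.multi_scatter >= 0 and r.sigma_total >= 0

    def test_scatter_fraction_rises_toward_center(self, results):
        # depth order: alpha ring (1 cm), beta (2.5), gamma (4), center
        frac = {r.name: r.scatter_fraction for r in results}
        assert frac["alpha_0"] < frac["beta_0"] < frac["gamma_0"] \
            < frac["C"]


class TestPercentDifference:
    def test_equal_values_give_zero(self):
        assert percent_difference(1.7, 1.7) == 0.0

    def test_three_to_one_is_hundred_percent(self):
        assert percent_difference(3.0, 1.0) == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        assert percent_difference(1.02, 1.00) == pytest.approx(1.9802,
                                                               abs=1e-4)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 0.0)


class TestConvergenceStudy:
    def test_reference_level_self_comparison_is_zero(self, pmma_model,
                                                     pmma_fixture,
                                                     pmma_setup):
        phantom, pois, _ = pmma_fixture
        table = convergence_study(pmma_model, phantom, pois[:3],
                                  photon_counts=[2000, 8000],
                                  reference_count=8000, seed=3,
                                  setup=pmma_setup)
        total = table[(table.component == "total")
                      & (table.n_photons == 8000)]
        assert total.mean_abs_pct.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_deviation_decreases_with_seeding(self, pmma_model,
                                              pmma_fixture, pmma_setup):
        from scipy.stats import spearmanr

        phantom, pois, _ = pmma_fixture
        counts = [2000, 8000, 32000, 128000]
        table = convergence_study(pmma_model, phantom, pois[:5],
                                  photon_counts=counts,
                                  reference_count=256000, seed=17,
                                  setup=pmma_setup)
        total = table[table.component == "total"].sort_values("n_photons")
        rho, _ = spearmanr(total.n_photons, total.mean_abs_pct)
        assert rho < 0

    def test_reference_must_dominate_ladder(self, pmma_model, pmma_fixture):
        phantom, pois, _ = pmma_fixture
        with pytest.raises(ValueError):
            convergence_study(pmma_model, phantom, pois[:1],
                              photon_counts=[10000], reference_count=5000,
                              seed=1)


class TestVolumeEffect:
    def test_flat_region_has_small_spread(self, pmma_model, pmma_fixture,
                                          pmma_setup):
        phantom, pois, _ = pmma_fixture
        rel = volume_effect_uncertainty(pmma_model, phantom, pois[0],
                                        n_photons=20000, seed=21,
                                        setup=pmma_setup)
        assert rel < 0.05

    def test_shallow_poi_spread_exceeds_center(self, pmma_model,
                                               pmma_fixture, pmma_setup):
        phantom, pois, _ = pmma_fixture
        center = volume_effect_uncertainty(pmma_model, phantom, pois[0],
                                           n_photons=20000, seed=22,
                                           setup=pmma_setup)
        shallow = volume_effect_uncertainty(pmma_model, phantom, pois[1],
                                            n_photons=20000, seed=22,
                                            setup=pmma_setup)
        assert shallow > center

    def test_edge_point_outside_phantom_rejected(self, pmma_model,
                                                 pmma_fixture):
        phantom, _, _ = pmma_fixture
        edge = phantom.upper_cm - 0.1
        with pytest.raises(ValueError):
            volume_effect_uncertainty(pmma_model, phantom, edge,
                                      n_photons=2000, seed=1)
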