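"""Source assembly: spectrum field, fluence derivation, sampling, I/O."""

import numpy as np
import pytest
from scipy import stats

from ctkvdose.hvl_measurement import build_hvl_profile
from ctkvdose.source_model import (SourceModel, SpectrumField,
                                   build_fluence_grid, build_spectrum_field,
                                   default_axial_profile,
                                   derive_axial_fluence,
                                   derive_lateral_fluence, load_model,
                                   sample_photon, sample_photons, save_model)
from ctkvdose.spectrum import (air_kerma, compute_hvl, fit_filtration,
                               generate_spectrum)


@pytest.fixture(scope="module")
def bowtie_field():
    """Spectrum field from a known quadratic bow-tie at 120 kVp."""
    x = np.arange(0.0, 12.1, 2.0)
    t_true = 2.0 + 0.05 * x**2
    hvls = [(xi, compute_hvl(generate_spectrum(120, ti)))
            for xi, ti in zip(x, t_true)]
    profile = build_hvl_profile(hvls)
    return build_spectrum_field(120, profile, x), t_true


class TestBuildSpectrumField:
    def test_flat_profile_gives_identical_spectra(self):
        profile = build_hvl_profile([(0.0, 5.0), (2.0, 5.0), (4.0, 5.0)])
        field = build_spectrum_field(120, profile, np.array([0.0, 2.0, 4.0]))
        for s in field.spectra[1:]:
            np.testing.assert_allclose(s.counts, field.spectra[0].counts,
                                       atol=1e-9)

    def test_hardening_with_off_axis_distance(self, bowtie_field):
        field, _ = bowtie_field
        means = [s.mean_energy for s in field.spectra]
        assert np.all(np.diff(means) > 0)

    def test_recovers_true_filtration_within_tolerance(self, bowtie_field):
        field, t_true = bowtie_field
        fitted = np.array([s.filtration_mm_al for s in field.spectra])
        np.testing.assert_allclose(fitted, t_true, atol=0.02)

    def test_nearest_position_lookup_uses_absolute_x(self, bowtie_field):
        field, _ = bowtie_field
        assert field.spectrum_at(-4.1) is field.spectrum_at(4.1)


class TestDeriveFluence:
    def test_constant_spectrum_reduces_to_dose_ratio(self):
        profile = build_hvl_profile([(0.0, 5.0), (2.0, 5.0), (4.0, 5.0)])
        field = build_spectrum_field(120, profile, np.array([0.0, 2.0, 4.0]))
        dose = np.array([[0.0, 1.0], [2.0, 0.8], [4.0, 0.5]])
        xs, fl = derive_lateral_fluence(dose, field)
        np.testing.assert_allclose(fl, [1.0, 0.8, 0.5], rtol=1e-9)

    def test_normalized_at_isocenter(self, bowtie_field):
        field, _ = bowtie_field
        dose = np.column_stack([field.x_positions_cm,
                                np.linspace(1.0, 0.4, len(field.spectra))])
        _, fl = derive_lateral_fluence(dose, field)
        assert fl[0] == 1.0

    def test_round_trip_through_kerma_integral(self, bowtie_field):
        """Synthesize D(x) from a known fluence, then derive it back."""
        field, _ = bowtie_field
        truth = np.exp(-field.x_positions_cm**2 / 200.0)
        kermas = np.array([air_kerma(s) for s in field.spectra])
        dose = truth * kermas
        dose = dose / dose[0]
        _, fl = derive_lateral_fluence(
            np.column_stack([field.x_positions_cm, dose]), field)
        np.testing.assert_allclose(fl, truth, rtol=1e-3)

    def test_missing_isocenter_rejected(self, bowtie_field):
        field, _ = bowtie_field
        with pytest.raises(ValueError):
            derive_lateral_fluence(np.array([[2.0, 0.9], [4.0, 0.7]]), field)

    def test_axial_flat_profile_all_ones(self):
        z = np.linspace(-2, 2, 9)
        _, fl = derive_axial_fluence(np.column_stack([z, np.ones_like(z)]))
        np.testing.assert_array_equal(fl, 1.0)

    def test_axial_triangle_normalized_to_apex(self):
        z = np.array([-1.0, 0.0, 1.0])
        d = np.array([0.5, 2.0, 0.5])
        _, fl = derive_axial_fluence(np.column_stack([z, d]))
        np.testing.assert_allclose(fl, [0.25, 1.0, 0.25])

    def test_default_axial_profile_has_penumbra_support(self):
        z, v = default_axial_profile(2.0, penumbra_cm=0.4)
        support = z[v > 0]
        assert support.min() == pytest.approx(-1.4, abs=0.11)
        assert support.max() == pytest.approx(1.4, abs=0.11)
        core = v[np.abs(z) <= 0.99]
        np.testing.assert_allclose(core, 1.0)


class TestFluenceGrid:
    def test_outer_product_identity(self):
        lx = np.linspace(-4, 4, 9)
        lv = np.exp(-lx**2 / 8)
        az = np.linspace(-1, 1, 5)
        av = 1 - 0.3 * np.abs(az)
        grid = build_fluence_grid((lx, lv), (az, av))
        expected = np.outer(grid.lateral, grid.axial)
        np.testing.assert_allclose(grid.values, expected, atol=1e-12)

    def test_max_cell_is_one(self):
        lx = np.linspace(-4, 4, 9)
        grid = build_fluence_grid((lx, np.exp(-lx**2)),
                                  (np.linspace(-1, 1, 5), np.ones(5)))
        assert grid.values.max() == pytest.approx(1.0)

    def test_marginals_proportional_to_inputs(self):
        lx = np.linspace(-4, 4, 9)
        lv = np.exp(-lx**2 / 10)
        az = np.linspace(-1, 1, 5)
        av = 1 - 0.2 * np.abs(az)
        grid = build_fluence_grid((lx, lv), (az, av))
        row = grid.values.sum(axis=1)
        ratio = row / grid.lateral
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_positive_half_input_is_mirrored(self):
        lx = np.array([0.0, 2.0, 4.0])
        lv = np.array([1.0, 0.7, 0.4])
        grid = build_fluence_grid((lx, lv), (np.linspace(-1, 1, 5),
                                             np.ones(5)))
        assert len(grid.x_centers_cm) == 5
        np.testing.assert_allclose(grid.values, grid.values[::-1, :])


class TestSamplePhoton:
    def test_histogram_matches_fluence_grid(self, pmma_model):
        rng = np.random.default_rng(7)
        grid = pmma_model.fluence_grid
        n = 1_000_000
        origins, dirs, energies, weights = sample_photons(pmma_model, n, rng)
        assert np.all(weights == 1.0)
        assert energies.max() <= pmma_model.kvp
        # recover the isocenter-plane point in the gantry frame: intersect
        # the ray with the rotated plane through the isocenter whose normal
        # points at the source
        ox, oy = origins[:, 0], origins[:, 1]
        alpha = np.arctan2(ox, oy)
        nvx, nvy = np.sin(alpha), np.cos(alpha)
        s = -(ox * nvx + oy * nvy) / (dirs[:, 0] * nvx + dirs[:, 1] * nvy)
        px = ox + s * dirs[:, 0]
        py = oy + s * dirs[:, 1]
        x_g = px * np.cos(alpha) - py * np.sin(alpha)
        z = origins[:, 2] + s * dirs[:, 2]

        def chi2_p(samples, edges, probs):
            counts, _ = np.histogram(samples, bins=edges)
            expected = probs / probs.sum() * counts.sum()
            keep = expected > 20
            chi2 = ((counts[keep] - expected[keep])**2
                    / expected[keep]).sum()
            return stats.chi2.sf(chi2, int(keep.sum()) - 1)

        assert chi2_p(x_g, grid.x_edges, grid.values.sum(axis=1)) > 0.01
        assert chi2_p(z, grid.z_edges, grid.values.sum(axis=0)) > 0.01
        # separability: x and z statistically independent
        assert abs(np.corrcoef(x_g, z)[0, 1]) < 0.01

    def test_gantry_angles_uniform(self, pmma_model):
        rng = np.random.default_rng(11)
        origins, _, _, _ = sample_photons(pmma_model, 200_000, rng)
        alpha = np.arctan2(origins[:, 0], origins[:, 1]) % (2 * np.pi)
        counts, _ = np.histogram(alpha, bins=36, range=(0, 2 * np.pi))
        expected = len(alpha) / 36
        chi2 = ((counts - expected)**2 / expected).sum()
        assert stats.chi2.sf(chi2, 35) > 0.01

    def test_delta_fluence_rays_pass_near_isocenter(self, pmma_model):
        field = pmma_model.spectrum_field
        lx = np.array([-0.005, 0.0, 0.005])
        lv = np.array([0.0, 1.0, 0.0])
        grid = build_fluence_grid((lx, lv), (lx.copy(), lv.copy()))
        model = SourceModel(sad_cm=64.5, kvp=field.kvp, spectrum_field=field,
                            fluence_grid=grid, collimation_z_cm=0.01)
        rng = np.random.default_rng(3)
        origins, dirs, _, _ = sample_photons(model, 1000, rng)
        miss = np.linalg.norm(np.cross(dirs, -origins), axis=1)
        assert miss.max() < 0.01

    def test_single_photon_wrapper_and_rng_validation(self, pmma_model):
        o, d, e, w = sample_photon(pmma_model, np.random.default_rng(0))
        assert np.linalg.norm(d) == pytest.approx(1.0)
        assert w == 1.0
        with pytest.raises(ValueError):
            sample_photon(pmma_model, None)


class TestModelIO:
    def test_lossless_round_trip(self, pmma_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(pmma_model, path)
        loaded = load_model(path)
        assert loaded.sad_cm == pmma_model.sad_cm
        assert loaded.kvp == pmma_model.kvp
        np.testing.assert_allclose(loaded.fluence_grid.values,
                                   pmma_model.fluence_grid.values,
                                   atol=1e-12)
        for s1, s2 in zip(loaded.spectrum_field.spectra,
                          pmma_model.spectrum_field.spectra):
            np.testing.assert_allclose(s1.counts, s2.counts, atol=1e-12)

    def test_missing_sad_is_an_error(self, pmma_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(pmma_model, path)
        doc = json.loads(path.read_text())
        del doc["sad_cm"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="sad_cm"):
            load_model(path)

    def test_version_mismatch_warns_but_loads(self, pmma_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(pmma_model, path)
        doc = json.loads(path.read_text())
        doc["version"] = "0"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="version"):
            loaded = load_model(path)
        assert loaded.kvp == pmma_model.kvp
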