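"""Forward projection, water pre-correction, noise and FBP."""

import numpy as np
import pytest

from abhc import materials as M
from abhc import simulator as S
from abhc.phantoms import Ellipse, PhantomDefinition, make_cylinder_phantom
from abhc.materials import WATER, iodine_solution

from conftest import REF_120


def _quadrature_line_integral(prim, theta, s, n=200_001):
    """Brute-force ray integration oracle for one primitive's chord."""
    t = np.linspace(-80.0, 80.0, n)
    x = s * np.cos(theta) - t * np.sin(theta)
    y = s * np.sin(theta) + t * np.cos(theta)
    inside = prim.contains(x, y)
    return inside.sum() * (t[1] - t[0])


class TestChords:
    @pytest.mark.parametrize(
        "center,axes,rot,theta,s",
        [
            ((0.0, 0.0), (10.0, 10.0), 0.0, 0.3, 4.0),
            ((7.0, -5.0), (12.0, 6.0), 25.0, 1.1, -3.5),
            ((-10.0, 3.0), (5.0, 15.0), 120.0, 2.4, 8.0),
        ],
    )
    def test_closed_form_matches_quadrature(self, center, axes, rot, theta, s):
        prim = Ellipse(center, axes, WATER, rotation_deg=rot)
        chord = prim.chords(np.array([theta]), np.array([s]))[0, 0]
        oracle = _quadrature_line_integral(prim, theta, s)
        assert chord == pytest.approx(oracle, rel=2e-4, abs=2e-3)

    def test_central_ray_through_cylinder(self):
        geom = S.Geometry(64, 1.0, 60, detector_oversample=1)
        ph = PhantomDefinition([Ellipse((0, 0), (20, 20), WATER)])
        sino = S.project_mono(ph, 70.0, geom)
        mu = WATER.linear_attenuation(np.array([70.0]))[0]
        central = sino.values[:, geom.n_pixels // 2]
        assert np.allclose(central, 2 * 2.0 * mu, rtol=1e-9)  # 2r in cm * mu

    def test_empty_phantom_projects_to_zero(self):
        geom = S.Geometry(32, 1.0, 30)
        ph = PhantomDefinition([])
        assert np.all(S.project_mono(ph, 70.0, geom).values == 0)


class TestPolyProjection:
    def test_delta_spectrum_reduces_to_mono(self, small_geometry,
                                            cylinder_phantom):
        spec = M.monoenergetic_spectrum(70.0)
        a = S.project_poly(cylinder_phantom, spec, small_geometry)
        b = S.project_mono(cylinder_phantom, 70.0, small_geometry)
        assert np.array_equal(a.values, b.values)

    def test_two_bin_slab_closed_form(self):
        """P = -ln(w1 e^{-mu40 t} + w2 e^{-mu80 t}) for a water disk."""
        geom = S.Geometry(64, 1.0, 4, detector_oversample=1)
        r_mm = 20.0
        ph = PhantomDefinition([Ellipse((0, 0), (r_mm, r_mm), WATER)])
        grid = M.DEFAULT_GRID
        w = np.zeros(len(grid))
        w[grid.index_of(40.0)] = 0.5
        w[grid.index_of(80.0)] = 0.5
        spec = M.SourceSpectrum(80.0, grid, w)
        sino = S.project_poly(ph, spec, geom)
        t = 2 * r_mm * 0.1
        mu40 = WATER.linear_attenuation(np.array([40.0]))[0]
        mu80 = WATER.linear_attenuation(np.array([80.0]))[0]
        expected = -np.log(0.5 * np.exp(-mu40 * t) + 0.5 * np.exp(-mu80 * t))
        central = sino.values[0, geom.n_pixels // 2]
        assert central == pytest.approx(expected, rel=1e-12)

    def test_projection_per_thickness_decreases_for_bone(self):
        from abhc.materials import CORTICAL_BONE

        geom = S.Geometry(128, 1.0, 2, detector_oversample=1)
        spec = M.make_spectrum(120)
        ph = PhantomDefinition([Ellipse((0, 0), (50, 50), CORTICAL_BONE)])
        sino = S.project_poly(ph, spec, geom)
        p = sino.values[0]
        chords = ph.primitives[0].chords(
            np.array([0.0]), geom.detector_s_mm
        )[0] * 0.1
        sel = chords > 1.0
        t_unique, idx = np.unique(chords[sel].round(9), return_index=True)
        ratio = (p[sel] / chords[sel])[idx]
        assert np.all(np.diff(ratio) < 0)

    def test_phantom_larger_than_fov_rejected(self):
        geom = S.Geometry(32, 0.5, 30)  # FOV 16 mm
        ph = PhantomDefinition([Ellipse((0, 0), (20, 20), WATER)])
        with pytest.raises(ValueError, match="exceeds"):
            S.project_mono(ph, 70.0, geom)


class TestWaterPrecorrection:
    def test_zero_sinogram_unchanged(self, small_geometry, spectrum_120):
        z = S.Sinogram(np.zeros((160, 128)), small_geometry)
        out = S.water_precorrect(z, spectrum_120, REF_120)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_mono_sinogram_at_reference_unchanged(self, small_geometry):
        spec = M.monoenergetic_spectrum(REF_120)
        ph = make_cylinder_phantom(insert_concentrations=[])
        sino = S.project_mono(ph, REF_120, small_geometry)
        out = S.water_precorrect(sino, spec, REF_120)
        assert np.allclose(out.values, sino.values, atol=1e-6)

    def test_water_cylinder_flat_after_precorrection(self, small_geometry,
                                                     spectrum_120):
        """Interior ~0 HU and cupping < 3 HU for a pure-water cylinder."""
        ph = make_cylinder_phantom(insert_concentrations=[])
        sino = S.project_poly(ph, spectrum_120, small_geometry)
        sino = S.water_precorrect(sino, spectrum_120, REF_120)
        img = S.reconstruct_fbp(sino, small_geometry, REF_120)
        x, y = small_geometry.pixel_coords()
        interior = x**2 + y**2 < 40.0**2
        assert abs(img.values[interior].mean()) < 2.0
        from abhc.metrics import cupping

        assert abs(cupping(img.values, interior)) < 3.0


class TestPoissonNoise:
    def _sino(self, value=1.0):
        geom = S.Geometry(16, 1.0, 8)
        return S.Sinogram(np.full((8, 16), value), geom), geom

    def test_fixed_seed_reproducible(self):
        sino, _ = self._sino()
        spec = M.make_spectrum(120, total_fluence=1e4)
        a = S.add_poisson_noise(sino, spec, seed=42)
        b = S.add_poisson_noise(sino, spec, seed=42)
        assert np.array_equal(a.values, b.values)
        c = S.add_poisson_noise(sino, spec, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_high_fluence_limit_is_noiseless(self):
        sino, _ = self._sino()
        spec = M.make_spectrum(120, total_fluence=1e9)
        out = S.add_poisson_noise(sino, spec, seed=0)
        assert np.max(np.abs(out.values - sino.values)) < 1e-3

    def test_variance_matches_delta_method(self):
        """var(P) ~ 1/(I0 e^{-P}) to first order."""
        sino, _ = self._sino(1.0)
        spec = M.make_spectrum(120, total_fluence=1e4)
        draws = np.stack([
            S.add_poisson_noise(sino, spec, seed=s).values for s in range(150)
        ])
        var = draws.var(axis=0).mean()
        expected = 1.0 / (1e4 * np.exp(-1.0))
        assert var == pytest.approx(expected, rel=0.10)


class TestFBP:
    def test_zero_sinogram_reconstructs_air(self, small_geometry):
        z = S.Sinogram(np.zeros((160, 128)), small_geometry)
        img = S.reconstruct_fbp(z, small_geometry, REF_120)
        assert np.allclose(img.values, -1000.0, atol=1e-6)

    def test_linearity(self, small_geometry, cylinder_phantom, spectrum_120):
        s1 = S.project_mono(cylinder_phantom, 50.0, small_geometry)
        s2 = S.project_mono(cylinder_phantom, 80.0, small_geometry)
        both = S.Sinogram(s1.values + s2.values, small_geometry)
        r1 = S.reconstruct_fbp(s1, small_geometry, REF_120).values + 1000
        r2 = S.reconstruct_fbp(s2, small_geometry, REF_120).values + 1000
        r12 = S.reconstruct_fbp(both, small_geometry, REF_120).values + 1000
        scale = np.abs(r12).max()
        assert np.max(np.abs(r12 - (r1 + r2))) < 1e-6 * scale

    def test_water_cylinder_round_trip(self, small_geometry):
        ph = make_cylinder_phantom(insert_concentrations=[])
        sino = S.project_mono(ph, REF_120, small_geometry)
        img = S.reconstruct_fbp(sino, small_geometry, REF_120)
        x, y = small_geometry.pixel_coords()
        interior = x**2 + y**2 < 40.0**2
        assert abs(img.values[interior].mean()) < 2.0

    def test_insert_recovery_within_2pct(self, cylinder_images,
                                         cylinder_phantom, small_geometry):
        """Mono reconstruction recovers analytic insert HU within 2%."""
        from scipy import ndimage

        _, mono = cylinder_images
        mu_w = WATER.linear_attenuation(np.array([REF_120]))[0]
        for k, c in enumerate(cylinder_phantom.primitives[1:]):
            mask = ndimage.binary_erosion(
                cylinder_phantom.region_mask(f"insert_{k}", small_geometry),
                iterations=3,
            )
            mu = c.material.linear_attenuation(np.array([REF_120]))[0]
            expected = 1000.0 * (mu - mu_w) / mu_w
            assert mono.values[mask].mean() == pytest.approx(expected, rel=0.02)
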