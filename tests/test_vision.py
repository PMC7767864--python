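import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floricolor.spectra import ReflectanceSpectrum, standard_grid
from floricolor.vision import (
    DegenerateBackgroundError,
    avian_visual_system,
    bee_visual_system,
    build_receptor_sensitivities,
    compute_quantum_catches,
    default_foliage_background,
    govardovskii_alpha,
    hexagon_locus,
    QuantumCatches,
    spectrum_locus,
    tetrahedral_locus,
    tetrahedron_vertices,
)


class TestSensitivities:
    @pytest.mark.parametrize("peak", [344.0, 436.0, 544.0, 416.0, 607.0])
    def test_curve_peaks_at_nominal_wavelength(self, peak):
        v = build_receptor_sensitivities([peak])
        curve = v.sensitivities[0]
        assert curve.max() == pytest.approx(1.0)
        assert abs(v.grid[np.argmax(curve)] - peak) <= 1.0

    def test_template_decays_far_from_peak(self, grid):
        # evaluate the pigment template formula directly, away from the peak
        for peak in (450.0, 550.0):
            for off in (-150.0, 150.0):
                wl = peak + off
                x = peak / wl
                a = 0.8795 + 0.0459 * np.exp(-((peak - 300.0) ** 2) / 11940.0)
                expected = 1.0 / (
                    np.exp(69.7 * (a - x))
                    + np.exp(28.0 * (0.922 - x))
                    + np.exp(-14.9 * (1.104 - x))
                    + 0.674
                )
                assert govardovskii_alpha(np.array([wl]), peak)[0] == pytest.approx(expected)
                assert expected < 0.05

    def test_bee_curves_overlap_pairwise(self):
        v = bee_visual_system()
        s = v.sensitivities
        for i in range(2):
            assert np.any(np.minimum(s[i], s[i + 1]) > 0.05)

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            build_receptor_sensitivities([250.0])


class TestQuantumCatches:
    def test_background_self_adapts_to_unity(self):
        v = bee_visual_system()
        q = compute_quantum_catches(v.background, v)
        np.testing.assert_allclose(q.adapted, 1.0, atol=1e-12)

    def test_zero_spectrum_flags_achromatic_null(self, flat_spectrum):
        v = bee_visual_system()
        q = compute_quantum_catches(flat_spectrum(0.0), v)
        assert q.achromatic_null and q.relative is None
        np.testing.assert_array_equal(q.raw, 0.0)

    def test_doubled_background_doubles_adapted_catches(self, grid):
        v = avian_visual_system()
        doubled = ReflectanceSpectrum(
            "x2", "whole", grid, 2.0 * v.background.reflectance_pct
        )
        q = compute_quantum_catches(doubled, v)
        np.testing.assert_allclose(q.adapted, 2.0, atol=1e-12)

    def test_degenerate_background_rejected(self, grid, flat_spectrum):
        v = bee_visual_system(background=flat_spectrum(0.0))
        with pytest.raises(DegenerateBackgroundError):
            compute_quantum_catches(flat_spectrum(10.0), v)

    def test_illuminant_scaling_cancels(self, grid):
        rng = np.random.default_rng(5)
        refl = rng.uniform(0, 100, grid.shape)
        s = ReflectanceSpectrum("s", "whole", grid, refl)
        v1 = bee_visual_system()
        v2 = bee_visual_system(illuminant=7.3 * np.ones_like(grid))
        l1 = spectrum_locus(s, v1)
        l2 = spectrum_locus(s, v2)
        np.testing.assert_allclose(l1.coords, l2.coords, atol=1e-12)


class TestHexagon:
    def test_background_maps_to_achromatic_center(self):
        q = QuantumCatches(raw=np.ones(3), adapted=np.ones(3), relative=np.ones(3) / 3)
        locus = hexagon_locus(q)
        np.testing.assert_allclose(locus.excitations, 0.5)
        np.testing.assert_allclose(locus.coords, [0.0, 0.0], atol=1e-15)

    def test_saturated_green_limit_is_unit_vertex(self):
        big = 1e12
        q = QuantumCatches(
            raw=np.array([0.0, 0.0, big]),
            adapted=np.array([0.0, 0.0, big]),
            relative=np.array([0.0, 0.0, 1.0]),
        )
        locus = hexagon_locus(q)
        np.testing.assert_allclose(locus.coords, [np.sqrt(3) / 2, -0.5], atol=1e-9)
        assert np.linalg.norm(locus.coords) == pytest.approx(1.0, abs=1e-9)

    def test_simple_arithmetic_case(self):
        q = QuantumCatches(
            raw=np.array([1.0, 2.0, 1.0]),
            adapted=np.array([1.0, 2.0, 1.0]),
            relative=np.array([0.25, 0.5, 0.25]),
        )
        locus = hexagon_locus(q)
        np.testing.assert_allclose(locus.excitations, [0.5, 2 / 3, 0.5])
        np.testing.assert_allclose(locus.coords, [0.0, 1 / 6], atol=1e-15)

    def test_wrong_receptor_count_rejected(self):
        q = QuantumCatches(raw=np.ones(4), adapted=np.ones(4), relative=np.ones(4) / 4)
        with pytest.raises(ValueError):
            hexagon_locus(q)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_physical_spectra_stay_inside_unit_hexagon(self, seed):
        rng = np.random.default_rng(seed)
        grid = standard_grid()
        s = ReflectanceSpectrum("r", "whole", grid, rng.uniform(0, 100, grid.shape))
        locus = spectrum_locus(s, bee_visual_system())
        assert np.all(locus.excitations >= 0) and np.all(locus.excitations < 1)
        assert np.linalg.norm(locus.coords) <= 1.0 + 1e-12


class TestTetrahedron:
    def test_equal_catches_at_origin(self):
        q = QuantumCatches(raw=np.ones(4), adapted=np.ones(4), relative=np.full(4, 0.25))
        np.testing.assert_allclose(tetrahedral_locus(q).coords, 0.0, atol=1e-15)

    def test_pure_stimulus_at_vertex(self):
        q = QuantumCatches(
            raw=np.array([1.0, 0, 0, 0]),
            adapted=np.array([1.0, 0, 0, 0]),
            relative=np.array([1.0, 0, 0, 0]),
        )
        coords = tetrahedral_locus(q).coords
        np.testing.assert_allclose(coords, [0.0, 0.0, 0.75], atol=1e-15)
        assert np.linalg.norm(coords) == pytest.approx(0.75)

    def test_barycentric_linearity(self):
        q = QuantumCatches(
            raw=np.array([0.5, 0.5, 0, 0]),
            adapted=np.array([0.5, 0.5, 0, 0]),
            relative=np.array([0.5, 0.5, 0, 0]),
        )
        verts = tetrahedron_vertices()
        np.testing.assert_allclose(
            tetrahedral_locus(q).coords, (verts[0] + verts[1]) / 2, atol=1e-15
        )

    def test_vertices_form_regular_tetrahedron(self):
        verts = tetrahedron_vertices()
        np.testing.assert_allclose(np.linalg.norm(verts, axis=1), 0.75, atol=1e-12)
        np.testing.assert_allclose(verts.mean(axis=0), 0.0, atol=1e-15)
        dists = [
            np.linalg.norm(verts[i] - verts[j]) for i in range(4) for j in range(i + 1, 4)
        ]
        np.testing.assert_allclose(dists, dists[0], atol=1e-12)

    def test_unnormalized_catches_rejected(self):
        q = QuantumCatches(
            raw=np.ones(4), adapted=np.ones(4), relative=np.array([0.5, 0.5, 0.5, 0.5])
        )
        with pytest.raises(ValueError, match="sum to 1"):
            tetrahedral_locus(q)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_physical_spectra_stay_inside_tetrahedron(self, seed):
        rng = np.random.default_rng(seed)
        grid = standard_grid()
        s = ReflectanceSpectrum("r", "whole", grid, rng.uniform(0, 100, grid.shape))
        v = avian_visual_system()
        q = compute_quantum_catches(s, v)
        # relative catches are the barycentric weights: all >= 0, summing to 1
        assert np.all(q.relative >= 0)
        locus = tetrahedral_locus(q)
        assert np.linalg.norm(locus.coords) <= 0.75 + 1e-12


def test_foliage_background_positive_where_sensitivities_positive(grid):
    bg = default_foliage_background(grid)
    v = bee_visual_system()
    mask = v.sensitivities.max(axis=0) > 1e-6
    assert np.all(bg.reflectance_pct[mask] > 0)
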