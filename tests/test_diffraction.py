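"""Detector geometry, form factors and the coherent/double-sum intensity."""

import numpy as np
import pytest

import fieldunfold as fu
from fieldunfold.diffraction import (
    DEFAULT_TIME_POINTS_PS,
    R_E_ANGSTROM,
    DetectorConfig,
)
from fieldunfold.errors import ConfigurationError, ElementError, SamplingError


class TestWavelength:
    def test_8_kev_gives_1_55_angstrom(self):
        assert fu.wavelength_from_energy(8.0) == pytest.approx(1.55, abs=0.005)

    def test_hc_identity(self):
        assert fu.wavelength_from_energy(12.398) == pytest.approx(1.0, rel=1e-12)

    def test_inverse_proportionality(self):
        assert fu.wavelength_from_energy(4.0) == pytest.approx(
            2 * fu.wavelength_from_energy(8.0), rel=1e-12
        )

    def test_non_positive_energy(self):
        with pytest.raises(ConfigurationError):
            fu.wavelength_from_energy(0.0)


class TestQMap:
    def test_centre_q_is_small_and_min_over_map(self):
        qmap = fu.build_q_map(DetectorConfig())
        centre = qmap.qmag[511:513, 511:513]
        assert centre.max() == qmap.qmag.min()
        assert centre.max() < 1e-3  # essentially forward scattering

    def test_edge_midpoint_resolution_oracle(self):
        """Exact trigonometric oracle at r = 102.4 mm, D = 250 mm."""
        det = DetectorConfig()
        lam = det.wavelength_angstrom
        r, D = 102.4e7, 250e7  # Å
        expected = 1.0 / (2 * np.sin(np.arctan2(r, D) / 2) / lam)
        assert expected == pytest.approx(4.01, abs=0.01)
        # the map's largest full ring sits half a pixel inside that edge
        qmap = fu.build_q_map(det)
        assert qmap.best_full_ring_resolution_angstrom == pytest.approx(
            expected, rel=2e-3
        )

    def test_corner_reaches_three_point_five_angstrom(self):
        """The far corner captures scattering beyond the quoted 3.5 Å."""
        qmap = fu.build_q_map(DetectorConfig())
        r, D = np.sqrt(2) * 102.4e7, 250e7
        lam = DetectorConfig().wavelength_angstrom
        expected = 1.0 / (2 * np.sin(np.arctan2(r, D) / 2) / lam)
        assert expected == pytest.approx(2.99, abs=0.01)
        assert qmap.best_resolution_angstrom <= 3.5
        assert qmap.best_resolution_angstrom == pytest.approx(expected, rel=2e-3)

    def test_qmag_increases_radially_and_solid_angle_bounded(self, small_qmap, small_detector):
        row = small_qmap.qmag[small_detector.n_pixels[0] // 2]
        half = row[small_detector.n_pixels[1] // 2 :]
        assert np.all(np.diff(half) > 0)
        pixel_area = (small_detector.pixel_size_um * 1e4) ** 2
        dist2 = (small_detector.distance_cm * 1e8) ** 2
        assert np.all(small_qmap.solid_angle <= pixel_area / dist2 + 1e-30)

    def test_horizontal_polarization_factor(self):
        det = DetectorConfig(n_pixels=(64, 64), pixel_size_um=3200,
                             polarization_mode="horizontal")
        qmap = fu.build_q_map(det)
        assert np.all(qmap.polarization <= 1.0)
        # suppression is strongest along the horizontal axis
        mid = 32
        assert qmap.polarization[mid, -1] < qmap.polarization[-1, mid]


class TestFormFactor:
    @pytest.mark.parametrize("element,z", [("C", 6.0), ("H", 1.0), ("N", 7.0),
                                           ("O", 8.0), ("S", 16.0)])
    def test_forward_value_is_electron_count(self, element, z):
        assert fu.atomic_form_factor(element, 0.0) == pytest.approx(z, rel=0.01)

    @pytest.mark.parametrize("element", ["C", "N", "O"])
    def test_strictly_decreasing_on_saxs_range(self, element):
        q = np.linspace(0.0, 0.3, 50)
        f = fu.atomic_form_factor(element, q)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element(self):
        with pytest.raises(ElementError):
            fu.atomic_form_factor("Xq", 0.1)


class TestDiffractionPattern:
    def test_single_carbon_atom(self, small_detector, small_qmap):
        pattern = fu.diffraction_pattern(
            np.zeros((1, 3)), small_detector, elements=["C"], qmap=small_qmap
        )
        f = fu.atomic_form_factor("C", small_qmap.qmag)
        expected = (
            small_detector.incident_intensity
            * R_E_ANGSTROM**2
            * small_qmap.polarization
            * small_qmap.solid_angle
            * f**2
        )
        np.testing.assert_allclose(pattern.intensities, expected, rtol=1e-9)

    def test_destructive_interference_of_identical_pair(self, small_detector, small_qmap):
        """Where q.(R1-R2) = 1/2, the two-atom intensity vanishes."""
        qvec = small_qmap.qvec[40, 50]
        delta = 0.5 * qvec / np.dot(qvec, qvec)  # Å, so q.delta = 0.5
        coords_nm = np.array([[0.0, 0.0, 0.0], delta / 10.0])
        pattern = fu.diffraction_pattern(
            coords_nm, small_detector, elements=["C", "C"], qmap=small_qmap
        )
        peak = pattern.intensities.max()
        assert pattern.intensities[40, 50] < 1e-9 * peak

    def test_translation_invariance(self, small_detector, small_qmap, rng):
        coords = rng.normal(scale=0.5, size=(12, 3))
        elements = ["C"] * 8 + ["N", "O", "S", "H"]
        a = fu.diffraction_pattern(coords, small_detector, elements=elements, qmap=small_qmap)
        b = fu.diffraction_pattern(
            coords + np.array([1.7, -2.3, 0.9]), small_detector,
            elements=elements, qmap=small_qmap,
        )
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-7)

    def test_coherent_sum_equals_double_sum(self, small_detector, small_qmap, rng):
        """The production coherent sum and the explicit self+cross double sum
        agree to 1e-9 relative error on random frames."""
        for _ in range(5):
            m = rng.integers(5, 30)
            coords = rng.normal(scale=1.0, size=(m, 3))
            elements = list(np.array(["H", "C", "N", "O", "S"])[rng.integers(0, 5, m)])
            a = fu.diffraction_pattern(coords, small_detector, elements=elements, qmap=small_qmap)
            b = fu.diffraction_pattern_double_sum(
                coords, small_detector, elements=elements, qmap=small_qmap
            )
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_forward_limit_is_total_electron_count_squared(self, rng):
        """Central-pixel intensity approaches I0 re^2 P dOmega (sum Z)^2."""
        det = DetectorConfig()  # fine pixels -> central q is tiny
        qmap = fu.build_q_map(det)
        coords = rng.normal(scale=0.8, size=(15, 3))
        elements = ["C"] * 10 + ["N", "O", "O", "S", "H"]
        z_total = sum({"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}[e] for e in elements)
        # evaluate only the 4 central pixels by masking a tiny detector view
        pattern = fu.diffraction_pattern(coords, det, elements=elements, qmap=qmap)
        centre = pattern.intensities[511:513, 511:513]
        prefactor = (
            det.incident_intensity
            * R_E_ANGSTROM**2
            * qmap.polarization[511:513, 511:513]
            * qmap.solid_angle[511:513, 511:513]
        )
        np.testing.assert_allclose(centre, prefactor * z_total**2, rtol=0.01)

    def test_rotation_about_beam_rotates_pattern(self, small_detector, rng):
        """A 90-degree rotation about +z maps pixel (i, j) intensities onto
        the 90-degree-rotated pixel grid exactly (square detector)."""
        coords = rng.normal(scale=0.6, size=(10, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        a = fu.diffraction_pattern(coords, small_detector, elements=["C"] * 10)
        b = fu.diffraction_pattern(coords @ rot90.T, small_detector, elements=["C"] * 10)
        np.testing.assert_allclose(
            b.intensities, np.rot90(a.intensities, k=-1), rtol=1e-6
        )

    def test_intensities_non_negative(self, small_detector, rng):
        coords = rng.normal(scale=2.0, size=(25, 3))
        p = fu.diffraction_pattern(coords, small_detector, elements=["C"] * 25)
        assert np.all(p.intensities >= 0)
        assert np.all(np.isfinite(p.intensities))


class TestPatternSeries:
    def test_default_grid_has_eleven_frames(self):
        assert len(DEFAULT_TIME_POINTS_PS) == 11
        assert DEFAULT_TIME_POINTS_PS[0] == 0.0
        assert DEFAULT_TIME_POINTS_PS[-1] == 50.0

    def test_series_bookkeeping(self, topology, small_detector):
        sched = fu.UnfoldingSchedule.from_order("CDEB")
        ens = fu.generate_ensemble(topology, sched, n_runs=3, seed=0, n_frames=11, dt=5.0)
        series = fu.pattern_series(ens, small_detector)
        assert series.intensities.shape == (11, 3, 64, 64)
        assert series.run_ids == [r.run_id for r in ens]

    def test_missing_time_point_raises(self, topology, small_detector):
        sched = fu.UnfoldingSchedule.from_order("CDEB")
        ens = fu.generate_ensemble(topology, sched, n_runs=2, seed=0, n_frames=11, dt=5.0)
        with pytest.raises(SamplingError):
            fu.pattern_series(ens, small_detector, time_points=[0.0, 7.0])

    def test_h5_round_trip(self, tmp_path, topology, small_detector):
        sched = fu.UnfoldingSchedule.from_order("CDEB")
        ens = fu.generate_ensemble(topology, sched, n_runs=2, seed=0, n_frames=11, dt=5.0)
        series = fu.pattern_series(ens, small_detector, time_points=[0.0, 50.0])
        path = tmp_path / "patterns.h5"
        series.save_h5(path)
        back = fu.PatternSeries.load_h5(path)
        np.testing.assert_allclose(back.intensities, series.intensities)
        assert back.detector == small_detector
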