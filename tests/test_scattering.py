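"""FRC correlation properties, resolution limits and ring anisotropy."""

import numpy as np
import pytest

import fieldunfold as fu
from fieldunfold.errors import AnalysisError, ConfigurationError
from fieldunfold.scattering import (
    FRCCurve,
    RingPartition,
    frc,
    half_set_average,
    resolution_limit,
    ring_anisotropy,
)


def _noise_partition(n_rings, pixels_per_ring, rng=None):
    """A synthetic flat partition with equal-size rings (no detector)."""
    n = n_rings * pixels_per_ring
    return RingPartition(
        edges=np.linspace(0.0, 0.25, n_rings + 1),
        ring_index=np.repeat(np.arange(n_rings), pixels_per_ring),
        azimuth=np.linspace(-np.pi, np.pi, n, endpoint=False),
        shape=(1, n),
    )


class TestHalfSetAverage:
    def test_identical_patterns(self, rng):
        p = rng.uniform(size=(8, 8))
        a, b = half_set_average([p, p])
        np.testing.assert_allclose(a, p)
        np.testing.assert_allclose(b, p)

    def test_even_odd_split_of_scaled_pair(self, rng):
        p = rng.uniform(size=(4, 4))
        a, b = half_set_average([p, 3 * p])
        np.testing.assert_allclose(a, p)
        np.testing.assert_allclose(b, 3 * p)

    def test_seeded_random_split_is_deterministic(self, rng):
        patterns = rng.uniform(size=(10, 6, 6))
        a1, b1 = half_set_average(patterns, split="seeded-random", seed=5)
        a2, b2 = half_set_average(patterns, split="seeded-random", seed=5)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_odd_count_drops_last_with_warning(self, rng):
        patterns = rng.uniform(size=(5, 3, 3))
        with pytest.warns(UserWarning, match="odd"):
            a, b = half_set_average(patterns)
        np.testing.assert_allclose(a, patterns[[0, 2]].mean(axis=0))

    def test_fewer_than_two_patterns(self, rng):
        with pytest.raises(AnalysisError):
            half_set_average(rng.uniform(size=(1, 3, 3)))
        with pytest.raises(ConfigurationError):
            half_set_average(rng.uniform(size=(4, 3, 3)), split="bogus")


class TestFrc:
    def test_self_correlation_is_one(self, rng):
        part = _noise_partition(8, 50)
        p = rng.uniform(size=(1, 400))
        curve = frc(p, p, part)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_negative_affine_gives_minus_one(self, rng):
        part = _noise_partition(8, 50)
        p = rng.uniform(size=(1, 400))
        curve = frc(p, 2.0 - 3.0 * p, part)
        np.testing.assert_allclose(curve.values, -1.0, atol=1e-12)

    def test_affine_invariance_and_symmetry(self, rng):
        part = _noise_partition(6, 40)
        p1 = rng.uniform(size=(1, 240))
        p2 = rng.uniform(size=(1, 240))
        c12 = frc(p1, p2, part).values
        c21 = frc(p2, p1, part).values
        scaled = frc(0.7 + 2.5 * p1, p2, part).values
        np.testing.assert_allclose(c12, c21, atol=1e-12)
        np.testing.assert_allclose(c12, scaled, atol=1e-10)

    def test_zero_variance_ring_is_nan(self, rng):
        part = _noise_partition(2, 30)
        p1 = np.concatenate([np.ones(30), rng.uniform(size=30)])[None, :]
        p2 = rng.uniform(size=(1, 60))
        curve = frc(p1, p2, part)
        assert np.isnan(curve.values[0])
        assert np.isfinite(curve.values[1])

    @pytest.mark.parametrize("pixels", [100, 1000, 10000])
    def test_white_noise_null_scales_as_inverse_sqrt_n(self, pixels):
        """Independent noise: FRC ~ 0 with E|FRC| = sqrt(2/pi)/sqrt(n)."""
        rng = np.random.default_rng(99)
        n_rings = 200
        part = _noise_partition(n_rings, pixels)
        p1 = rng.normal(size=(1, n_rings * pixels))
        p2 = rng.normal(size=(1, n_rings * pixels))
        values = frc(p1, p2, part).values
        assert abs(values.mean()) < 3.0 / np.sqrt(n_rings * pixels / n_rings)
        ratio = np.abs(values).mean() * np.sqrt(pixels)
        assert 0.5 < ratio < 1.2  # sqrt(2/pi) ~ 0.80 within sampling error


class TestResolutionLimit:
    def _curve(self, values, q_max=0.25):
        n = len(values)
        edges = np.linspace(0.0, q_max, n + 1)
        return FRCCurve(
            q_centres=0.5 * (edges[:-1] + edges[1:]),
            values=np.asarray(values, dtype=float),
            edges=edges,
        )

    def test_all_above_cutoff_is_detector_limited(self):
        lim = resolution_limit(self._curve([1.0] * 10))
        assert lim.status == "detector-limited"
        assert lim.resolution_angstrom == pytest.approx(1 / 0.25)

    def test_crossing_at_point_two(self):
        """FRC 0.9 below q = 0.2, 0.3 beyond -> limit 1/0.2 = 5 A."""
        values = [0.9 if q < 0.2 else 0.3 for q in np.linspace(0.0125, 0.2375, 10)]
        lim = resolution_limit(self._curve(values))
        assert lim.status == "ok"
        assert lim.resolution_angstrom == pytest.approx(5.0)

    def test_first_ring_below_cutoff(self):
        lim = resolution_limit(self._curve([0.2, 0.9, 0.9]))
        assert lim.status == "not-reached"
        assert np.isinf(lim.resolution_angstrom)

    def test_monotone_in_cutoff(self, rng):
        values = np.clip(rng.uniform(-0.2, 1.0, size=20), None, 1.0)
        curve = self._curve(list(values))
        lims = [
            resolution_limit(curve, cutoff=c).resolution_angstrom
            for c in (0.3, 0.5, 0.7)
        ]
        assert lims[0] <= lims[1] <= lims[2]

    def test_empty_curve(self):
        with pytest.raises(AnalysisError):
            resolution_limit(self._curve([]))


class TestFrcPipeline:
    def test_homogeneous_ensemble_is_detector_limited(self, topology, small_detector):
        """All runs identical (no jitter, no noise): zero heterogeneity, so
        the limit equals the detector's best full ring at every time."""
        sched = fu.UnfoldingSchedule.from_order("CDEB")
        ens = fu.generate_ensemble(topology, sched, n_runs=4, seed=0, n_frames=11, dt=5.0)
        series = fu.pattern_series(ens, small_detector)
        qmap = fu.build_q_map(small_detector)
        part = RingPartition.from_qmap(qmap, n_rings=24)
        table = fu.frc_timeseries(series, part)
        assert len(table) == 11
        assert (table.status == "detector-limited").all()
        np.testing.assert_allclose(
            table.resolution_angstrom, 1.0 / part.edges[-1], rtol=1e-9
        )


class TestRingAnisotropy:
    def test_isotropic_cloud_is_flat(self, small_detector, rng):
        """A spherically symmetric random cloud gives a nearly flat profile."""
        coords = rng.normal(scale=0.8, size=(60, 3))
        p = fu.diffraction_pattern(coords, small_detector, elements=["C"] * 60)
        series = fu.PatternSeries(
            times=np.array([0.0]),
            intensities=p.intensities[None, None],
            detector=small_detector,
        )
        qmap = fu.build_q_map(small_detector)
        part = RingPartition.from_qmap(qmap, n_rings=24)
        profiles = ring_anisotropy(series, part, resolutions=(15.0,), n_theta_bins=8)
        ratio = profiles[15.0].anisotropy_ratio[0]
        assert ratio < 1.8  # speckle keeps it from exactly 1

    def test_two_spot_pattern_peaks_at_those_azimuths(self, small_qmap, small_detector):
        part = RingPartition.from_qmap(small_qmap, n_rings=16)
        ring = part.ring_containing(1.0 / 10.0)
        px = part.pixels(ring)
        intensity = np.zeros(small_qmap.qmag.size)
        theta = part.azimuth[px]
        spots = px[(np.abs(theta) < 0.3) | (np.abs(np.abs(theta) - np.pi) < 0.3)]
        intensity[spots] = 5.0
        series = fu.PatternSeries(
            times=np.array([0.0]),
            intensities=intensity.reshape(small_qmap.qmag.shape)[None, None],
            detector=small_detector,
        )
        profiles = ring_anisotropy(series, part, resolutions=(10.0,), n_theta_bins=12)
        prof = profiles[10.0].intensity[0]
        peak_bins = np.argsort(prof)[-2:]
        centres = profiles[10.0].theta_centres[peak_bins]
        assert all(
            min(abs(abs(c) - 0.0), abs(abs(c) - np.pi)) < 0.6 for c in centres
        )

    def test_stretching_increases_ring_anisotropy(self, topology):
        """As the molecule elongates along x into a thin chain, the 10 A
        ring's max/mean ratio grows above its folded-state value.  (The 5 A
        ring needs sub-residue axial structure that a Calpha-only chain does
        not carry; see the methods note.)"""
        det = fu.DetectorConfig().binned(8)  # 128 px: adequate ring statistics
        sched = fu.UnfoldingSchedule.from_order(
            "CDEB", first_break=4.0, spacing=5.0, jitter_sd=0.5,
            positional_noise_sd=0.07,
        )
        ens = fu.generate_ensemble(topology, sched, n_runs=8, seed=2, n_frames=11, dt=5.0)
        series = fu.pattern_series(ens, det)
        part = RingPartition.from_qmap(fu.build_q_map(det), n_rings=64)
        profiles = ring_anisotropy(series, part, n_theta_bins=36)
        r10 = profiles[10.0].anisotropy_ratio
        assert r10[-1] > r10[0]

    def test_off_detector_resolution_raises(self, small_qmap):
        part = RingPartition.from_qmap(small_qmap, n_rings=16)
        series = fu.PatternSeries(
            times=np.array([0.0]),
            intensities=np.zeros((1, 1) + small_qmap.qmag.shape),
            detector=small_qmap.detector,
        )
        with pytest.raises(AnalysisError):
            ring_anisotropy(series, part, resolutions=(3.0,))  # beyond full ring


def test_ring_partition_geometry(small_qmap):
    part = RingPartition.from_qmap(small_qmap, n_rings=16)
    assert part.n_rings == 16
    # rings are contiguous, disjoint, and every pixel index maps to one ring
    for k in range(16):
        q = small_qmap.qmag.reshape(-1)[part.pixels(k)]
        assert np.all(q >= part.edges[k] - 1e-12)
        assert np.all(q < part.edges[k + 1] + 1e-12)
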