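"""Noise-free single-particle X-ray diffraction on a virtual pixel detector.

The detector emulates an AGIPD-like panel: 1024 × 1024 square pixels of
200 μm, 25 cm downstream of the sample, 8 keV photons (λ = 1.55 Å), 10¹²
photons per pulse focused uniformly into a 100 nm spot.  The beam runs along
+z through the detector centre (the corner junction of the four central
pixels).

Per pixel, the expected photon count is the coherent elastic sum

    I(q) = I₀ r_e² P(q) dΩ |Σ_i f_i(q) exp(2πi q·R_i)|²,

algebraically identical (for real form factors) to the explicit
self + cross-term double sum Σ_i A_i + Σ_{i≠j} B_ij with A_i = f_i² and
B_ij = f_i f_j cos(2πq·(R_i−R_j)); both forms are implemented, the coherent
sum as the production path and the double sum as the independent cross-check.
The momentum-transfer convention carries no 2π: |q| = 2 sin θ/λ, so real-
space resolution is 1/|q|.

Atomic form factors are the tabulated 4-Gaussian (Cromer–Mann)
parameterizations, static and spherically symmetric; no damage, photon noise
or incoherent background is modeled — pattern-to-pattern variation comes
only from structural heterogeneity between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import ConfigurationError, ElementError, SamplingError
from .trajectory import EnsembleHandle, Trajectory

#: hc in keV·Å.
HC_KEV_ANGSTROM = 12.398
#: Classical electron radius in Å.
R_E_ANGSTROM = 2.8179403262e-5
ANGSTROM_PER_NM = 10.0


def wavelength_from_energy(photon_energy_kev: float) -> float:
    """Photon wavelength λ = hc/E in Å (8 keV → 1.55 Å)."""
    if photon_energy_kev <= 0:
        raise ConfigurationError("photon energy must be positive")
    return HC_KEV_ANGSTROM / photon_energy_kev


@dataclass(frozen=True)
class DetectorConfig:
    """Virtual detector geometry and beam parameters.

    Defaults are the AGIPD-like reference configuration: 1024 × 1024 pixels
    of 200 μm at 25 cm, 8 keV, 10¹² photons over a 100 nm focus.
    """

    n_pixels: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 200.0
    distance_cm: float = 25.0
    photon_energy_kev: float = 8.0
    fluence: float = 1e12
    focal_diameter_nm: float = 100.0
    polarization_mode: str = "none"

    def __post_init__(self) -> None:
        if min(self.n_pixels) < 1:
            raise ConfigurationError("detector needs at least one pixel")
        for name in ("pixel_size_um", "distance_cm", "photon_energy_kev",
                     "fluence", "focal_diameter_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.polarization_mode not in ("none", "horizontal"):
            raise ConfigurationError(
                f"unknown polarization mode {self.polarization_mode!r}"
            )

    @property
    def wavelength_angstrom(self) -> float:
        return wavelength_from_energy(self.photon_energy_kev)

    @property
    def incident_intensity(self) -> float:
        """I₀: photons per Å², uniform over the focal spot."""
        radius_angstrom = self.focal_diameter_nm * ANGSTROM_PER_NM / 2.0
        return self.fluence / (np.pi * radius_angstrom**2)

    def binned(self, factor: int) -> "DetectorConfig":
        """A coarser detector covering the same solid angle: ``factor``-fold
        fewer pixels per side, ``factor``-fold larger pixels.  Useful for
        desk-scale ensemble analyses where full AGIPD sampling is overkill."""
        return replace(
            self,
            n_pixels=(self.n_pixels[0] // factor, self.n_pixels[1] // factor),
            pixel_size_um=self.pixel_size_um * factor,
        )


@dataclass
class QMap:
    """Per-pixel scattering geometry for one detector configuration.

    ``qvec`` (rows, cols, 3) is the scattering vector in Å⁻¹ on the Ewald
    construction with |q| = 2 sin θ/λ; ``solid_angle`` includes the cos³2θ
    obliquity factor; ``polarization`` is 1 for unpolarized mode or
    1 − (cos φ sin 2θ)² for horizontal polarization.
    """

    qvec: np.ndarray
    qmag: np.ndarray
    two_theta: np.ndarray
    azimuth: np.ndarray
    solid_angle: np.ndarray
    polarization: np.ndarray
    detector: DetectorConfig

    @property
    def max_full_ring_q(self) -> float:
        """Largest |q| whose complete azimuthal ring lies on the detector
        (set by the nearest edge through pixel centres)."""
        rows, cols = self.detector.n_pixels
        pixel_angstrom = self.detector.pixel_size_um * 1e4
        distance_angstrom = self.detector.distance_cm * 1e8
        r_edge = (min(rows, cols) / 2.0 - 0.5) * pixel_angstrom
        theta = 0.5 * np.arctan2(r_edge, distance_angstrom)
        return 2.0 * np.sin(theta) / self.detector.wavelength_angstrom

    @property
    def best_resolution_angstrom(self) -> float:
        """1/q at the outermost pixel centre (the detector corner)."""
        return float(1.0 / self.qmag.max())

    @property
    def best_full_ring_resolution_angstrom(self) -> float:
        return float(1.0 / self.max_full_ring_q)


def build_q_map(detector: DetectorConfig) -> QMap:
    """Scattering-vector map, solid angles and polarization factors.

    The beam axis (+z) passes through the junction of the four central
    pixels; pixel-centre transverse offsets are therefore half-integer
    multiples of the pixel size.  For a pixel at transverse radius r the
    scattering angle is 2θ = atan(r/D), the scattering vector is
    (ŝ − ẑ)/λ with ŝ the unit vector toward the pixel, and the pixel solid
    angle is A cos³(2θ)/D².
    """
    rows, cols = detector.n_pixels
    pixel = detector.pixel_size_um * 1e4  # Å
    distance = detector.distance_cm * 1e8  # Å
    lam = detector.wavelength_angstrom

    y = (np.arange(rows) - rows / 2.0 + 0.5) * pixel
    x = (np.arange(cols) - cols / 2.0 + 0.5) * pixel
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X, Y)
    two_theta = np.arctan2(r, distance)
    azimuth = np.arctan2(Y, X)

    norm = np.sqrt(X**2 + Y**2 + distance**2)
    qvec = np.stack(
        [X / norm, Y / norm, distance / norm - 1.0], axis=-1
    ) / lam
    qmag = 2.0 * np.sin(two_theta / 2.0) / lam

    solid_angle = (pixel**2) * np.cos(two_theta) ** 3 / distance**2
    if detector.polarization_mode == "horizontal":
        polarization = 1.0 - (np.cos(azimuth) * np.sin(two_theta)) ** 2
    else:
        polarization = np.ones_like(qmag)
    return QMap(
        qvec=qvec,
        qmag=qmag,
        two_theta=two_theta,
        azimuth=azimuth,
        solid_angle=solid_angle,
        polarization=polarization,
        detector=detector,
    )


def _it92_coefficients(element: str):
    el = gemmi.Element(element.capitalize())
    if el.atomic_number == 0:
        raise ElementError(f"unknown element symbol {element!r}")
    it = el.it92
    if it is None:
        raise ElementError(f"no form-factor table entry for {element!r}")
    return np.asarray(it.a), np.asarray(it.b), float(it.c)


def atomic_form_factor(element: str, qmag) -> np.ndarray | float:
    """Tabulated coherent X-ray form factor f(|q|), dimensionless.

    The 4-Gaussian-plus-constant parameterization is evaluated at
    s² = (|q|/2)², the crystallographic (sin θ/λ)² argument; f(0) equals the
    element's electron count Z.
    """
    a, b, c = _it92_coefficients(element)
    q = np.asarray(qmag, dtype=float)
    stol2 = (q / 2.0) ** 2
    f = c + np.sum(a * np.exp(-b * stol2[..., None]), axis=-1)
    return float(f) if np.isscalar(qmag) else f


@dataclass
class DiffractionPattern:
    """Expected photon counts per pixel for one frame."""

    intensities: np.ndarray
    time_label: float
    detector: DetectorConfig


def _frame_inputs(frame, elements=None):
    if isinstance(frame, Trajectory):
        if frame.n_frames != 1:
            raise ConfigurationError("pass a single frame, not a trajectory")
        return frame.coords[0], list(frame.elements)
    coords = np.asarray(frame, dtype=float)
    if elements is None:
        elements = ["C"] * coords.shape[0]
    return coords, list(elements)


def diffraction_pattern(
    frame,
    detector: DetectorConfig,
    elements: list[str] | None = None,
    qmap: QMap | None = None,
    time_label: float = 0.0,
    chunk_pixels: int = 16384,
) -> DiffractionPattern:
    """Coherent-sum diffraction pattern of one frame (production path).

    ``frame`` is either a single-frame :class:`Trajectory` or an
    ``(n_atoms, 3)`` coordinate array in nm (with ``elements``).  Pass a
    precomputed ``qmap`` when evaluating many frames on one detector.
    """
    coords_nm, elem = _frame_inputs(frame, elements)
    if not np.all(np.isfinite(coords_nm)):
        raise ConfigurationError("coordinates must be finite")
    if qmap is None:
        qmap = build_q_map(detector)
    coords = coords_nm * ANGSTROM_PER_NM

    shape = qmap.qmag.shape
    qvec_flat = qmap.qvec.reshape(-1, 3)
    qmag_flat = qmap.qmag.reshape(-1)
    elem_arr = np.array([e.upper() for e in elem])
    unique_elements = sorted(set(elem_arr))
    coeffs = {e: _it92_coefficients(e) for e in unique_elements}

    amplitude = np.zeros(qvec_flat.shape[0], dtype=complex)
    for start in range(0, qvec_flat.shape[0], chunk_pixels):
        sl = slice(start, start + chunk_pixels)
        stol2 = (qmag_flat[sl] / 2.0) ** 2
        chunk_amp = np.zeros(stol2.shape[0], dtype=complex)
        for e in unique_elements:
            sel = elem_arr == e
            a, b, c = coeffs[e]
            f = c + np.sum(a * np.exp(-b * stol2[:, None]), axis=-1)
            phases = np.exp(
                2j * np.pi * (qvec_flat[sl] @ coords[sel].T)
            ).sum(axis=1)
            chunk_amp += f * phases
        amplitude[sl] = chunk_amp

    prefactor = (
        detector.incident_intensity
        * R_E_ANGSTROM**2
        * qmap.polarization.reshape(-1)
        * qmap.solid_angle.reshape(-1)
    )
    intensities = (prefactor * np.abs(amplitude) ** 2).reshape(shape)
    return DiffractionPattern(intensities, time_label, detector)


def diffraction_pattern_double_sum(
    frame,
    detector: DetectorConfig,
    elements: list[str] | None = None,
    qmap: QMap | None = None,
    time_label: float = 0.0,
) -> DiffractionPattern:
    """Explicit self + cross-term double sum (independent cross-check path).

    Evaluates I = I₀ r_e² P dΩ (Σ_i A_i + Σ_{i≠j} B_ij) with A_i = f_i² and
    B_ij = f_i f_j cos(2πq·(R_i−R_j)).  O(pixels × M²): intended for small
    frames and coarse detectors.
    """
    coords_nm, elem = _frame_inputs(frame, elements)
    if qmap is None:
        qmap = build_q_map(detector)
    coords = coords_nm * ANGSTROM_PER_NM
    shape = qmap.qmag.shape
    qvec = qmap.qvec.reshape(-1, 3)
    qmag = qmap.qmag.reshape(-1)

    f = np.stack([atomic_form_factor(e, qmag) for e in elem], axis=1)  # (px, M)
    total = np.sum(f**2, axis=1)  # Σ A_i
    m = coords.shape[0]
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            phase = 2.0 * np.pi * (qvec @ (coords[i] - coords[j]))
            total += f[:, i] * f[:, j] * np.cos(phase)

    prefactor = (
        detector.incident_intensity
        * R_E_ANGSTROM**2
        * qmap.polarization.reshape(-1)
        * qmap.solid_angle.reshape(-1)
    )
    return DiffractionPattern((prefactor * total).reshape(shape), time_label, detector)


DEFAULT_TIME_POINTS_PS = tuple(float(t) for t in range(0, 51, 5))


@dataclass
class PatternSeries:
    """Per-time, per-run diffraction patterns of an ensemble.

    ``intensities`` has shape ``(n_times, n_runs, rows, cols)``.
    """

    times: np.ndarray
    intensities: np.ndarray
    detector: DetectorConfig
    run_ids: list[str] = field(default_factory=list)

    @property
    def n_times(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_runs(self) -> int:
        return self.intensities.shape[1]

    def at_time(self, t: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise SamplingError(f"no patterns at t = {t} ps")
        return self.intensities[idx[0]]

    def mean_patterns(self) -> np.ndarray:
        """Run-averaged pattern per time, shape (n_times, rows, cols)."""
        return self.intensities.mean(axis=1)

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("times_ps", data=self.times)
            h5.create_dataset("intensities", data=self.intensities)
            h5.attrs["run_ids"] = [str(r) for r in self.run_ids]
            for key, value in vars(self.detector).items():
                h5.attrs[f"detector_{key}"] = (
                    list(value) if isinstance(value, tuple) else value
                )

    @classmethod
    def load_h5(cls, path) -> "PatternSeries":
        import h5py

        with h5py.File(path, "r") as h5:
            det = DetectorConfig(
                n_pixels=tuple(int(v) for v in h5.attrs["detector_n_pixels"]),
                pixel_size_um=float(h5.attrs["detector_pixel_size_um"]),
                distance_cm=float(h5.attrs["detector_distance_cm"]),
                photon_energy_kev=float(h5.attrs["detector_photon_energy_kev"]),
                fluence=float(h5.attrs["detector_fluence"]),
                focal_diameter_nm=float(h5.attrs["detector_focal_diameter_nm"]),
                polarization_mode=str(h5.attrs["detector_polarization_mode"]),
            )
            return cls(
                times=np.asarray(h5["times_ps"]),
                intensities=np.asarray(h5["intensities"]),
                detector=det,
                run_ids=[str(r) for r in h5.attrs.get("run_ids", [])],
            )


def pattern_series(
    ensemble: EnsembleHandle,
    detector: DetectorConfig,
    time_points: list[float] | None = None,
) -> PatternSeries:
    """Diffraction patterns for every run at every requested time point.

    The default time list is 0, 5, …, 50 ps (11 frames).  Every requested
    time must lie on the ensemble's frame grid.
    """
    times = np.asarray(
        DEFAULT_TIME_POINTS_PS if time_points is None else time_points, dtype=float
    )
    qmap = build_q_map(detector)
    rows, cols = detector.n_pixels
    out = np.empty((times.shape[0], ensemble.n_runs, rows, cols))
    for ti, t in enumerate(times):
        for ri, run in enumerate(ensemble):
            frame = run.frame_at_time(t)  # raises SamplingError if absent
            out[ti, ri] = diffraction_pattern(
                frame, detector, elements=run.elements, qmap=qmap, time_label=t
            ).intensities
    return PatternSeries(
        times=times,
        intensities=out,
        detector=detector,
        run_ids=[run.run_id for run in ensemble],
    )
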