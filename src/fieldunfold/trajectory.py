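"""The canonical in-memory trajectory container used by every analysis stage.

Units are nm for coordinates and ps for times throughout the package; only the
diffraction stage converts to Å internally (resolution and momentum transfer
are conventionally quoted in Å for X-ray scattering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EnsembleError, FormatError

#: Elements with a form-factor table entry (extendable; see diffraction module).
KNOWN_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P", "FE", "ZN"})


@dataclass
class Trajectory:
    """Ordered frames of atomic coordinates for one run.

    Attributes
    ----------
    times
        Frame times in ps, strictly increasing and uniformly spaced,
        shape ``(n_frames,)``.
    coords
        Coordinates in nm, shape ``(n_frames, n_atoms, 3)``.
    elements
        Per-atom chemical element symbols (upper case), length ``n_atoms``.
    residue_index
        Per-atom 1-based residue indices, shape ``(n_atoms,)``.
    run_id
        Identifier of the run within its ensemble.
    """

    times: np.ndarray
    coords: np.ndarray
    elements: list[str]
    residue_index: np.ndarray
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        n_frames, n_atoms, _ = self.coords.shape
        if self.times.shape != (n_frames,):
            raise FormatError("times length does not match number of frames")
        if len(self.elements) != n_atoms or self.residue_index.shape != (n_atoms,):
            raise FormatError("elements/residue_index length does not match atom count")
        if n_frames >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise FormatError("frame times must be uniformly spaced")
        unknown = {e.upper() for e in self.elements} - KNOWN_ELEMENTS
        if unknown:
            raise FormatError(f"unknown element symbols: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` in nm, shape ``(n_atoms, 3)``."""
        return self.coords[i]

    def frame_at_time(self, t: float, atol: float = 1e-6) -> np.ndarray:
        """Coordinates at time ``t`` (must lie on the grid within ``atol`` ps)."""
        idx = self.index_at_time(t, atol=atol)
        return self.coords[idx]

    def index_at_time(self, t: float, atol: float = 1e-6) -> int:
        hits = np.nonzero(np.isclose(self.times, t, rtol=0, atol=atol))[0]
        if hits.size == 0:
            from .errors import SamplingError

            raise SamplingError(f"time {t} ps is not on the trajectory grid")
        return int(hits[0])


@dataclass
class EnsembleHandle:
    """An ensemble: N independent runs of the same system on a shared time grid."""

    runs: list[Trajectory]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.runs:
            raise EnsembleError("ensemble contains no runs")
        ref = self.runs[0]
        for i, run in enumerate(self.runs):
            if run.n_atoms != ref.n_atoms:
                raise EnsembleError(
                    f"run {i} ({run.run_id}) has {run.n_atoms} atoms, expected {ref.n_atoms}"
                )
            if run.elements != ref.elements or not np.array_equal(
                run.residue_index, ref.residue_index
            ):
                raise EnsembleError(f"run {i} ({run.run_id}) has a different atom ordering")
            if run.times.shape != ref.times.shape or not np.allclose(
                run.times, ref.times, rtol=0, atol=1e-9
            ):
                raise EnsembleError(f"run {i} ({run.run_id}) is on a different time grid")

    @property
    def times(self) -> np.ndarray:
        return self.runs[0].times

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)
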