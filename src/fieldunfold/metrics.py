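"""Ensemble structural statistics.

Per-frame RMSD to the shared initial structure (after optimal rigid-body
superposition), radius of gyration, the mean ± one-sigma-deviation-of-the-
average statistic σ/√N over N independent runs, residue–residue Cα distance
maps averaged over time windows, and identification of the residue regions
that separate furthest between two windows (candidate chromophore attachment
sites for FRET detection of unfolding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as _cc_label
from scipy.spatial.transform import Rotation

from .errors import AnalysisError
from .trajectory import EnsembleHandle


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Uses the Kabsch algorithm (via quaternion-based alignment); the rotation
    is always proper (no reflection).  Returns the transformed coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def rmsd_to_reference(
    frame: np.ndarray, reference: np.ndarray, superpose_first: bool = True
) -> float:
    """RMSD (nm) between a frame and a reference frame.

    With ``superpose_first`` (default) an optimal rigid-body superposition
    (rotation + translation, reflection excluded) precedes the comparison, so
    rigid motions contribute nothing.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise AnalysisError(
            f"atom count mismatch: {frame.shape} vs {reference.shape}"
        )
    if superpose_first:
        frame = superpose(frame, reference)
    return float(np.sqrt(np.mean(np.sum((frame - reference) ** 2, axis=1))))


def radius_of_gyration(frame: np.ndarray) -> float:
    """Root-mean-square distance (nm) of atoms from their centre of mass,
    unweighted (uniform masses in the Cα model)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] < 1:
        raise AnalysisError("frame has no atoms")
    centred = frame - frame.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


@dataclass
class EnsembleStats:
    """Mean and one-sigma deviation of the average of a per-run scalar metric.

    ``sem`` is σ/√N with σ the sample standard deviation (N−1 denominator)
    over the N runs, per time point.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_runs: int
    metric: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "mean": self.mean, "sem": self.sem}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# metric={self.metric} n_runs={self.n_runs}\n")
            df.to_csv(fh, index=False)


def ensemble_mean_sem(
    values: np.ndarray, times: np.ndarray, metric: str = ""
) -> EnsembleStats:
    """Mean over runs and σ/√N per time point.

    ``values`` has shape ``(n_runs, n_times)``; at least 2 runs are required
    for the standard deviation to be defined.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise AnalysisError("need a (n_runs >= 2, n_times) value array")
    n = values.shape[0]
    sigma = values.std(axis=0, ddof=1)
    return EnsembleStats(
        times=np.asarray(times, dtype=float),
        mean=values.mean(axis=0),
        sem=sigma / np.sqrt(n),
        n_runs=n,
        metric=metric,
    )


def rmsd_series(ensemble: EnsembleHandle, superpose_first: bool = True) -> np.ndarray:
    """Per-run, per-frame RMSD (nm) to each run's initial frame,
    shape ``(n_runs, n_times)``."""
    out = np.empty((ensemble.n_runs, ensemble.times.shape[0]))
    for r, run in enumerate(ensemble):
        ref = run.coords[0]
        for f in range(run.n_frames):
            out[r, f] = rmsd_to_reference(run.coords[f], ref, superpose_first)
    return out


def rmsd_ensemble(
    ensemble: EnsembleHandle, mode: str = "reference", superpose_first: bool = True
) -> EnsembleStats:
    """Ensemble RMSD statistic vs time.

    ``mode="reference"`` (default): per-run RMSD against the shared initial
    structure, then mean ± σ/√N over runs — the deviation-from-the-original-
    configuration reading.  ``mode="spread"``: mean pairwise RMSD between
    runs at each time, a structural-heterogeneity measure (its ``sem`` is the
    σ/√(pairs) over the pairwise values).
    """
    if mode == "reference":
        return ensemble_mean_sem(
            rmsd_series(ensemble, superpose_first), ensemble.times, metric="rmsd_nm"
        )
    if mode == "spread":
        n_times = ensemble.times.shape[0]
        runs = ensemble.runs
        mean = np.empty(n_times)
        sem = np.empty(n_times)
        for f in range(n_times):
            vals = [
                rmsd_to_reference(runs[i].coords[f], runs[j].coords[f], superpose_first)
                for i in range(len(runs))
                for j in range(i + 1, len(runs))
            ]
            vals = np.asarray(vals)
            mean[f] = vals.mean()
            sem[f] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        return EnsembleStats(ensemble.times, mean, sem, ensemble.n_runs, "rmsd_spread_nm")
    raise AnalysisError(f"unknown RMSD mode {mode!r}")


def rg_ensemble(ensemble: EnsembleHandle) -> EnsembleStats:
    """Radius of gyration vs time, mean ± σ/√N over runs."""
    values = np.empty((ensemble.n_runs, ensemble.times.shape[0]))
    for r, run in enumerate(ensemble):
        centred = run.coords - run.coords.mean(axis=1, keepdims=True)
        values[r] = np.sqrt(np.mean(np.sum(centred**2, axis=2), axis=1))
    return ensemble_mean_sem(values, ensemble.times, metric="rg_nm")


@dataclass
class DistanceMap:
    """Residue × residue mean Cα–Cα distance (nm) over a time window."""

    matrix: np.ndarray
    window: tuple[float, float]
    n_runs: int

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# window_ps={self.window[0]}:{self.window[1]} n_runs={self.n_runs}\n"
            )
            pd.DataFrame(self.matrix).to_csv(fh, index=False, header=False)

    def to_image(self, path) -> None:
        """Grayscale map, upper triangle populated, lower left empty (dark) —
        the redundant half carries no information."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        upper = np.triu(self.matrix)
        plt.imsave(path, upper, cmap="gray")


def ca_distance_map(
    ensemble: EnsembleHandle, window: tuple[float, float]
) -> DistanceMap:
    """Mean pairwise Cα distance over all frames in ``window`` and all runs.

    The window is inclusive in ps.  In the default Cα model every atom is an
    α-carbon; for all-atom input, filter to Cα before building the handle.
    """
    t0, t1 = window
    sel = (ensemble.times >= t0 - 1e-9) & (ensemble.times <= t1 + 1e-9)
    if not np.any(sel):
        raise AnalysisError(f"window {window} ps contains no frames")
    n_atoms = ensemble.runs[0].n_atoms
    acc = np.zeros((n_atoms, n_atoms))
    n_frames = 0
    for run in ensemble:
        frames = run.coords[sel]
        # chunked so the (frames, n, n, 3) broadcast stays small
        for chunk in np.array_split(frames, max(1, frames.shape[0] // 64)):
            diff = chunk[:, :, None, :] - chunk[:, None, :, :]
            acc += np.sqrt(np.sum(diff**2, axis=3)).sum(axis=0)
        n_frames += frames.shape[0]
    return DistanceMap(matrix=acc / n_frames, window=(t0, t1), n_runs=ensemble.n_runs)


@dataclass
class RegionPair:
    """A pair of contiguous residue ranges with their mean separation gain."""

    rows: tuple[int, int]
    cols: tuple[int, int]
    mean_gain: float
    max_gain: float


def max_separating_regions(
    map_early: DistanceMap,
    map_late: DistanceMap,
    top_k: int = 3,
    threshold_fraction: float = 0.5,
) -> list[RegionPair]:
    """Residue-region pairs that separate furthest between two windows.

    The per-pair gain matrix ``late − early`` is thresholded at
    ``threshold_fraction`` of its maximum positive entry; connected segments
    of the upper triangle (4-connectivity) become candidate region pairs,
    ranked by mean gain.  Residue ranges are 1-based inclusive bounding
    ranges of each segment.  Returns an empty list if no pair gains.
    """
    if map_early.matrix.shape != map_late.matrix.shape:
        raise AnalysisError("distance maps have different shapes")
    gain = map_late.matrix - map_early.matrix
    gain = np.triu(gain, k=1)
    max_gain = gain.max()
    if max_gain <= 0:
        return []
    mask = gain > threshold_fraction * max_gain
    labels, n_components = _cc_label(mask)
    regions: list[RegionPair] = []
    for comp in range(1, n_components + 1):
        rows, cols = np.nonzero(labels == comp)
        vals = gain[rows, cols]
        regions.append(
            RegionPair(
                rows=(int(rows.min()) + 1, int(rows.max()) + 1),
                cols=(int(cols.min()) + 1, int(cols.max()) + 1),
                mean_gain=float(vals.mean()),
                max_gain=float(vals.max()),
            )
        )
    regions.sort(key=lambda r: -r.mean_gain)
    return regions[:top_k]
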