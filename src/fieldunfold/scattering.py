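"""Fourier Ring Correlation and azimuthal ring anisotropy of pattern sets.

FRC compares two half-ensemble average patterns ring by ring: the set of
patterns at one time point is split into two equal halves, each half is
averaged pixel-wise, and for every resolution ring the Pearson correlation
of the two averages over the ring's pixels is computed.  FRC lies in
[−1, 1]; 1 means the halves agree perfectly at that resolution, 0 that they
are uncorrelated.  The resolution limit at a time point is 1/q_max where
q_max is the largest momentum transfer below which FRC stays above a cutoff
(0.5 by default).  Structural heterogeneity between runs degrades the limit,
so a two-pathway ensemble resolves worse than a single-pathway one while the
pathways diverge.

Ring anisotropy addresses ensemble-averaged (SAXS-like) detection instead:
the azimuthal intensity profile I_R(θ, t) within fixed resolution rings
(5/10/15 Å by default).  A compact, roughly isotropic particle gives a flat
profile; field-aligned elongation concentrates intensity at azimuths
perpendicular to the stretch axis, so the max/mean anisotropy ratio grows as
unfolding proceeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .diffraction import PatternSeries, QMap

DEFAULT_FRC_CUTOFF = 0.5
DEFAULT_N_RINGS = 64
DEFAULT_RING_RESOLUTIONS = (5.0, 10.0, 15.0)


@dataclass
class RingPartition:
    """Partition of detector pixels into equal-width resolution rings.

    ``ring_index`` assigns each (flattened) pixel to a ring, −1 for pixels
    beyond the outermost ring edge; rings are contiguous in |q| with edges
    ``edges[k] <= q < edges[k+1]``.
    """

    edges: np.ndarray
    ring_index: np.ndarray
    azimuth: np.ndarray
    shape: tuple[int, int]
    _pixels: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.ring_index = np.asarray(self.ring_index)
        if not self._pixels:
            self._pixels = [
                np.nonzero(self.ring_index == k)[0] for k in range(self.n_rings)
            ]
        if any(p.size == 0 for p in self._pixels):
            raise AnalysisError("every ring must contain at least one pixel")

    @property
    def n_rings(self) -> int:
        return self.edges.shape[0] - 1

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def pixels(self, ring: int) -> np.ndarray:
        """Flat pixel indices of one ring."""
        return self._pixels[ring]

    def ring_containing(self, q: float) -> int:
        """Index of the ring whose q interval contains ``q``."""
        if q < self.edges[0] or q >= self.edges[-1]:
            raise AnalysisError(
                f"q = {q:.4f} 1/Å lies outside the ring partition "
                f"[{self.edges[0]:.4f}, {self.edges[-1]:.4f})"
            )
        return int(np.searchsorted(self.edges, q, side="right") - 1)

    @classmethod
    def from_qmap(
        cls, qmap: QMap, n_rings: int = DEFAULT_N_RINGS, q_max: float | None = None
    ) -> "RingPartition":
        """Equal-width rings in |q| from 0 to the largest full ring on the
        detector (or ``q_max``).  ``n_rings`` is capped at half the smaller
        pixel dimension so every ring contains at least one pixel."""
        if q_max is None:
            q_max = qmap.max_full_ring_q
        n_rings = min(n_rings, min(qmap.qmag.shape) // 2)
        edges = np.linspace(0.0, q_max, n_rings + 1)
        qflat = qmap.qmag.reshape(-1)
        idx = np.floor(qflat / q_max * n_rings).astype(int)
        idx[(qflat >= q_max) | (idx >= n_rings)] = -1
        return cls(
            edges=edges,
            ring_index=idx,
            azimuth=qmap.azimuth.reshape(-1),
            shape=qmap.qmag.shape,
        )


def half_set_average(
    patterns, split: str = "even-odd", seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split a set of patterns into two equal halves and average each.

    ``patterns`` is an array ``(n, rows, cols)`` or a list of 2-D arrays.
    ``split="even-odd"`` alternates by index (deterministic);
    ``split="seeded-random"`` permutes with ``seed`` first.  An odd pattern
    count drops the last pattern with a warning.
    """
    arr = np.asarray([np.asarray(p) for p in patterns], dtype=float)
    if arr.shape[0] < 2:
        raise AnalysisError("need at least 2 patterns to form half sets")
    if arr.shape[0] % 2:
        warnings.warn(
            f"odd pattern count {arr.shape[0]}: dropping the last pattern",
            stacklevel=2,
        )
        arr = arr[:-1]
    order = np.arange(arr.shape[0])
    if split == "seeded-random":
        order = np.random.default_rng(seed).permutation(order)
    elif split != "even-odd":
        raise ConfigurationError(f"unknown split mode {split!r}")
    return arr[order[0::2]].mean(axis=0), arr[order[1::2]].mean(axis=0)


@dataclass
class FRCCurve:
    """FRC value per resolution ring; NaN where a ring has zero variance."""

    q_centres: np.ndarray
    values: np.ndarray
    edges: np.ndarray
    time_label: float = 0.0

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q_centre": self.q_centres, "frc": self.values})


def frc(
    pattern_1: np.ndarray,
    pattern_2: np.ndarray,
    partition: RingPartition,
    time_label: float = 0.0,
) -> FRCCurve:
    """Ring-wise Pearson correlation between two patterns.

    Per ring, FRC = Σ(I₁−Ī₁)(I₂−Ī₂) / √(Σ(I₁−Ī₁)² Σ(I₂−Ī₂)²) with the sums
    over the ring's pixels and Ī the ring means; rings with zero variance in
    either pattern are undefined (NaN).
    """
    p1 = np.asarray(pattern_1, dtype=float)
    p2 = np.asarray(pattern_2, dtype=float)
    if p1.shape != p2.shape or p1.reshape(-1).shape[0] != partition.ring_index.shape[0]:
        raise AnalysisError("patterns and ring partition have mismatched geometry")
    f1, f2 = p1.reshape(-1), p2.reshape(-1)
    values = np.full(partition.n_rings, np.nan)
    for k in range(partition.n_rings):
        px = partition.pixels(k)
        a = f1[px] - f1[px].mean()
        b = f2[px] - f2[px].mean()
        denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
        if denom > 0:
            values[k] = float(np.sum(a * b) / denom)
    return FRCCurve(
        q_centres=partition.centres,
        values=values,
        edges=partition.edges,
        time_label=time_label,
    )


@dataclass
class ResolutionLimit:
    """FRC resolution limit at one time point.

    ``status`` is ``"ok"`` (the curve crossed the cutoff), ``"detector-
    limited"`` (it never did: the limit is the detector's best full-ring
    resolution), or ``"not-reached"`` (the first ring already fails — the
    limit is worse than the lowest-resolution ring).  Limits are taken at
    ring upper edges; ``bin_width`` quantifies the half-bin ambiguity.
    """

    resolution_angstrom: float
    status: str
    q_max: float
    bin_width: float
    time_label: float = 0.0


def resolution_limit(
    curve: FRCCurve, cutoff: float = DEFAULT_FRC_CUTOFF
) -> ResolutionLimit:
    """Scan rings from low q; q_max is the upper edge of the last ring before
    the first ring with FRC ≤ cutoff.  Undefined (NaN) rings are skipped."""
    if curve.values.shape[0] == 0:
        raise AnalysisError("empty FRC curve")
    q_max = None
    for k in range(curve.values.shape[0]):
        v = curve.values[k]
        if np.isnan(v):
            continue
        if v <= cutoff:
            if q_max is None:
                return ResolutionLimit(
                    np.inf, "not-reached", 0.0, curve.bin_width, curve.time_label
                )
            return ResolutionLimit(
                1.0 / q_max, "ok", q_max, curve.bin_width, curve.time_label
            )
        q_max = float(curve.edges[k + 1])
    if q_max is None:
        raise AnalysisError("FRC curve has no defined rings")
    return ResolutionLimit(
        1.0 / q_max, "detector-limited", q_max, curve.bin_width, curve.time_label
    )


def frc_timeseries(
    series: PatternSeries,
    partition: RingPartition,
    cutoff: float = DEFAULT_FRC_CUTOFF,
    split: str = "even-odd",
    seed: int | None = None,
    n_splits: int = 1,
) -> pd.DataFrame:
    """Half-set split, average, FRC and resolution limit per time point.

    With ``n_splits > 1`` (requires ``split="seeded-random"``), the limit at
    each time point is averaged over several seeded half-splits on the q_max
    scale: a single split of a heterogeneous ensemble can by chance place
    equal numbers of each structural class in both halves and so hide the
    heterogeneity; split averaging removes that variance.  The reported
    resolution is then 1/mean(q_max) with q_max = 0 for splits whose first
    ring already falls below the cutoff, and the status is the majority
    status over splits.

    Returns a DataFrame with columns ``time_ps``, ``resolution_angstrom``,
    ``status``, ``q_max`` and ``bin_width``.
    """
    if n_splits > 1 and split != "seeded-random":
        raise ConfigurationError("n_splits > 1 requires split='seeded-random'")
    base_seed = 0 if seed is None else seed
    records = []
    for ti, t in enumerate(series.times):
        limits = []
        for k in range(n_splits):
            avg1, avg2 = half_set_average(
                series.intensities[ti], split=split, seed=base_seed + k
            )
            curve = frc(avg1, avg2, partition, time_label=float(t))
            limits.append(resolution_limit(curve, cutoff=cutoff))
        if n_splits == 1:
            lim = limits[0]
            resolution, status, q_max = lim.resolution_angstrom, lim.status, lim.q_max
        else:
            q_max = float(np.mean([l.q_max for l in limits]))
            resolution = 1.0 / q_max if q_max > 0 else np.inf
            statuses = [l.status for l in limits]
            status = max(set(statuses), key=statuses.count)
        records.append(
            {
                "time_ps": float(t),
                "resolution_angstrom": resolution,
                "status": status,
                "q_max": q_max,
                "bin_width": limits[0].bin_width,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass
class RingProfile:
    """Azimuthal intensity profile of one resolution ring over time.

    ``intensity[t, b]`` is the mean pixel intensity of θ-bin ``b`` at time
    index ``t``, normalized by the ring's angular mean at the first time
    point; ``anisotropy_ratio[t]`` is max_θ/mean_θ at time ``t`` (a flat,
    isotropic ring gives 1).
    """

    resolution_angstrom: float
    theta_centres: np.ndarray
    times: np.ndarray
    intensity: np.ndarray
    anisotropy_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for ti, t in enumerate(self.times):
            for bi, th in enumerate(self.theta_centres):
                recs.append(
                    {
                        "resolution_angstrom": self.resolution_angstrom,
                        "time_ps": float(t),
                        "theta_rad": float(th),
                        "intensity": float(self.intensity[ti, bi]),
                    }
                )
        return pd.DataFrame.from_records(recs)


def ring_anisotropy(
    series: PatternSeries,
    partition: RingPartition,
    resolutions: tuple[float, ...] = DEFAULT_RING_RESOLUTIONS,
    n_theta_bins: int = 36,
) -> dict[float, RingProfile]:
    """Azimuthal profiles I_R(θ, t) of the run-averaged patterns within
    fixed resolution rings (one q-bin wide) at R = 5, 10, 15 Å by default.

    Each requested resolution ring must lie inside the partition (i.e. on
    the detector's full-ring range); intensities are normalized by the
    ring's angular mean at the first time point.
    """
    mean_patterns = series.mean_patterns().reshape(series.n_times, -1)
    theta_edges = np.linspace(-np.pi, np.pi, n_theta_bins + 1)
    theta_centres = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    out: dict[float, RingProfile] = {}
    for R in resolutions:
        ring = partition.ring_containing(1.0 / R)
        px = partition.pixels(ring)
        theta = partition.azimuth[px]
        bins = np.clip(np.digitize(theta, theta_edges) - 1, 0, n_theta_bins - 1)
        profile = np.empty((series.n_times, n_theta_bins))
        for ti in range(series.n_times):
            vals = mean_patterns[ti, px]
            sums = np.bincount(bins, weights=vals, minlength=n_theta_bins)
            counts = np.bincount(bins, minlength=n_theta_bins)
            with np.errstate(invalid="ignore"):
                profile[ti] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        norm = np.nanmean(profile[0])
        if norm > 0:
            profile = profile / norm
        ratio = np.nanmax(profile, axis=1) / np.nanmean(profile, axis=1)
        out[R] = RingProfile(
            resolution_angstrom=float(R),
            theta_centres=theta_centres,
            times=series.times,
            intensity=profile,
            anisotropy_ratio=ratio,
        )
    return out
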