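"""β-sheet coupling states, Markovian transition maps and unfolding pathways.

Each frame of a run is encoded as a 4-bit state ``*BCDE``: bit 0 means the
coupling's two strands are connected, bit 1 that they are broken, where
"broken" means the centre-of-mass distance of the two strands exceeds a
threshold (0.7 nm by default; the value is an empirical choice that gives
clean diagrams rather than a physical constant).  The helix carries no bit —
its end-to-end distance oscillates too fast to give a stable criterion — so
the state space is the 2^4 = 16 codes ``*0000`` (native) … ``*1111`` (fully
unfolded).

Probing every ``dt_probe`` (0.05 ps by default) yields a state series per
run; counting probe-to-probe transitions over an ensemble yields a Markovian
transition count map whose sinks are the states runs terminate in.  The
unfolding pathway of a run is the order in which its couplings first break,
e.g. ``"CDEB"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, EncodingError, SamplingError, TopologyError
from .topology import COUPLING_LABELS, StrandTopology
from .trajectory import Trajectory

DEFAULT_THRESHOLD_NM = 0.7
DEFAULT_DT_PROBE_PS = 0.05

#: All 16 state codes, ordered by integer value of the BCDE bits.
ALL_STATES: tuple[str, ...] = tuple(
    "*" + format(i, "04b") for i in range(16)
)
NATIVE_STATE = "*0000"
UNFOLDED_STATE = "*1111"


def state_index(code: str) -> int:
    """Integer 0–15 of a ``*BCDE`` code (B is the most significant bit)."""
    return int(code.lstrip("*"), 2)


def state_code(index: int) -> str:
    return ALL_STATES[index]


def hamming_weight(code: str) -> int:
    """Number of broken couplings in a state code."""
    return code.count("1")


def strand_com_distances(
    coords: np.ndarray,
    topology: StrandTopology,
    residue_index: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """Centre-of-mass distance (nm) between the two strands of each coupling.

    ``coords`` is one frame, shape ``(n_atoms, 3)``.  The COM is the
    unweighted per-atom mean by default (uniform masses in the Cα model);
    pass per-atom ``weights`` (e.g. masses) for all-atom input.
    """
    coords = np.asarray(coords, dtype=float)
    if residue_index is None:
        residue_index = np.arange(1, coords.shape[0] + 1)
    residue_index = np.asarray(residue_index)
    out: dict[str, float] = {}
    for label, (a, b) in topology.couplings.items():
        coms = []
        for strand in (a, b):
            lo, hi = topology.strand_ranges[strand]
            sel = (residue_index >= lo) & (residue_index <= hi)
            if not np.any(sel):
                raise TopologyError(
                    f"coupling {label}: strand {strand} selects no atoms"
                )
            if weights is None:
                coms.append(coords[sel].mean(axis=0))
            else:
                w = np.asarray(weights, dtype=float)[sel]
                coms.append((coords[sel] * w[:, None]).sum(axis=0) / w.sum())
        out[label] = float(np.linalg.norm(coms[0] - coms[1]))
    return out


def coupling_distance_series(
    trajectory: Trajectory, topology: StrandTopology
) -> dict[str, np.ndarray]:
    """Per-coupling strand COM distance for every frame, vectorized."""
    out: dict[str, np.ndarray] = {}
    residx = trajectory.residue_index
    for label, (a, b) in topology.couplings.items():
        coms = []
        for strand in (a, b):
            lo, hi = topology.strand_ranges[strand]
            sel = (residx >= lo) & (residx <= hi)
            if not np.any(sel):
                raise TopologyError(
                    f"coupling {label}: strand {strand} selects no atoms"
                )
            coms.append(trajectory.coords[:, sel, :].mean(axis=1))
        out[label] = np.linalg.norm(coms[0] - coms[1], axis=1)
    return out


def encode_state(
    distances: dict[str, float], threshold: float = DEFAULT_THRESHOLD_NM
) -> str:
    """Encode coupling distances as a ``*BCDE`` code.

    A bit is 1 iff its distance strictly exceeds the threshold; boundary
    equality counts as connected.
    """
    bits = []
    for c in COUPLING_LABELS:
        if c not in distances:
            raise EncodingError(f"distance for coupling {c} missing")
        bits.append("1" if distances[c] > threshold else "0")
    return "*" + "".join(bits)


@dataclass
class StateSeries:
    """Per-probe state codes of one run."""

    probe_times: np.ndarray
    states: list[str]
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.probe_times = np.asarray(self.probe_times, dtype=float)
        if len(self.states) != self.probe_times.shape[0]:
            raise EncodingError("states and probe_times lengths differ")

    def __len__(self) -> int:
        return len(self.states)

    def distinct(self) -> list[str]:
        """States in order of first visit, consecutive duplicates collapsed."""
        out: list[str] = []
        for s in self.states:
            if not out or out[-1] != s:
                out.append(s)
        return out

    def first_break_times(self) -> dict[str, float]:
        """Per coupling, the first probe time its bit is 1 (inf if never)."""
        out: dict[str, float] = {}
        bits = np.array([[int(b) for b in s.lstrip("*")] for s in self.states])
        for j, c in enumerate(COUPLING_LABELS):
            broken = np.nonzero(bits[:, j])[0]
            out[c] = float(self.probe_times[broken[0]]) if broken.size else np.inf
        return out


def state_series(
    trajectory: Trajectory,
    topology: StrandTopology,
    dt_probe: float = DEFAULT_DT_PROBE_PS,
    threshold: float = DEFAULT_THRESHOLD_NM,
) -> StateSeries:
    """Probe a run every ``dt_probe`` ps and encode each probed frame.

    ``dt_probe`` must be an integer multiple of the trajectory frame spacing;
    states are taken from the frame at exactly the probe time, without
    interpolation.
    """
    dt = trajectory.dt
    if dt <= 0:
        raise SamplingError("trajectory has fewer than 2 frames")
    ratio = dt_probe / dt
    stride = round(ratio)
    if stride < 1 or abs(ratio - stride) > 1e-9 * max(1.0, ratio):
        raise SamplingError(
            f"dt_probe {dt_probe} ps is not an integer multiple of the "
            f"frame spacing {dt} ps"
        )
    idx = np.arange(0, trajectory.n_frames, stride)
    sub = Trajectory(
        times=trajectory.times[idx],
        coords=trajectory.coords[idx],
        elements=trajectory.elements,
        residue_index=trajectory.residue_index,
        run_id=trajectory.run_id,
    )
    distances = coupling_distance_series(sub, topology)
    bits = np.stack(
        [(distances[c] > threshold).astype(int) for c in COUPLING_LABELS], axis=1
    )
    codes = ["*" + "".join(str(b) for b in row) for row in bits]
    return StateSeries(probe_times=sub.times, states=codes, run_id=trajectory.run_id)


def ensemble_state_series(
    ensemble,
    topology: StrandTopology,
    dt_probe: float = DEFAULT_DT_PROBE_PS,
    threshold: float = DEFAULT_THRESHOLD_NM,
) -> list[StateSeries]:
    """State series for every run of an ensemble."""
    return [state_series(run, topology, dt_probe, threshold) for run in ensemble]


@dataclass
class TransitionMap:
    """16-state Markovian transition count map built from an ensemble.

    ``counts[i, j]`` is the number of consecutive probe pairs that went from
    state ``i`` to state ``j`` (the diagonal counts "remained in state");
    ``dwell`` is the total number of probes spent in each state; ``sinks``
    maps each final state to the number of runs terminating in it; sources
    are visited states with no incoming transition from a different state.
    """

    counts: np.ndarray
    dwell: np.ndarray
    sinks: Counter = field(default_factory=Counter)
    n_runs: int = 0
    states: tuple[str, ...] = ALL_STATES

    @property
    def sources(self) -> list[str]:
        incoming = self.counts.sum(axis=0) - np.diag(self.counts)
        visited = self.dwell > 0
        return [
            self.states[i]
            for i in range(len(self.states))
            if visited[i] and incoming[i] == 0
        ]

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())

    def probability_matrix(self) -> np.ndarray:
        """Row-normalized transition probabilities (rows of unvisited states
        are left as zeros)."""
        rowsum = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(rowsum > 0, self.counts / rowsum, 0.0)
        return probs

    def edges(self) -> list[tuple[str, str, int]]:
        """Observed off-diagonal transitions as (from, to, count)."""
        out = []
        for i, j in zip(*np.nonzero(self.counts)):
            if i != j:
                out.append((self.states[i], self.states[j], int(self.counts[i, j])))
        return out

    def direction_class(self) -> dict[tuple[str, str], str]:
        """Per observed edge: ``unfolding`` if the number of broken couplings
        increases, ``refolding`` if it decreases, ``mixed`` if the reverse
        edge is also observed (matching the two-way striped links of the
        transition diagrams)."""
        classes: dict[tuple[str, str], str] = {}
        for si, sj, _ in self.edges():
            i, j = state_index(si), state_index(sj)
            if self.counts[j, i] > 0:
                classes[(si, sj)] = "mixed"
            elif hamming_weight(sj) > hamming_weight(si):
                classes[(si, sj)] = "unfolding"
            elif hamming_weight(sj) < hamming_weight(si):
                classes[(si, sj)] = "refolding"
            else:
                classes[(si, sj)] = "mixed"
        return classes

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "counts": self.counts.tolist(),
            "dwell": self.dwell.tolist(),
            "sources": self.sources,
            "sinks": dict(self.sinks),
            "n_runs": self.n_runs,
            "direction_class": {
                f"{a}->{b}": c for (a, b), c in self.direction_class().items()
            },
        }

    def to_networkx(self):
        """Visited-state directed graph with dwell/count/direction attributes."""
        import networkx as nx

        g = nx.DiGraph()
        classes = self.direction_class()
        for i, s in enumerate(self.states):
            if self.dwell[i] > 0:
                g.add_node(
                    s, dwell=int(self.dwell[i]), sink=int(self.sinks.get(s, 0))
                )
        for a, b, c in self.edges():
            g.add_edge(a, b, count=c, direction=classes[(a, b)])
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path) -> None:
        """Minimal Graphviz DOT export: edge width ∝ count, color by
        direction class (green unfolding, blue refolding, dashed mixed)."""
        colors = {"unfolding": "green", "refolding": "blue", "mixed": "black"}
        classes = self.direction_class()
        max_count = max((c for _, _, c in self.edges()), default=1)
        lines = ["digraph transitions {"]
        for i, s in enumerate(self.states):
            if self.dwell[i] > 0:
                shape = "doublecircle" if self.sinks.get(s) else "circle"
                lines.append(
                    f'  "{s}" [shape={shape}, width={0.5 + self.dwell[i] / max(1, self.dwell.max()):.2f}];'
                )
        for a, b, c in self.edges():
            style = "dashed" if classes[(a, b)] == "mixed" else "solid"
            lines.append(
                f'  "{a}" -> "{b}" [penwidth={0.5 + 4 * c / max_count:.2f}, '
                f'color={colors[classes[(a, b)]]}, style={style}, label="{c}"];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_transition_map(series: list[StateSeries]) -> TransitionMap:
    """Count probe-to-probe transitions of an ensemble of state series."""
    if not series:
        raise AnalysisError("no state series given")
    n = len(ALL_STATES)
    counts = np.zeros((n, n), dtype=np.int64)
    dwell = np.zeros(n, dtype=np.int64)
    sinks: Counter = Counter()
    for s in series:
        idx = np.array([state_index(code) for code in s.states])
        np.add.at(dwell, idx, 1)
        if idx.size >= 2:
            flat = np.bincount(idx[:-1] * n + idx[1:], minlength=n * n)
            counts += flat.reshape(n, n)
        sinks[s.states[-1]] += 1
    return TransitionMap(counts=counts, dwell=dwell, sinks=sinks, n_runs=len(series))


@dataclass
class PathwayResult:
    """Dominant unfolding pathway of an ensemble.

    ``pathway`` is the modal complete break order (all four couplings broke)
    and ``frequency`` its fraction among complete runs; partial orders (runs
    where some coupling never broke) are tallied separately.
    """

    pathway: str | None
    frequency: float
    complete_orders: Counter
    partial_orders: Counter
    n_complete: int
    n_runs: int


def _break_order(first_breaks: dict[str, float]) -> tuple[str, bool]:
    broken = {c: t for c, t in first_breaks.items() if np.isfinite(t)}
    order = "".join(sorted(broken, key=lambda c: (broken[c], COUPLING_LABELS.index(c))))
    return order, len(broken) == len(COUPLING_LABELS)


def dominant_pathway(series: list[StateSeries]) -> PathwayResult:
    """Modal complete break order over an ensemble of state series."""
    if not series:
        raise AnalysisError("no state series given")
    complete: Counter = Counter()
    partial: Counter = Counter()
    for s in series:
        order, is_complete = _break_order(s.first_break_times())
        (complete if is_complete else partial)[order] += 1
    if not complete:
        return PathwayResult(None, 0.0, complete, partial, 0, len(series))
    pathway, count = complete.most_common(1)[0]
    n_complete = sum(complete.values())
    return PathwayResult(
        pathway, count / n_complete, complete, partial, n_complete, len(series)
    )


@dataclass
class BreakOrderResult:
    """Fraction of runs in which one coupling first breaks before another."""

    probability: float
    n_counted: int
    n_excluded: int
    n_ties: int
    pair: tuple[str, str]


def break_order_probability(
    series: list[StateSeries], pair: tuple[str, str] = ("B", "D")
) -> BreakOrderResult:
    """P(first break of ``pair[0]`` precedes first break of ``pair[1]``).

    Runs where either coupling never breaks are excluded (and counted in
    ``n_excluded``); simultaneous first breaks at the same probe are ties,
    counted as "not before" and reported in ``n_ties``.
    """
    a, b = pair
    n_before = n_counted = n_excluded = n_ties = 0
    for s in series:
        fb = s.first_break_times()
        if not (np.isfinite(fb[a]) and np.isfinite(fb[b])):
            n_excluded += 1
            continue
        n_counted += 1
        if fb[a] == fb[b]:
            n_ties += 1
        elif fb[a] < fb[b]:
            n_before += 1
    if n_counted == 0:
        raise AnalysisError(
            f"break-order probability of {a} before {b} is undefined: "
            "no run broke both couplings"
        )
    return BreakOrderResult(n_before / n_counted, n_counted, n_excluded, n_ties, pair)
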