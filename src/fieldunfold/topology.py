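"""Secondary-structure topology: strand residue ranges and β-sheet couplings.

A ubiquitin-like fold is described by five β-strands (Roman numerals I–V) and
one α-helix (label ``A``), each given as an inclusive 1-based residue range,
plus four couplings labelled B, C, D, E — the native β-sheet contacts between
strand pairs:

    B = (I, II),  C = (I, V),  D = (III, V),  E = (III, IV).

A coupling is "broken" when the centre-of-mass distance of its two strands
exceeds a threshold (0.7 nm by default, see :mod:`fieldunfold.pathways`).
The helix carries no coupling bit: its end-to-end distance fluctuates too fast
to give a clean binary criterion, so state codes cover B–E only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import TopologyError

COUPLING_LABELS = ("B", "C", "D", "E")

#: Coupling label -> ordered strand pair forming the native sheet contact.
DEFAULT_COUPLINGS: dict[str, tuple[str, str]] = {
    "B": ("I", "II"),
    "C": ("I", "V"),
    "D": ("III", "V"),
    "E": ("III", "IV"),
}

#: Published ubiquitin secondary-structure ranges (1-based, inclusive).
#: Strand IV is extended from 48–49 to 48–50 so its COM is not degenerate.
DEFAULT_STRAND_RANGES: dict[str, tuple[int, int]] = {
    "I": (2, 7),
    "II": (12, 16),
    "III": (41, 45),
    "IV": (48, 50),
    "V": (66, 71),
    "A": (23, 34),
}


@dataclass(frozen=True)
class StrandTopology:
    """Residue ranges of strands I–V and helix A plus the coupling pairs B–E.

    Parameters
    ----------
    strand_ranges
        Map from strand label to an inclusive 1-based ``(first, last)``
        residue range.  Ranges must be non-empty and mutually disjoint.
    couplings
        Map from coupling label (``B``–``E``) to the ordered pair of strand
        labels it connects.  All four couplings must be present and reference
        defined strands.
    n_residues
        Total chain length; defaults to 76 (ubiquitin).
    """

    strand_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STRAND_RANGES)
    )
    couplings: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    n_residues: int = 76

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, (lo, hi) in self.strand_ranges.items():
            if hi < lo:
                raise TopologyError(f"strand {label}: empty range {lo}–{hi}")
            if lo < 1 or hi > self.n_residues:
                raise TopologyError(
                    f"strand {label}: range {lo}–{hi} outside chain 1–{self.n_residues}"
                )
            residues = set(range(lo, hi + 1))
            if residues & seen:
                raise TopologyError(f"strand {label}: range {lo}–{hi} overlaps another strand")
            seen |= residues
        missing = [c for c in COUPLING_LABELS if c not in self.couplings]
        if missing:
            raise TopologyError(f"couplings missing: {missing}")
        for label, (a, b) in self.couplings.items():
            for strand in (a, b):
                if strand not in self.strand_ranges:
                    raise TopologyError(
                        f"coupling {label} references undefined strand {strand!r}"
                    )

    def strand_residues(self, strand: str) -> range:
        """1-based residue indices of one strand, as a ``range``."""
        lo, hi = self.strand_ranges[strand]
        return range(lo, hi + 1)

    @classmethod
    def from_dict(cls, cfg: dict) -> "StrandTopology":
        ranges = {k: (int(v[0]), int(v[1])) for k, v in cfg["strand_ranges"].items()}
        couplings = {
            k: (str(v[0]), str(v[1]))
            for k, v in cfg.get("couplings", DEFAULT_COUPLINGS).items()
        }
        return cls(
            strand_ranges=ranges,
            couplings=couplings,
            n_residues=int(cfg.get("n_residues", 76)),
        )

    @classmethod
    def from_yaml(cls, path) -> "StrandTopology":
        """Load a topology from a YAML file with ``strand_ranges``/``couplings`` keys."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_topology() -> StrandTopology:
    """The ubiquitin-like default: 76 residues, 5 strands, 1 helix, couplings B–E."""
    return StrandTopology()
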