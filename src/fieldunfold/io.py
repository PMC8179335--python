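"""Trajectory and ensemble I/O.

Formats
-------
* Multi-model PDB (``MODEL``/``ENDMDL`` records, coordinates in Å per the PDB
  convention, converted to the package-internal nm).  PDB carries no per-model
  time metadata, so frame times come from a supplied ``(t0, dt)``.
* Extended XYZ with a comment line of the form ``time=<ps> ps`` per frame and
  an optional fifth column holding the 1-based residue index.
* An ensemble is a directory of run files (ordered lexicographically for
  reproducibility) or a JSON manifest listing run files plus ``(t0, dt)``.

Binary MD formats (XTC/TRR/DCD) are out of scope; convert externally.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .errors import EnsembleError, FormatError
from .trajectory import EnsembleHandle, Trajectory

NM_PER_ANGSTROM = 0.1


def write_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates in Å)."""
    n_atoms = trajectory.n_atoms
    stack = struc.AtomArrayStack(trajectory.n_frames, n_atoms)
    stack.coord = trajectory.coords / NM_PER_ANGSTROM
    stack.set_annotation("chain_id", np.full(n_atoms, "A"))
    stack.set_annotation("res_id", trajectory.residue_index)
    stack.set_annotation("res_name", np.full(n_atoms, "GLY"))
    stack.set_annotation("atom_name", np.full(n_atoms, "CA"))
    stack.set_annotation(
        "element", np.array([e.upper() for e in trajectory.elements])
    )
    stack.set_annotation("hetero", np.zeros(n_atoms, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _validate_pdb_model_counts(path) -> None:
    """Pre-scan MODEL/ATOM records so an inconsistent model is named by index."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            record = line[:6].strip()
            if record == "MODEL":
                current = 0
            elif record in ("ATOM", "HETATM"):
                if current is None:  # implicit single model without MODEL records
                    current = 0
                current += 1
            elif record == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None:  # trailing model without ENDMDL
        counts.append(current)
    for i, c in enumerate(counts):
        if c != counts[0]:
            raise FormatError(
                f"inconsistent atom count in model {i + 1}: "
                f"{c} atoms, expected {counts[0]}"
            )


def read_pdb(path, t0: float = 0.0, dt: float = 0.05, run_id: str | None = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory` (coordinates in nm).

    PDB files carry no frame times, so the grid is ``t0 + k*dt`` (ps).
    """
    _validate_pdb_model_counts(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float) * NM_PER_ANGSTROM
    elements = [str(e).upper() for e in stack.element]
    times = t0 + dt * np.arange(coords.shape[0])
    return Trajectory(
        times=times,
        coords=coords,
        elements=elements,
        residue_index=np.asarray(stack.res_id, dtype=int),
        run_id=run_id or Path(path).stem,
    )


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write an extended XYZ file: Å coordinates, a ``time=`` comment per
    frame and the residue index as a fifth column."""
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"time={trajectory.times[f]:.6f} ps run_id={trajectory.run_id}\n")
            for a in range(trajectory.n_atoms):
                x, y, z = trajectory.coords[f, a] / NM_PER_ANGSTROM
                fh.write(
                    f"{trajectory.elements[a]:<2s} {x:15.6f} {y:15.6f} {z:15.6f} "
                    f"{trajectory.residue_index[a]:d}\n"
                )


_TIME_RE = re.compile(r"time=([-+0-9.eE]+)")
_RUN_RE = re.compile(r"run_id=(\S+)")


def read_xyz(path, t0: float = 0.0, dt: float = 0.05, run_id: str | None = None) -> Trajectory:
    """Read an (extended) XYZ file; frame times come from the ``time=``
    comment when present, else from ``(t0, dt)``."""
    frames: list[np.ndarray] = []
    times: list[float] = []
    elements: list[str] = []
    residx: list[int] = []
    file_run_id: str | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        model += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"model {model}: bad atom-count line {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else t0 + dt * (model - 1))
        r = _RUN_RE.search(comment)
        if r:
            file_run_id = r.group(1)
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"model {model}: truncated ({len(block)} of {n} atoms)")
        coords = np.empty((n, 3))
        frame_elements: list[str] = []
        frame_residx: list[int] = []
        for a, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"model {model}: bad atom line {line!r}")
            frame_elements.append(parts[0].upper())
            coords[a] = [float(v) for v in parts[1:4]]
            frame_residx.append(int(parts[4]) if len(parts) > 4 else a + 1)
        if model == 1:
            elements, residx = frame_elements, frame_residx
        elif frame_elements != elements:
            raise FormatError(f"model {model}: atom ordering differs from model 1")
        frames.append(coords * NM_PER_ANGSTROM)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    if any(len(f) != len(frames[0]) for f in frames):
        bad = next(k for k, f in enumerate(frames) if len(f) != len(frames[0]))
        raise FormatError(f"inconsistent atom count in model {bad + 1}")
    return Trajectory(
        times=np.array(times),
        coords=np.stack(frames),
        elements=elements,
        residue_index=np.array(residx),
        run_id=run_id or file_run_id or Path(path).stem,
    )


def read_trajectory(path, format: str | None = None, t0: float = 0.0, dt: float = 0.05) -> Trajectory:
    """Read one run; the format is inferred from the suffix unless given
    (``"pdb-multimodel"`` or ``"xyz"``)."""
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb-multimodel")
    if fmt in ("pdb", "pdb-multimodel"):
        return read_pdb(path, t0=t0, dt=dt)
    if fmt == "xyz":
        return read_xyz(path, t0=t0, dt=dt)
    raise FormatError(f"unknown trajectory format {fmt!r}")


def write_trajectory(trajectory: Trajectory, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb-multimodel")
    if fmt in ("pdb", "pdb-multimodel"):
        write_pdb(trajectory, path)
    elif fmt == "xyz":
        write_xyz(trajectory, path)
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")


def save_ensemble(ensemble: EnsembleHandle, directory, format: str = "pdb") -> Path:
    """Write every run plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".xyz" if format == "xyz" else ".pdb"
    files = []
    for run in ensemble.runs:
        fname = f"{run.run_id}{suffix}"
        write_trajectory(run, directory / fname, format=format)
        files.append(fname)
    manifest = {
        "runs": files,
        "t0": float(ensemble.times[0]),
        "dt": float(ensemble.runs[0].dt),
        "metadata": {
            k: v for k, v in ensemble.metadata.items() if isinstance(v, (str, int, float, list))
        },
    }
    manifest_path = directory / "ensemble.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_ensemble(path, t0: float = 0.0, dt: float = 0.05) -> EnsembleHandle:
    """Load an ensemble from a directory of run files or a JSON manifest.

    Run order is lexicographic by filename (manifest order if a manifest is
    given).  All runs must share the atom ordering and time grid; mismatches
    raise :class:`~fieldunfold.errors.EnsembleError`.
    """
    path = Path(path)
    metadata: dict = {}
    if path.is_dir():
        manifest = path / "ensemble.json"
        if manifest.exists():
            return load_ensemble(manifest)
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".pdb", ".xyz")
        )
        base = path
    elif path.suffix == ".json":
        spec = json.loads(path.read_text())
        base = path.parent
        files = [base / f for f in spec["runs"]]
        t0 = float(spec.get("t0", t0))
        dt = float(spec.get("dt", dt))
        metadata = spec.get("metadata", {})
    else:
        raise FormatError(f"{path}: expected a directory or a JSON manifest")
    if not files:
        raise EnsembleError(f"{path}: no trajectory files found (empty ensemble)")
    runs = [read_trajectory(f, t0=t0, dt=dt) for f in files]
    metadata.setdefault("source", str(path))
    return EnsembleHandle(runs=runs, metadata=metadata)
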