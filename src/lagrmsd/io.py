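"""Trajectory / matrix file input and tabular output.

Multi-model PDB files are handled through MDAnalysis.  The multi-frame XYZ
dialect is read and written here in full float64 precision (coordinates
printed with 17 significant digits) so that a write/read cycle is the
identity on every finite coordinate — a property the analysis pipeline's
determinism contract relies on.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trajectory import DEFAULT_LENGTH_UNIT, RMSDMatrix, Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_rmsd_matrix",
    "write_rmsd_matrix",
    "write_table",
    "read_table",
    "FormatError",
]


class FormatError(ValueError):
    """A file violates its declared format."""


_FORMATS = ("pdb-multimodel", "xyz", "auto")


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb-multimodel"
    if ext == ".xyz":
        return "xyz"
    raise FormatError(f"cannot infer trajectory format from extension {ext!r}")


# ---------------------------------------------------------------------------
# XYZ (multi-frame)
# ---------------------------------------------------------------------------

def _read_xyz(path: str):
    frames, labels = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, frame_idx = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"frame {frame_idx}: expected atom count, got {lines[pos]!r}"
            ) from exc
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise FormatError(f"frame {frame_idx}: truncated ({len(body)}/{n} atoms)")
        frame_labels, xyz = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"frame {frame_idx}: malformed atom line {ln!r}")
            frame_labels.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise FormatError(
                f"frame {frame_idx} has {len(frame_labels)} atoms, expected {len(labels)}"
            )
        frames.append(xyz)
        pos += 2 + n
        frame_idx += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return np.array(frames, dtype=float), np.array(labels)


def _write_xyz(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[k]:.17g} ps\n")
            for label, (x, y, z) in zip(traj.atom_labels, traj.coords[k]):
                fh.write(f"{label} {x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# multi-model PDB (via MDAnalysis)
# ---------------------------------------------------------------------------

def _check_pdb_models(path: str) -> None:
    """Verify every MODEL block has the same atom count; name the offender."""
    counts, current, in_model, saw_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model, saw_model, current = True, True, 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                if not saw_model:
                    in_model, saw_model = True, True  # implicit single model
                current += 1
    if in_model:  # missing ENDMDL before EOF is tolerated
        counts.append(current)
    for idx, c in enumerate(counts):
        if c != counts[0]:
            raise FormatError(
                f"frame {idx} has {c} atoms, expected {counts[0]} (from frame 0)"
            )


def _read_pdb(path: str):
    import MDAnalysis as mda

    _check_pdb_models(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        labels = np.asarray(u.atoms.names, dtype=str)
        coords = np.array([u.atoms.positions.astype(float) for _ in u.trajectory])
    return coords, labels


def _write_pdb(traj: Trajectory, path: str) -> None:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", [str(l) for l in traj.atom_labels])
        u.add_TopologyAttr("resnames", ["MOL"])
        u.add_TopologyAttr("resids", [1])
        with mda.Writer(path, traj.n_atoms, multiframe=True) as w:
            for k in range(traj.n_frames):
                u.atoms.positions = traj.coords[k]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str,
    format: str = "auto",
    selection: Iterable[str] | None = None,
    frame_spacing_ps: float | None = None,
    unit: str = DEFAULT_LENGTH_UNIT,
) -> Trajectory:
    """Read a multi-frame coordinate file into a :class:`Trajectory`.

    Neither PDB nor XYZ carries frame times, so ``frame_spacing_ps`` is
    required; times are synthesized as ``index * frame_spacing_ps``.
    ``selection`` filters atoms by label, applied identically to every frame.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if frame_spacing_ps is None:
        raise ValueError("frame_spacing_ps is required (PDB/XYZ carry no times)")
    if frame_spacing_ps <= 0:
        raise ValueError("frame_spacing_ps must be positive")
    if fmt == "xyz":
        coords, labels = _read_xyz(path)
    else:
        coords, labels = _read_pdb(path)
    times = np.arange(coords.shape[0]) * float(frame_spacing_ps)
    traj = Trajectory(coords=coords, times=times, atom_labels=labels, unit=unit)
    if selection is not None:
        traj = traj.select(selection)
    return traj


def write_trajectory(traj: Trajectory, path: str, format: str = "auto") -> None:
    """Write a trajectory as multi-frame XYZ or multi-model PDB."""
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "pdb-multimodel":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


def read_rmsd_matrix(
    path: str,
    frame_spacing_ps: float,
    unit: str = DEFAULT_LENGTH_UNIT,
) -> RMSDMatrix:
    """Read a whitespace- or comma-delimited square RMSD matrix.

    Asymmetries up to 1e-6 relative are symmetrized by averaging; anything
    larger is an error, as are negative entries and a nonzero diagonal.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    v = np.atleast_2d(np.loadtxt(path, delimiter=delimiter, dtype=float))
    if v.shape[0] != v.shape[1]:
        raise FormatError(f"matrix must be square, got shape {v.shape}")
    if np.any(v < 0):
        raise FormatError("matrix has negative entries")
    scale = max(float(np.max(np.abs(v))), 1.0)
    asym = np.max(np.abs(v - v.T))
    if asym > 1e-6 * scale:
        raise FormatError(f"matrix asymmetry {asym:g} exceeds 1e-6 relative")
    if np.any(np.abs(np.diagonal(v)) > 1e-9 * scale):
        raise FormatError("matrix diagonal is not zero")
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    times = np.arange(v.shape[0]) * float(frame_spacing_ps)
    return RMSDMatrix(values=v, times=times, unit=unit)


def write_rmsd_matrix(matrix: RMSDMatrix, path: str) -> None:
    np.savetxt(path, matrix.values, fmt="%.17g", delimiter="\t")


def write_table(
    records: Sequence[Mapping[str, object]],
    path: str,
    format: str = "tsv",
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write keyed numeric records with a deterministic column order.

    Columns are the sorted union of keys (or ``fieldnames`` if given);
    floats are printed with 17 significant digits so re-reading the file
    reproduces them exactly.
    """
    if fieldnames is None:
        keys: set[str] = set()
        for r in records:
            keys.update(r.keys())
        fieldnames = sorted(keys)
    else:
        fieldnames = list(fieldnames)

    def fmt_val(v):
        if isinstance(v, (bool, np.bool_)):
            return str(bool(v))
        if isinstance(v, (float, np.floating)):
            return f"{float(v):.17g}"
        return str(v)

    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(fieldnames) + "\n")
            for r in records:
                fh.write("\t".join(fmt_val(r.get(k, "")) for k in fieldnames) + "\n")
    elif format == "json":
        def default(v):
            if isinstance(v, (np.floating, np.integer, np.bool_)):
                return v.item()
            raise TypeError(type(v))

        with open(path, "w") as fh:
            json.dump(
                [{k: r.get(k) for k in fieldnames} for r in records],
                fh,
                indent=2,
                default=default,
            )
            fh.write("\n")
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_table(path: str, format: str = "tsv") -> list[dict]:
    """Inverse of :func:`write_table` (numbers parsed back to float/int/bool)."""
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0]:
        return []
    header = lines[0].split("\t")

    def parse(s: str):
        if s in ("True", "False"):
            return s == "True"
        try:
            f = float(s)
        except ValueError:
            return s
        if f.is_integer() and "." not in s and "e" not in s.lower():
            return int(s)
        return f

    return [dict(zip(header, map(parse, ln.split("\t")))) for ln in lines[1:] if ln]
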