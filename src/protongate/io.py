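"""Readers and writers for coordinate frames and tabular pipeline data.

Frame reading (multi-model PDB, GRO, XYZ) is delegated to MDAnalysis;
coordinates come back in Å (MDAnalysis converts GRO's nm natively) and
residue numbering is preserved from the source file (1-based in typical
PDB/GRO usage). Multi-model PDB writing goes through biotite; XYZ writing
is a plain text formatter.

Tables travel as CSV with a header row; each generator writes a JSON
sidecar (``<stem>.meta.json``) holding the scenario configuration and the
ground truth, kept out of the data columns so fitting code cannot see it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import Frame

__all__ = [
    "read_frames",
    "write_frames_pdb",
    "write_frames_xyz",
    "write_table",
    "read_table",
]

_FORMATS = {"pdb", "gro", "xyz"}


def _frames_from_universe(u, fmt: str) -> list[Frame]:
    atoms = u.atoms
    names = atoms.names.astype(object)
    try:
        resnames = atoms.resnames.astype(object)
    except Exception:
        resnames = np.array(["UNK"] * len(atoms), dtype=object)
    try:
        resids = atoms.resids.astype(int)
    except Exception:
        resids = np.arange(1, len(atoms) + 1)
    try:
        subunits = atoms.chainIDs.astype(object)
    except Exception:
        try:
            subunits = atoms.segids.astype(object)
        except Exception:
            subunits = np.array([""] * len(atoms), dtype=object)
    try:
        elements = atoms.elements.astype(object)
    except Exception:
        elements = None

    frames: list[Frame] = []
    for i, ts in enumerate(u.trajectory):
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            alpha, beta, gamma = ts.dimensions[3:6]
            if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
                raise ValueError(
                    "triclinic boxes are not supported; only orthorhombic "
                    f"(got angles {alpha:.2f}, {beta:.2f}, {gamma:.2f})"
                )
            box = np.array(ts.dimensions[:3], dtype=float)
        frames.append(
            Frame(
                names=names.copy(),
                resnames=resnames.copy(),
                resids=resids.copy(),
                subunits=subunits.copy(),
                elements=None if elements is None else elements.copy(),
                positions=ts.positions.astype(float).copy(),
                box=box,
                index=i,
                metadata={"source_format": fmt},
            )
        )
    return frames


def read_frames(path: str | Path, format: str | None = None) -> list[Frame]:
    """Read a trajectory file into a list of :class:`Frame`, in file order.

    Parameters
    ----------
    path:
        A multi-model PDB, GRO or XYZ file.
    format:
        Optional format hint overriding the file extension.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(
            f"unknown trajectory format {fmt!r} for {path}; "
            f"supported: {sorted(_FORMATS)} (pass format= to override)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt, topology_format=fmt)
    return _frames_from_universe(u, fmt)


def write_frames_pdb(frames: Sequence[Frame], path: str | Path) -> Path:
    """Write frames as a multi-model PDB (coordinates to 3 decimals)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if not frames:
        raise ValueError("no frames to write")
    path = Path(path)
    n = frames[0].n_atoms
    arrays = []
    for fr in frames:
        if fr.n_atoms != n:
            raise ValueError("all frames must share one atom table for PDB output")
        arr = struc.AtomArray(n)
        arr.coord = fr.positions.astype(np.float32)
        arr.atom_name = fr.names.astype("U6")
        arr.res_name = fr.resnames.astype("U5")
        arr.res_id = fr.resids
        arr.chain_id = np.array([str(s)[:4] or "A" for s in fr.subunits], dtype="U4")
        arr.element = fr.elements.astype("U2")
        arr.hetero = np.array(
            [str(rn).upper() in {"HOH", "SOL", "TIP3", "WAT"} for rn in fr.resnames]
        )
        if fr.box is not None:
            arr.box = np.diag(fr.box).astype(np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    return path


def write_frames_xyz(frames: Sequence[Frame], path: str | Path) -> Path:
    """Write frames as a concatenated-XYZ trajectory (element + coordinates)."""
    if not frames:
        raise ValueError("no frames to write")
    path = Path(path)
    lines: list[str] = []
    for fr in frames:
        lines.append(str(fr.n_atoms))
        lines.append(f"frame {fr.index}")
        for el, pos in zip(fr.elements, fr.positions):
            lines.append(f"{el or 'X':<3s} {pos[0]:14.6f} {pos[1]:14.6f} {pos[2]:14.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_table(
    df: pd.DataFrame, path: str | Path, sidecar: dict | None = None
) -> Path:
    """Write a CSV table; optionally a ``<stem>.meta.json`` sidecar next to it."""
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar is not None:
        meta_path = path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(sidecar, indent=2, default=_json_default))
    return path


def read_table(path: str | Path, with_sidecar: bool = False):
    """Read a CSV table; with ``with_sidecar`` also load ``<stem>.meta.json``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    if not with_sidecar:
        return df
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    return df, meta


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
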