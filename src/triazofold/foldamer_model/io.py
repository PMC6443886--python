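"""Multi-model PDB and XYZ trajectory readers/writers.

PDB output follows v3.3 fixed columns: chain A, residue numbering equal to
the topology position index, triazole ring atoms as HETATM under residue
name ``TZ4``.  The XYZ flavour is plain ``element x y z`` with the frame
index and provenance on the comment line.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

from .topology import Conformation, FoldamerTopology

__all__ = [
    "write_pdb",
    "read_pdb_frames",
    "write_xyz",
    "read_xyz_frames",
]

_PDB_NAMES = {
    "N": "N", "H_N": "H", "CA": "CA", "H_A": "HA", "C_O": "C", "O": "O",
    "CB": "CB", "SC_centroid": "CEN",
    "ring_N1": "N1", "ring_N2": "N2", "ring_N3": "N3",
    "ring_C4": "C4", "ring_C5": "C5", "ring_H5": "H5",
    "cap_C": "CP", "cap_O": "OP", "cap_OE": "OE", "cap_centroid": "CEN",
}
_ROLE_BY_NAME: dict[tuple[str, str], str] = {}
for role, name in _PDB_NAMES.items():
    _ROLE_BY_NAME.setdefault(name, role)

_RESNAMES = {
    "Boc": "BOC", "Bus": "BUS", "OAll": "OAL", "OBzl": "OBZ", "OH": "OXH",
    "TZ4": "TZ4",
}


def _resname(res_name: str) -> str:
    return _RESNAMES.get(res_name, res_name.upper()[:3])


def _atom_line(rec: str, serial: int, name: str, resname: str, resseq: int,
               xyz: np.ndarray, element: str) -> str:
    nm = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{rec:<6}{serial:>5} {nm}{'':1}{resname:>3} A{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2}\n"
    )


def write_pdb(path, topology: FoldamerTopology,
              frames: Iterable[np.ndarray | Conformation],
              remarks: Iterable[str] = ()) -> None:
    """Write one or more frames as a multi-MODEL PDB file."""
    frames = list(frames)
    with open(path, "w") as fh:
        for r in remarks:
            fh.write(f"REMARK   1 {r}\n")
        multi = len(frames) > 1
        for mi, frame in enumerate(frames, start=1):
            coords = frame.coords if isinstance(frame, Conformation) else np.asarray(frame)
            if multi:
                fh.write(f"MODEL {mi:>8}\n")
            for serial, atom in enumerate(topology.atoms, start=1):
                rec = "HETATM" if atom.res_name in _RESNAMES else "ATOM"
                fh.write(_atom_line(
                    rec, serial, _PDB_NAMES[atom.role], _resname(atom.res_name),
                    atom.position_index, coords[serial - 1], atom.element,
                ))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_frames(path, topology: FoldamerTopology) -> list[np.ndarray]:
    """Read coordinate frames from a (multi-MODEL) PDB onto a topology.

    Atoms are matched by residue number + atom name, so column order in the
    file does not matter; a missing atom raises ``ValueError``.
    """
    frames: list[np.ndarray] = []
    current: dict[str, np.ndarray] = {}

    def flush():
        if not current:
            return
        coords = np.empty((topology.n_atoms, 3))
        for atom in topology.atoms:
            if atom.atom_id not in current:
                raise ValueError(f"PDB model missing atom {atom.atom_id}")
            coords[topology.atom_index(atom.atom_id)] = current[atom.atom_id]
        frames.append(coords)
        current.clear()

    # CEN appears for both SC_centroid and cap_centroid: disambiguate by
    # which id exists at that residue number
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                name = line[12:16].strip()
                resseq = int(line[22:26])
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                role = _ROLE_BY_NAME.get(name)
                if role is None:
                    continue
                aid = f"{resseq}:{role}"
                if aid not in topology._index and name == "CEN":
                    aid = f"{resseq}:cap_centroid"
                current[aid] = xyz
            elif rec == "ENDMDL":
                flush()
    flush()
    if not frames:
        raise ValueError(f"no coordinate frames found in {os.fspath(path)!r}")
    return frames


def write_xyz(path, topology: FoldamerTopology,
              frames: Iterable[np.ndarray | Conformation],
              provenance: str = "") -> None:
    """Write frames in XYZ trajectory format."""
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            coords = frame.coords if isinstance(frame, Conformation) else np.asarray(frame)
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {fi} {provenance}\n".rstrip() + "\n")
            for atom, xyz in zip(topology.atoms, coords):
                fh.write(
                    f"{atom.element:<2} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n"
                )


def read_xyz_frames(path) -> tuple[list[np.ndarray], list[str]]:
    """Read an XYZ trajectory; returns (frames, comment lines)."""
    frames, comments = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comments.append(lines[i + 1])
        block = lines[i + 2 : i + 2 + n]
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords)
        i += 2 + n
    return frames, comments
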