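"""Foldamer topology: atoms, bonds, torsion bookkeeping, conformations.

Atoms are coarse-grained: full backbone (N, H_N, CA, H_A, C_O, O and the
five triazole ring atoms plus ring H5), side chains as Cβ + one centroid
pseudo-atom, and cap atoms for acyl N-caps / ester C-caps.  Atom ids are
``"<position>:<role>"`` strings; each role occurs at most once per
position, so ids are unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import ResidueSpec, parse_residues

__all__ = [
    "Atom",
    "FoldamerTopology",
    "TorsionState",
    "Conformation",
    "parse_sequence",
    "DEFAULT_BACKBONE_ROLES",
    "DEFAULT_RING_ROLES",
]

# default backbone selection used for RMSD/ROG/clustering; ring C4/C5 can
# be added via FoldamerTopology.backbone_atoms(include_ring_c=True)
DEFAULT_BACKBONE_ROLES = ("N", "CA", "C_O")
DEFAULT_RING_ROLES = ("ring_N1", "ring_N2", "ring_N3")

_ELEMENTS = {
    "N": "N", "H_N": "H", "CA": "C", "H_A": "H", "C_O": "C", "O": "O",
    "CB": "C", "SC_centroid": "C",
    "ring_N1": "N", "ring_N2": "N", "ring_N3": "N",
    "ring_C4": "C", "ring_C5": "C", "ring_H5": "H",
    "cap_C": "C", "cap_O": "O", "cap_OE": "O", "cap_centroid": "C",
}

# atomic masses; centroid pseudo-atoms carry the summed heavy-atom mass of
# the side-chain portion they replace (beyond CB)
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
_CENTROID_MASS = {
    "Ala": 3.0,  # methyl hydrogens, nominal
    "Val": 24.0, "Leu": 36.0, "Ile": 36.0, "Phe": 76.0, "Tyr": 92.0,
    "Trp": 115.0, "Met": 60.0, "Cys": 32.0, "Ser": 16.0, "Thr": 28.0,
    "Asn": 42.0, "Gln": 54.0, "Asp": 44.0, "Glu": 56.0, "Lys": 56.0,
    "Arg": 84.0, "His": 65.0, "Pro": 28.0,
}


@dataclass(frozen=True)
class Atom:
    atom_id: str
    element: str
    role: str
    position_index: int
    res_name: str  # residue/cap/ring label, e.g. "Ala", "TZ4", "Boc"


class FoldamerTopology:
    """Molecular topology of one peptidotriazolamer chain."""

    def __init__(
        self,
        residues: list[ResidueSpec],
        n_triazoles: int,
        n_cap: str = "none",
        c_cap: str = "none",
    ):
        self.residues = list(residues)
        self.n_triazoles = n_triazoles
        self.n_cap = n_cap
        self.c_cap = c_cap
        self.atoms: list[Atom] = []
        self.bonds: list[tuple[str, str]] = []
        self._index: dict[str, int] = {}
        self._build_atoms()
        self.backbone_selection = self.backbone_atoms()
        self._validate()

    # -- construction -------------------------------------------------

    def _add_atom(self, pos: int, role: str, res_name: str) -> str:
        atom_id = f"{pos}:{role}"
        if atom_id in self._index:
            raise ValueError(f"duplicate atom id {atom_id}")
        self._index[atom_id] = len(self.atoms)
        self.atoms.append(Atom(atom_id, _ELEMENTS[role], role, pos, res_name))
        return atom_id

    def _bond(self, a: str, b: str) -> None:
        self.bonds.append((a, b))

    def _build_atoms(self) -> None:
        res = self.residues
        if not res:
            raise ValueError("topology needs at least one residue")
        acyl = self.n_cap in ("Boc", "Bus")
        if acyl:
            cap = self.n_cap
            self._add_atom(0, "cap_C", cap)
            self._add_atom(0, "cap_O", cap)
            self._add_atom(0, "cap_centroid", cap)
            self._bond("0:cap_C", "0:cap_O")
            self._bond("0:cap_C", "0:cap_centroid")

        prev_link: str | None = "0:cap_C" if acyl else None
        for i, r in enumerate(res):
            p = r.position_index
            if r.kind in ("amide", "tz4n"):
                n_id = self._add_atom(p, "N", r.name)
                if prev_link is not None:
                    self._bond(prev_link, n_id)
                self._add_atom(p, "H_N", r.name)
                self._bond(n_id, f"{p}:H_N")
                ca_anchor = n_id
            else:  # tz4c: CA bonds to the preceding ring's N1
                ca_anchor = prev_link  # ring_N1 id, set below
            ca_id = self._add_atom(p, "CA", r.name)
            if ca_anchor is not None:
                self._bond(ca_anchor, ca_id)
            self._add_atom(p, "H_A", r.name)
            self._bond(ca_id, f"{p}:H_A")
            if r.side_chain != "none":
                cb_id = self._add_atom(p, "CB", r.name)
                self._bond(ca_id, cb_id)
                cen_id = self._add_atom(p, "SC_centroid", r.name)
                self._bond(cb_id, cen_id)

            if r.kind == "tz4n":
                ring_pos = p + 1
                c4 = self._add_atom(ring_pos, "ring_C4", "TZ4")
                c5 = self._add_atom(ring_pos, "ring_C5", "TZ4")
                n1 = self._add_atom(ring_pos, "ring_N1", "TZ4")
                n2 = self._add_atom(ring_pos, "ring_N2", "TZ4")
                n3 = self._add_atom(ring_pos, "ring_N3", "TZ4")
                h5 = self._add_atom(ring_pos, "ring_H5", "TZ4")
                self._bond(ca_id, c4)
                self._bond(n1, n2)
                self._bond(n2, n3)
                self._bond(n3, c4)
                self._bond(c4, c5)
                self._bond(c5, n1)
                self._bond(c5, h5)
                prev_link = n1
            else:
                c_id = self._add_atom(p, "C_O", r.name)
                self._bond(ca_id, c_id)
                o_id = self._add_atom(p, "O", r.name)
                self._bond(c_id, o_id)
                prev_link = c_id

        last = res[-1]
        if last.kind == "tz4n":
            raise ValueError("chain cannot end on a tz4n residue (dangling ring)")
        if self.c_cap != "none":
            cap_pos = max(a.position_index for a in self.atoms) + 1
            oe = self._add_atom(cap_pos, "cap_OE", self.c_cap)
            self._bond(prev_link, oe)
            if self.c_cap in ("OAll", "OBzl"):
                cen = self._add_atom(cap_pos, "cap_centroid", self.c_cap)
                self._bond(oe, cen)

    def _validate(self) -> None:
        # bond graph connectivity via union-find
        parent = {a.atom_id: a.atom_id for a in self.atoms}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.bonds:
            parent[find(a)] = find(b)
        roots = {find(a.atom_id) for a in self.atoms}
        if len(roots) != 1:
            raise ValueError("bond graph is not connected")

    # -- lookups -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, atom_id: str) -> int:
        try:
            return self._index[atom_id]
        except KeyError:
            raise LookupError(f"no atom {atom_id!r} in topology") from None

    def has_atom(self, pos: int, role: str) -> bool:
        return f"{pos}:{role}" in self._index

    def atom_id(self, pos: int, role: str) -> str:
        aid = f"{pos}:{role}"
        if aid not in self._index:
            raise LookupError(f"no atom with position {pos} and role {role!r}")
        return aid

    def residue_at(self, pos: int) -> ResidueSpec:
        for r in self.residues:
            if r.position_index == pos:
                return r
        raise LookupError(f"no residue at position {pos}")

    @property
    def ring_positions(self) -> list[int]:
        return sorted({a.position_index for a in self.atoms if a.res_name == "TZ4"})

    def backbone_atoms(
        self,
        roles: tuple[str, ...] = DEFAULT_BACKBONE_ROLES,
        ring_roles: tuple[str, ...] = DEFAULT_RING_ROLES,
        include_ring_c: bool = False,
    ) -> list[str]:
        """Ordered backbone atom ids used for RMSD/ROG/clustering.

        Defaults to N, CA, C_O per residue plus ring N1, N2, N3 per
        triazole; ``include_ring_c`` adds ring C4 and C5.
        """
        if include_ring_c:
            ring_roles = tuple(ring_roles) + ("ring_C4", "ring_C5")
        sel = []
        for a in self.atoms:
            if a.res_name == "TZ4":
                if a.role in ring_roles:
                    sel.append(a.atom_id)
            elif a.role in roles:
                sel.append(a.atom_id)
        return sel

    def selection_indices(self, atom_ids: list[str] | None = None) -> np.ndarray:
        ids = self.backbone_selection if atom_ids is None else atom_ids
        return np.array([self.atom_index(a) for a in ids], dtype=int)

    def masses(self) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, a in enumerate(self.atoms):
            if a.role == "SC_centroid":
                out[i] = _CENTROID_MASS.get(a.res_name, 30.0)
            elif a.role == "cap_centroid":
                out[i] = 57.0  # tert-butyl / allyl-ish lump
            else:
                out[i] = _MASSES[a.element]
        return out

    def __repr__(self) -> str:
        return (
            f"FoldamerTopology({len(self.residues)} residues, "
            f"{self.n_triazoles} triazoles, caps {self.n_cap}/{self.c_cap}, "
            f"{self.n_atoms} atoms)"
        )


def parse_sequence(text: str) -> FoldamerTopology:
    """Parse sequence notation into a :class:`FoldamerTopology`."""
    residues, n_tz, n_cap, c_cap = parse_residues(text)
    return FoldamerTopology(residues, n_tz, n_cap, c_cap)


@dataclass
class TorsionState:
    """Backbone (ϕ, ψ) pairs, one per residue, in degrees on (-180, 180]."""

    entries: list[tuple[int, float, float]]  # (position_index, phi, psi)
    convention: str = "through-ring-v1"

    def __post_init__(self):
        for pos, phi, psi in self.entries:
            for v in (phi, psi):
                if np.isfinite(v) and not (-180.0 < v <= 180.0 + 1e-9):
                    raise ValueError(
                        f"torsion {v} at position {pos} outside (-180, 180]"
                    )

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {pos: (phi, psi) for pos, phi, psi in self.entries}

    @classmethod
    def uniform(cls, topology: FoldamerTopology, phi: float, psi: float):
        return cls([(r.position_index, phi, psi) for r in topology.residues])

    def to_vector(self, topology: FoldamerTopology) -> np.ndarray:
        """Flat [phi_0, psi_0, phi_1, psi_1, ...] in residue order."""
        d = self.as_dict()
        vec = np.empty(2 * len(topology.residues))
        for i, r in enumerate(topology.residues):
            if r.position_index not in d:
                raise ValueError(f"missing torsion entry for position {r.position_index}")
            vec[2 * i], vec[2 * i + 1] = d[r.position_index]
        return vec

    @classmethod
    def from_vector(cls, topology: FoldamerTopology, vec: np.ndarray):
        entries = [
            (r.position_index, float(vec[2 * i]), float(vec[2 * i + 1]))
            for i, r in enumerate(topology.residues)
        ]
        return cls(entries)


@dataclass
class Conformation:
    """Cartesian coordinates (Å) for every atom of a topology."""

    topology: FoldamerTopology
    coords: np.ndarray  # (n_atoms, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def coord(self, atom_id: str) -> np.ndarray:
        return self.coords[self.topology.atom_index(atom_id)]

    def distance(self, atom_a: str, atom_b: str) -> float:
        return float(np.linalg.norm(self.coord(atom_a) - self.coord(atom_b)))
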