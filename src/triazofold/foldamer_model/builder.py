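"""Internal-coordinate conformer builder and torsion measurement.

Coordinates are constructed sequentially (NeRF) from a fixed ideal-geometry
table; only the backbone ϕ/ψ torsions are free.  Amide ω is fixed at 180°
(trans) and every triazole is a rigid planar regular pentagon, so all bond
lengths and bond angles of a built conformer equal the table entries
exactly.

Torsion atom quadruples (package convention, through-ring backbone path
N1-C5-C4):

* amide residue:  ϕ = C_O(prev)-N-CA-C_O,     ψ = N-CA-C_O-N(next)
* tz4n residue:   ϕ = C_O(prev)-N-CA-ring_C4, ψ = N-CA-ring_C4-ring_C5
* tz4c residue:   ϕ = ring_C5-ring_N1-CA-C_O, ψ = ring_N1-CA-C_O-N(next)

For residue 1 the ϕ A-slot is the acyl cap carbonyl carbon (undefined and
reported as NaN for a free amine); for the C-terminal residue the ψ D-slot
is the ester oxygen of the C-cap, falling back to the carbonyl O shifted
by 180° when the chain is uncapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..geometry import dihedral, place_atom, wrap_angle
from .topology import Conformation, FoldamerTopology, TorsionState

__all__ = [
    "GEOM",
    "Program",
    "compile_program",
    "execute_program",
    "build_conformation",
    "measure_torsions",
    "measure_chirality",
]

# ideal-geometry table (Å, degrees); single editable source of truth
GEOM = {
    "b_C_N": 1.33,       # amide / carbamate C-N
    "b_N_CA": 1.46,
    "b_CA_C": 1.52,
    "b_C_O": 1.23,       # carbonyl C=O
    "b_CA_C4": 1.50,     # CA to triazole ring C4
    "b_N1_CA": 1.46,     # ring N1 to CA of the following residue
    "b_ring": 1.35,      # all five ring bonds
    "b_N_H": 1.01,
    "b_CA_H": 1.09,
    "b_CA_CB": 1.53,
    "b_C5_H5": 1.08,
    "b_C_OE": 1.34,      # ester C-O
    "b_OE_cen": 1.90,
    "b_capC_cen": 1.95,
    "a_CA_C_N": 116.0,
    "a_C_N_CA": 122.0,
    "a_N_CA_C": 111.0,
    "a_CA_C_O": 121.0,
    "a_N_CA_C4": 110.0,
    "a_CA_C4_C5": 126.0,
    "a_ring": 108.0,     # interior pentagon angle
    "a_C5_N1_CA": 126.0,
    "a_C_N_H": 119.5,
    "a_N_CA_CB": 110.5,
    "a_N_CA_HA": 108.5,
    "a_CA_CB_cen": 114.0,
    "a_C4_C5_H5": 126.0,
    "a_CA_C_OE": 114.0,
    "a_C_OE_cen": 117.0,
    "a_N_capC_O": 123.0,
    "a_N_capC_cen": 112.0,
    "a_capC_N_CA": 122.0,
    "omega": 180.0,      # trans amide
    "chi_CB_L": -122.0,  # improper dihedral(C_O|C4, N|N1, CA, CB) for L
    "chi_HA_L": 119.0,
}

# centroid pseudo-atom distance from CB, per residue (coarse side-chain extent)
CENTROID_BOND = {
    "Ala": 0.8, "Val": 1.2, "Leu": 1.9, "Ile": 1.9, "Phe": 2.4,
    "Tyr": 2.8, "Trp": 2.9, "Met": 2.3, "Cys": 1.4, "Ser": 1.2,
    "Thr": 1.3, "Asn": 1.7, "Gln": 2.2, "Asp": 1.7, "Glu": 2.2,
    "Lys": 2.7, "Arg": 3.0, "His": 2.2, "Pro": 1.4,
}


@dataclass
class Program:
    """Compiled placement program for one topology.

    Seed atoms ``seed_idx`` are placed analytically; every other atom is a
    NeRF step.  ``tor_idx`` indexes the flat torsion vector
    ``[phi_0, psi_0, phi_1, ...]`` (-1 for a fixed torsion); the effective
    torsion is ``tvec[tor_idx] + tor_base``.
    """

    topology: FoldamerTopology
    seed_idx: np.ndarray      # (3,) atom indices
    seed_bond01: float
    seed_bond12: float
    seed_angle: float         # angle seed0-seed1-seed2
    atom: np.ndarray          # (n_steps,)
    ref_a: np.ndarray
    ref_b: np.ndarray
    ref_c: np.ndarray
    bond: np.ndarray
    angle: np.ndarray
    tor_base: np.ndarray
    tor_idx: np.ndarray

    @property
    def n_torsions(self) -> int:
        return 2 * len(self.topology.residues)


_PROGRAM_CACHE: dict[int, Program] = {}


def compile_program(topology: FoldamerTopology) -> Program:
    """Compile (and cache) the placement program for a topology."""
    cached = _PROGRAM_CACHE.get(id(topology))
    if cached is not None and cached.topology is topology:
        return cached

    g = GEOM
    idx = topology.atom_index
    res = topology.residues
    acyl = topology.n_cap in ("Boc", "Bus")

    steps: list[tuple] = []  # (atom, ra, rb, rc, bond, angle, tbase, tidx)

    def add(atom_id, ra, rb, rc, bond, angle, tbase, tidx=-1):
        steps.append((idx(atom_id), idx(ra), idx(rb), idx(rc),
                      bond, angle, tbase, tidx))

    pos0 = res[0].position_index
    if acyl:
        seed_idx = np.array([idx("0:cap_C"), idx(f"{pos0}:N"), idx(f"{pos0}:CA")])
        seed = (g["b_C_N"], g["b_N_CA"], g["a_capC_N_CA"])
    else:
        first_c = (
            f"{res[0].position_index + 1}:ring_C4"
            if res[0].kind == "tz4n"
            else f"{pos0}:C_O"
        )
        seed_idx = np.array([idx(f"{pos0}:N"), idx(f"{pos0}:CA"), idx(first_c)])
        seed = (
            g["b_N_CA"],
            g["b_CA_C4"] if res[0].kind == "tz4n" else g["b_CA_C"],
            g["a_N_CA_C4"] if res[0].kind == "tz4n" else g["a_N_CA_C"],
        )

    prev = {"anchor_N": None, "CA": None, "C": None, "O": None}
    for i, r in enumerate(res):
        p = r.position_index
        phi_t, psi_t = 2 * i, 2 * i + 1
        if r.kind in ("amide", "tz4n"):
            n_id, ca_id = f"{p}:N", f"{p}:CA"
            if i == 0:
                if acyl:
                    add("0:cap_O", ca_id, n_id, "0:cap_C",
                        g["b_C_O"], g["a_N_capC_O"], 180.0)
                    add("0:cap_centroid", ca_id, n_id, "0:cap_C",
                        g["b_capC_cen"], g["a_N_capC_cen"], 0.0)
                    add(f"{p}:H_N", "0:cap_O", "0:cap_C", n_id,
                        g["b_N_H"], g["a_C_N_H"], 180.0)
                    prev_c_for_phi = "0:cap_C"
                else:
                    prev_c_for_phi = None  # ϕ(1) undefined; H_N placed below
            else:
                add(n_id, prev["anchor_N"], prev["CA"], prev["C"],
                    g["b_C_N"], g["a_CA_C_N"], 0.0, psi_t - 2)
                add(f"{p}:H_N", prev["O"], prev["C"], n_id,
                    g["b_N_H"], g["a_C_N_H"], 180.0)
                add(ca_id, prev["CA"], prev["C"], n_id,
                    g["b_N_CA"], g["a_C_N_CA"], g["omega"])
                prev_c_for_phi = prev["C"]
            anchor_n = n_id
        else:  # tz4c
            ring = r.position_index - 1
            c4, c5, n1 = (f"{ring}:ring_C4", f"{ring}:ring_C5", f"{ring}:ring_N1")
            ca_id = f"{p}:CA"
            add(ca_id, c4, c5, n1, g["b_N1_CA"], g["a_C5_N1_CA"], 180.0)
            anchor_n = n1
            prev_c_for_phi = c5

        if r.kind == "tz4n":
            ring = p + 1
            c4, c5 = f"{ring}:ring_C4", f"{ring}:ring_C5"
            n1, n2, n3 = (f"{ring}:ring_N1", f"{ring}:ring_N2", f"{ring}:ring_N3")
            if not (i == 0 and not acyl):
                add(c4, prev_c_for_phi, anchor_n, ca_id,
                    g["b_CA_C4"], g["a_N_CA_C4"], 0.0, phi_t)
            add(c5, anchor_n, ca_id, c4,
                g["b_ring"], g["a_CA_C4_C5"], 0.0, psi_t)
            add(n1, ca_id, c4, c5, g["b_ring"], g["a_ring"], 180.0)
            add(n2, c4, c5, n1, g["b_ring"], g["a_ring"], 0.0)
            add(n3, c5, n1, n2, g["b_ring"], g["a_ring"], 0.0)
            add(f"{ring}:ring_H5", ca_id, c4, c5,
                g["b_C5_H5"], g["a_C4_C5_H5"], 0.0)
            other = c4
            chain_c, chain_o = None, None
            next_anchor = n1
        else:
            c_id, o_id = f"{p}:C_O", f"{p}:O"
            if not (i == 0 and not acyl):
                add(c_id, prev_c_for_phi, anchor_n, ca_id,
                    g["b_CA_C"], g["a_N_CA_C"], 0.0, phi_t)
            add(o_id, anchor_n, ca_id, c_id,
                g["b_C_O"], g["a_CA_C_O"], 180.0, psi_t)
            other = c_id
            chain_c, chain_o = c_id, o_id
            next_anchor = anchor_n

        if i == 0 and not acyl and r.kind in ("amide", "tz4n"):
            add(f"{p}:H_N", other, ca_id, n_id,
                g["b_N_H"], g["a_C_N_H"], 180.0)

        sign = -1.0 if r.chirality == "D" else 1.0
        # Gly's H_A goes in-plane so mirroring torsions mirrors the build
        ha_base = 180.0 if r.chirality == "achiral" else sign * g["chi_HA_L"]
        add(f"{p}:H_A", other, anchor_n, ca_id,
            g["b_CA_H"], g["a_N_CA_HA"], ha_base)
        if r.side_chain != "none":
            add(f"{p}:CB", other, anchor_n, ca_id,
                g["b_CA_CB"], g["a_N_CA_CB"], sign * g["chi_CB_L"])
            add(f"{p}:SC_centroid", anchor_n, ca_id, f"{p}:CB",
                CENTROID_BOND.get(r.name, 1.8), g["a_CA_CB_cen"], 180.0)

        prev = {"anchor_N": anchor_n if r.kind != "tz4n" else next_anchor,
                "CA": ca_id, "C": chain_c, "O": chain_o}
        if r.kind == "tz4n":
            prev["anchor_N"] = anchor_n  # ψ refs use this residue's N
            # the following tz4c residue reads ring atoms directly

    if topology.c_cap != "none":
        last = res[-1]
        p = last.position_index
        cap_pos = max(a.position_index for a in topology.atoms)
        anchor = f"{p - 1}:ring_N1" if last.kind == "tz4c" else f"{p}:N"
        add(f"{cap_pos}:cap_OE", anchor, f"{p}:CA", f"{p}:C_O",
            g["b_C_OE"], g["a_CA_C_OE"], 0.0, 2 * (len(res) - 1) + 1)
        if topology.c_cap in ("OAll", "OBzl"):
            add(f"{cap_pos}:cap_centroid", f"{p}:CA", f"{p}:C_O",
                f"{cap_pos}:cap_OE", g["b_OE_cen"], g["a_C_OE_cen"], 180.0)

    arr = np.array(steps, dtype=float)
    prog = Program(
        topology=topology,
        seed_idx=seed_idx,
        seed_bond01=seed[0],
        seed_bond12=seed[1],
        seed_angle=seed[2],
        atom=arr[:, 0].astype(np.int64),
        ref_a=arr[:, 1].astype(np.int64),
        ref_b=arr[:, 2].astype(np.int64),
        ref_c=arr[:, 3].astype(np.int64),
        bond=np.ascontiguousarray(arr[:, 4]),
        angle=np.ascontiguousarray(arr[:, 5]),
        tor_base=np.ascontiguousarray(arr[:, 6]),
        tor_idx=arr[:, 7].astype(np.int64),
    )
    if len(np.unique(np.concatenate([prog.atom, prog.seed_idx]))) != topology.n_atoms:
        raise AssertionError("placement program does not cover every atom")
    _PROGRAM_CACHE[id(topology)] = prog
    return prog


def execute_program(prog: Program, tvec: np.ndarray) -> np.ndarray:
    """Run the placement program for a torsion vector; returns (n, 3) Å."""
    coords = np.zeros((prog.topology.n_atoms, 3))
    s0, s1, s2 = prog.seed_idx
    coords[s0] = (0.0, 0.0, 0.0)
    coords[s1] = (prog.seed_bond01, 0.0, 0.0)
    th = np.radians(prog.seed_angle)
    coords[s2] = coords[s1] + prog.seed_bond12 * np.array(
        [-np.cos(th), np.sin(th), 0.0]
    )
    for k in range(len(prog.atom)):
        ti = prog.tor_idx[k]
        tor = prog.tor_base[k] if ti < 0 else tvec[ti] + prog.tor_base[k]
        coords[prog.atom[k]] = place_atom(
            coords[prog.ref_a[k]],
            coords[prog.ref_b[k]],
            coords[prog.ref_c[k]],
            prog.bond[k],
            prog.angle[k],
            tor,
        )
    return coords


def build_conformation(
    topology: FoldamerTopology,
    torsions: TorsionState,
    provenance: dict | None = None,
) -> Conformation:
    """Build Cartesian coordinates from backbone torsions.

    Raises ``ValueError`` if a residue's torsion entry is missing or an
    entry refers to a triazole ring position.
    """
    ring_positions = set(topology.ring_positions)
    res_positions = {r.position_index for r in topology.residues}
    for pos, _, _ in torsions.entries:
        if pos in ring_positions:
            raise ValueError(f"torsion entry for ring position {pos}")
        if pos not in res_positions:
            raise ValueError(f"torsion entry for unknown position {pos}")
    tvec = torsions.to_vector(topology)  # raises on missing entries
    prog = compile_program(topology)
    coords = execute_program(prog, tvec)
    return Conformation(topology, coords, provenance or {"generator": "builder"})


def _phi_psi_quads(topology: FoldamerTopology):
    """Yield (residue, phi_quad, psi_quad, psi_from_O) atom-id quadruples."""
    res = topology.residues
    acyl = topology.n_cap in ("Boc", "Bus")
    cap_pos = max(a.position_index for a in topology.atoms)
    has_ccap = topology.c_cap != "none"
    for i, r in enumerate(res):
        p = r.position_index
        if r.kind in ("amide", "tz4n"):
            anchor_n = f"{p}:N"
            if i == 0:
                prev_c = "0:cap_C" if acyl else None
            else:
                prev_c = f"{res[i - 1].position_index}:C_O"
            phi_a = prev_c
        else:
            ring = p - 1
            anchor_n = f"{ring}:ring_N1"
            phi_a = f"{ring}:ring_C5"
        if r.kind == "tz4n":
            ring = p + 1
            phi = (phi_a, anchor_n, f"{p}:CA", f"{ring}:ring_C4")
            psi = (anchor_n, f"{p}:CA", f"{ring}:ring_C4", f"{ring}:ring_C5")
            psi_from_o = False
        else:
            if i + 1 < len(res):
                nxt = f"{res[i + 1].position_index}:N"
                psi_from_o = False
            elif has_ccap:
                nxt = f"{cap_pos}:cap_OE"
                psi_from_o = False
            else:
                nxt = f"{p}:O"
                psi_from_o = True  # carbonyl O sits at ψ + 180
            phi = (phi_a, anchor_n, f"{p}:CA", f"{p}:C_O")
            psi = (anchor_n, f"{p}:CA", f"{p}:C_O", nxt)
        yield r, phi, psi, psi_from_o


def measure_torsions(conf: Conformation) -> TorsionState:
    """Measure backbone (ϕ, ψ) per residue; undefined torsions are NaN."""
    top = conf.topology
    entries = []
    for r, phi_q, psi_q, psi_from_o in _phi_psi_quads(top):
        if phi_q[0] is None:
            phi = float("nan")
        else:
            phi = dihedral(*(conf.coord(a) for a in phi_q))
            if np.isnan(phi):
                warnings.warn(
                    f"undefined ϕ at position {r.position_index} (collinear)",
                    stacklevel=2,
                )
        psi = dihedral(*(conf.coord(a) for a in psi_q))
        if np.isnan(psi):
            warnings.warn(
                f"undefined ψ at position {r.position_index} (collinear)",
                stacklevel=2,
            )
        elif psi_from_o:
            psi = wrap_angle(psi - 180.0)
        entries.append((r.position_index, phi, psi))
    return TorsionState(entries)


def measure_chirality(conf: Conformation) -> dict[int, str]:
    """Cα chirality label per residue position via the Cβ improper dihedral.

    The improper dihedral(C_O|ring_C4, N|ring_N1, CA, CB) is negative
    (≈ −120°) for L — matching real L-amino-acid geometry under the IUPAC
    sign convention — and positive for D; Gly is reported achiral.
    """
    top = conf.topology
    out = {}
    for r in top.residues:
        p = r.position_index
        if r.side_chain == "none":
            out[p] = "achiral"
            continue
        # the build frame (other-backbone-neighbour, amine anchor, CA):
        # the improper there is ϕ/ψ-independent
        if r.kind == "tz4c":
            quad = (f"{p}:C_O", f"{p - 1}:ring_N1", f"{p}:CA", f"{p}:CB")
        elif r.kind == "tz4n":
            quad = (f"{p + 1}:ring_C4", f"{p}:N", f"{p}:CA", f"{p}:CB")
        else:
            quad = (f"{p}:C_O", f"{p}:N", f"{p}:CA", f"{p}:CB")
        imp = dihedral(*(conf.coord(a) for a in quad))
        out[p] = "L" if imp < 0 else "D"
    return out
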