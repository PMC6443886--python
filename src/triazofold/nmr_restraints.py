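"""ROESY cross-peaks → upper-bound interproton distance restraints.

Distances come from the isolated-spin-pair calibration
``r = r_ref * (I_ref / I)**(1/6)`` against a single reference peak of
known distance.  Restraints are flat-bottom harmonic on the upper bound
only, ``E = k * max(0, r - r_upper)**2`` (AMBER-style ``k·Δ²``, not
``½kΔ²``), with a default force constant of 32 kcal·mol⁻¹·Å⁻².

Proton references are ``(position_index, role)`` pairs with roles from
{H_N, H_A, ring_H5, SC_centroid}; methyl/methylene groups map onto the
side-chain centroid pseudo-atom with no multiplicity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foldamer_model.topology import Conformation

__all__ = [
    "DEFAULT_FORCE_CONSTANT",
    "PROTON_ROLES",
    "RoesyPeak",
    "DistanceRestraint",
    "RestraintSet",
    "peaks_to_distances",
    "distances_to_restraints",
    "restraint_energy",
    "total_restraint_energy",
    "read_peak_table",
    "write_peak_table",
    "read_restraint_table",
    "write_restraint_table",
]

DEFAULT_FORCE_CONSTANT = 32.0  # kcal·mol⁻¹·Å⁻²
PROTON_ROLES = ("H_N", "H_A", "ring_H5", "SC_centroid")

ProtonRef = tuple[int, str]  # (position_index, role)


@dataclass(frozen=True)
class RoesyPeak:
    proton_a: ProtonRef
    proton_b: ProtonRef
    intensity: float
    is_reference: bool = False
    r_ref: float | None = None  # Å, required on the reference peak

    def __post_init__(self):
        if not (self.intensity > 0):
            raise ValueError(
                f"peak intensity must be > 0, got {self.intensity}"
            )
        if self.is_reference and not (self.r_ref and self.r_ref > 0):
            raise ValueError("reference peak needs a positive r_ref")


@dataclass
class DistanceRestraint:
    proton_a: ProtonRef
    proton_b: ProtonRef
    r_upper: float  # Å
    k: float = DEFAULT_FORCE_CONSTANT
    source_peak: str = ""
    active: bool = True

    def __post_init__(self):
        if not (self.r_upper > 0):
            raise ValueError(f"r_upper must be > 0, got {self.r_upper}")
        if self.k < 0:
            raise ValueError(f"force constant must be >= 0, got {self.k}")

    @property
    def restraint_id(self) -> str:
        a, b = self.proton_a, self.proton_b
        return f"{a[0]}:{a[1]}--{b[0]}:{b[1]}"


@dataclass
class RestraintSet:
    """Ordered restraints with an audit trail of pruning events."""

    restraints: list[DistanceRestraint] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.restraint_id for r in self.restraints]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate restraint ids: {dupes}")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    @property
    def active(self) -> list[DistanceRestraint]:
        return [r for r in self.restraints if r.active]

    @property
    def active_ids(self) -> list[str]:
        return [r.restraint_id for r in self.active]

    def get(self, restraint_id: str) -> DistanceRestraint:
        for r in self.restraints:
            if r.restraint_id == restraint_id:
                return r
        raise LookupError(f"no restraint {restraint_id!r}")

    def deactivate(self, ids: list[str], statistics: dict[str, float] | None = None):
        """Deactivate restraints, appending a pruning-history record."""
        for rid in ids:
            self.get(rid).active = False
        self.history.append(
            {
                "iteration": len(self.history) + 1,
                "removed": list(ids),
                "statistics": dict(statistics or {}),
            }
        )

    def history_report(self) -> str:
        return json.dumps(self.history, indent=2)


def peaks_to_distances(
    peaks: list[RoesyPeak],
) -> list[tuple[tuple[ProtonRef, ProtonRef], float]]:
    """Calibrated interproton distances via the r⁻⁶ relation.

    Only the intensity ratio I_ref/I enters, so any common intensity scale
    cancels.  Exactly one reference peak must be present; it maps to its
    own r_ref.
    """
    refs = [p for p in peaks if p.is_reference]
    if len(refs) != 1:
        raise ValueError(
            f"peak table needs exactly one reference peak, found {len(refs)}"
        )
    ref = refs[0]
    out = []
    for p in peaks:
        if p is ref:
            r = float(ref.r_ref)
        else:
            r = float(ref.r_ref) * (ref.intensity / p.intensity) ** (1.0 / 6.0)
        out.append(((p.proton_a, p.proton_b), r))
    return out


def distances_to_restraints(
    distances: list[tuple[tuple[ProtonRef, ProtonRef], float]],
    k: float = DEFAULT_FORCE_CONSTANT,
    slack: float = 0.0,
) -> RestraintSet:
    """Upper-bound restraints at distance + slack (slack defaults to 0 Å)."""
    if k < 0:
        raise ValueError(f"force constant must be >= 0, got {k}")
    if slack < 0:
        raise ValueError(f"slack must be >= 0, got {slack}")
    restraints = [
        DistanceRestraint(pa, pb, d + slack, k=k, source_peak=f"peak{i}")
        for i, ((pa, pb), d) in enumerate(distances)
    ]
    return RestraintSet(restraints)


def resolve_proton(conf: Conformation, ref: ProtonRef) -> np.ndarray:
    """Coordinates of a proton / pseudo-proton reference."""
    pos, role = ref
    try:
        return conf.coord(f"{pos}:{role}")
    except LookupError:
        raise LookupError(
            f"cannot resolve proton reference ({pos}, {role!r})"
        ) from None


def restraint_energy(restraint: DistanceRestraint, conf: Conformation) -> float:
    """Flat-bottom harmonic penalty in kcal/mol: 0 inside the bound."""
    pa = resolve_proton(conf, restraint.proton_a)
    pb = resolve_proton(conf, restraint.proton_b)
    r = float(np.linalg.norm(pa - pb))
    delta = max(0.0, r - restraint.r_upper)
    return restraint.k * delta * delta


def total_restraint_energy(
    rset: RestraintSet, conf: Conformation
) -> tuple[float, dict[str, float]]:
    """Sum of active penalties; inactive restraints reported but excluded."""
    penalties: dict[str, float] = {}
    total = 0.0
    for r in rset.restraints:
        e = restraint_energy(r, conf)
        penalties[r.restraint_id] = e
        if r.active:
            total += e
    return total, penalties


# -- TSV / JSON interfaces --------------------------------------------------

_PEAK_COLS = ["res_a", "role_a", "res_b", "role_b", "intensity", "is_ref", "r_ref"]


def write_peak_table(path, peaks: list[RoesyPeak]) -> None:
    rows = [
        {
            "res_a": p.proton_a[0], "role_a": p.proton_a[1],
            "res_b": p.proton_b[0], "role_b": p.proton_b[1],
            "intensity": p.intensity,
            "is_ref": int(p.is_reference),
            "r_ref": p.r_ref if p.is_reference else "",
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> list[RoesyPeak]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PEAK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    peaks = []
    for _, row in df.iterrows():
        is_ref = bool(int(row["is_ref"]))
        r_ref = float(row["r_ref"]) if is_ref else None
        peaks.append(
            RoesyPeak(
                (int(row["res_a"]), str(row["role_a"])),
                (int(row["res_b"]), str(row["role_b"])),
                float(row["intensity"]),
                is_reference=is_ref,
                r_ref=r_ref,
            )
        )
    return peaks


def write_restraint_table(path, rset: RestraintSet) -> None:
    rows = [
        {
            "res_a": r.proton_a[0], "role_a": r.proton_a[1],
            "res_b": r.proton_b[0], "role_b": r.proton_b[1],
            "r_upper": r.r_upper, "k": r.k, "active": int(r.active),
        }
        for r in rset.restraints
    ]
    pd.DataFrame(
        rows,
        columns=["res_a", "role_a", "res_b", "role_b", "r_upper", "k", "active"],
    ).to_csv(path, sep="\t", index=False)


def read_restraint_table(path) -> RestraintSet:
    df = pd.read_csv(path, sep="\t")
    restraints = [
        DistanceRestraint(
            (int(row["res_a"]), str(row["role_a"])),
            (int(row["res_b"]), str(row["role_b"])),
            float(row["r_upper"]),
            k=float(row["k"]),
            active=bool(int(row["active"])),
        )
        for _, row in df.iterrows()
    ]
    return RestraintSet(restraints)
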