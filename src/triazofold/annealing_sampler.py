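"""Restrained torsion-space simulated annealing (Metropolis Monte Carlo).

This is a desk-scale stand-in for restrained gas-phase annealing MD: the
staged temperature schedule is preserved, with picosecond durations mapped
to MC steps via ``steps_per_ps`` (default 100), and the molecular energy
replaced by a declared-non-physical stand-in:

* steric: Σ over non-bonded pairs (> 3 bonds apart) of ε·(σij/rij)¹²,
  capped per pair, purely to prevent chain self-intersection;
* torsion: Σ K_ω·(1 + cos(2ω − 180°)) over amide ω angles (identically
  zero for the rigid builder, retained for flexibility);
* restraint: flat-bottom harmonic NOE term (k·Δ² above the upper bound).

Moves perturb one randomly chosen ϕ/ψ torsion by Gaussian noise whose
width scales with temperature; acceptance is Metropolis at T > 0 and
greedy (ΔE ≤ 0) at T = 0.  All randomness is drawn up front from
``numpy.random.default_rng(seed)``, so runs are deterministic and
platform-stable regardless of whether the numba fast path is active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .foldamer_model.builder import Program, compile_program
from .foldamer_model.topology import Conformation, FoldamerTopology, TorsionState
from .nmr_restraints import RestraintSet, total_restraint_energy

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


__all__ = [
    "GAS_CONSTANT",
    "AnnealSchedule",
    "EnergyBreakdown",
    "ReplicaResult",
    "MoveParams",
    "EnergyModel",
    "stand_in_energy",
    "run_annealing",
    "run_campaign",
    "schedule_total",
    "SA_STAGES",
    "HEATUP_STAGES",
]

GAS_CONSTANT = 1.98720425864e-3  # kcal·mol⁻¹·K⁻¹

# gas-phase SA ramp: 0 → 600 K → 0 K; stages sum to 900 ps (the protocol's
# prose calls the run "1 ns-long"; the stage list is taken as authoritative)
SA_STAGES = (
    (10.0, 5.0), (100.0, 5.0), (200.0, 90.0), (600.0, 400.0), (400.0, 100.0),
    (200.0, 200.0), (100.0, 75.0), (10.0, 20.0), (0.0, 5.0),
)
# solvated-system heat-up: 0 → 300 K over 890 ps
HEATUP_STAGES = (
    (10.0, 10.0), (50.0, 10.0), (100.0, 20.0), (100.0, 50.0),
    (200.0, 100.0), (300.0, 200.0), (300.0, 500.0),
)

# per-role steric σ parameters (Å); Lorentz combining σij = (σi + σj)/2
_ROLE_RADII = {"CB": 1.7, "SC_centroid": 2.2, "cap_centroid": 2.2}
_H_RADIUS = 1.0
_BACKBONE_RADIUS = 1.5
STERIC_EPS = 1.0  # kcal/mol
STERIC_CAP = 100.0  # kcal/mol per pair
K_OMEGA = 10.0  # kcal/mol, amide planarity (zero for the rigid builder)


@dataclass(frozen=True)
class AnnealSchedule:
    """Staged temperature protocol: ordered (temperature K, duration ps)."""

    stages: tuple[tuple[float, float], ...]
    steps_per_ps: int = 100

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("schedule needs at least one stage")
        for t, d in self.stages:
            if d <= 0:
                raise ValueError(f"stage duration must be > 0 ps, got {d}")
            if t < 0:
                raise ValueError(f"temperature must be >= 0 K, got {t}")
        if self.steps_per_ps < 0:
            raise ValueError("steps_per_ps must be >= 0")

    @property
    def total_ps(self) -> float:
        return float(sum(d for _, d in self.stages))

    def step_counts(self) -> np.ndarray:
        return np.array(
            [int(round(d * self.steps_per_ps)) for _, d in self.stages],
            dtype=np.int64,
        )

    @classmethod
    def gas_phase_sa(cls, steps_per_ps: int = 100) -> "AnnealSchedule":
        return cls(SA_STAGES, steps_per_ps)

    @classmethod
    def solvent_heatup(cls, steps_per_ps: int = 100) -> "AnnealSchedule":
        return cls(HEATUP_STAGES, steps_per_ps)


def schedule_total(schedule: AnnealSchedule | list | tuple) -> float:
    """Total duration in ps (sum of stage durations)."""
    if isinstance(schedule, AnnealSchedule):
        return schedule.total_ps
    stages = list(schedule)
    if not stages:
        raise ValueError("empty schedule")
    return float(sum(d for _, d in stages))


@dataclass(frozen=True)
class EnergyBreakdown:
    steric: float
    torsion: float
    restraint: float

    @property
    def total(self) -> float:
        return self.steric + self.torsion + self.restraint


@dataclass(frozen=True)
class MoveParams:
    """Single-torsion Gaussian move; width scales as sqrt(T/600 K)."""

    sigma_max: float = 30.0  # degrees at 600 K
    sigma_min: float = 2.0
    t_ref: float = 600.0

    def sigma(self, temperature: float) -> float:
        s = self.sigma_max * np.sqrt(max(temperature, 0.0) / self.t_ref)
        return float(np.clip(s, self.sigma_min, self.sigma_max))


@dataclass
class ReplicaResult:
    replica_id: int
    seed: int
    final_torsions: TorsionState
    final_conformation: Conformation
    energy: EnergyBreakdown
    penalties: dict[str, float]  # active restraints only
    acceptance_rate: float
    energy_trace: np.ndarray = field(repr=False, default=None)


# -- energy model compilation ----------------------------------------------


def _graph_distances_le3(topology: FoldamerTopology) -> set[tuple[int, int]]:
    """Atom-index pairs within 3 bonds of each other (incl. bonded)."""
    n = topology.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in topology.bonds:
        ia, ib = topology.atom_index(a), topology.atom_index(b)
        adj[ia].append(ib)
        adj[ib].append(ia)
    close: set[tuple[int, int]] = set()
    for start in range(n):
        depth = {start: 0}
        frontier = [start]
        for d in range(1, 4):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in depth:
                        depth[v] = d
                        nxt.append(v)
            frontier = nxt
        for v in depth:
            if v != start:
                close.add((min(start, v), max(start, v)))
    return close


def _role_radius(role: str, element: str) -> float:
    if element == "H":
        return _H_RADIUS
    return _ROLE_RADII.get(role, _BACKBONE_RADIUS)


class EnergyModel:
    """Compiled stand-in energy terms for one topology + restraint set."""

    def __init__(self, topology: FoldamerTopology, restraints: RestraintSet | None = None):
        self.topology = topology
        self.restraints = restraints
        close = _graph_distances_le3(topology)
        pi, pj, sig = [], [], []
        for i in range(topology.n_atoms):
            for j in range(i + 1, topology.n_atoms):
                if (i, j) in close:
                    continue
                pi.append(i)
                pj.append(j)
                ai, aj = topology.atoms[i], topology.atoms[j]
                sig.append(
                    0.5
                    * (
                        _role_radius(ai.role, ai.element)
                        + _role_radius(aj.role, aj.element)
                    )
                )
        self.pair_i = np.array(pi, dtype=np.int64)
        self.pair_j = np.array(pj, dtype=np.int64)
        self.sigma12 = np.array(sig, dtype=float) ** 12
        active = restraints.active if restraints is not None else []
        self.restraint_ids = [r.restraint_id for r in active]
        self.r_ai = np.array(
            [topology.atom_index(f"{r.proton_a[0]}:{r.proton_a[1]}") for r in active],
            dtype=np.int64,
        )
        self.r_aj = np.array(
            [topology.atom_index(f"{r.proton_b[0]}:{r.proton_b[1]}") for r in active],
            dtype=np.int64,
        )
        self.r_up = np.array([r.r_upper for r in active], dtype=float)
        self.r_k = np.array([r.k for r in active], dtype=float)
        # amide ω quadruples (CA_i, C_O_i, N_next, CA_next)
        quads = []
        res = topology.residues
        for a, b in zip(res, res[1:]):
            if a.kind == "tz4n":
                continue  # triazole link, no amide ω
            pa, pb = a.position_index, b.position_index
            if topology.has_atom(pb, "N"):
                quads.append(
                    tuple(
                        topology.atom_index(x)
                        for x in (f"{pa}:CA", f"{pa}:C_O", f"{pb}:N", f"{pb}:CA")
                    )
                )
        self.omega_quads = np.array(quads, dtype=np.int64).reshape(-1, 4)

    def steric(self, coords: np.ndarray) -> tuple[float, bool]:
        d = coords[self.pair_i] - coords[self.pair_j]
        r2 = (d * d).sum(axis=1)
        overlap = bool(np.any(r2 < 1e-4))
        r12 = np.maximum(r2, 1e-4) ** 6
        e = np.minimum(STERIC_EPS * self.sigma12 / r12, STERIC_CAP)
        return float(e.sum()), overlap

    def torsion(self, coords: np.ndarray) -> float:
        from .geometry import dihedral

        e = 0.0
        for qa, qb, qc, qd in self.omega_quads:
            om = dihedral(coords[qa], coords[qb], coords[qc], coords[qd])
            if np.isfinite(om):
                e += K_OMEGA * (1.0 + np.cos(np.radians(2 * om - 180.0)))
        return e


def stand_in_energy(
    conf: Conformation,
    restraints: RestraintSet | None = None,
    model: EnergyModel | None = None,
) -> EnergyBreakdown:
    """Full stand-in energy breakdown for a conformer."""
    if model is None:
        model = EnergyModel(conf.topology, restraints)
    steric, overlap = model.steric(conf.coords)
    if overlap:
        warnings.warn("overlapping atoms: steric contribution capped", stacklevel=2)
    torsion = model.torsion(conf.coords)
    if restraints is not None:
        restraint, _ = total_restraint_energy(restraints, conf)
    else:
        restraint = 0.0
    return EnergyBreakdown(steric=steric, torsion=torsion, restraint=restraint)


# -- MC kernel --------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _build_coords(
    n_atoms, s0, s1, s2, sb01, sb12, sang,
    atom, ra, rb, rc, bond, angle, tbase, tidx, tvec, coords,
):
    coords[s0, 0] = 0.0
    coords[s0, 1] = 0.0
    coords[s0, 2] = 0.0
    coords[s1, 0] = sb01
    coords[s1, 1] = 0.0
    coords[s1, 2] = 0.0
    th = np.radians(sang)
    coords[s2, 0] = sb01 - sb12 * np.cos(th)
    coords[s2, 1] = sb12 * np.sin(th)
    coords[s2, 2] = 0.0
    for k in range(atom.shape[0]):
        ti = tidx[k]
        tor = tbase[k] if ti < 0 else tvec[ti] + tbase[k]
        theta = np.radians(angle[k])
        phi = np.radians(tor)
        ax, ay, az = coords[ra[k], 0], coords[ra[k], 1], coords[ra[k], 2]
        bx, by, bz = coords[rb[k], 0], coords[rb[k], 1], coords[rb[k], 2]
        cx, cy, cz = coords[rc[k], 0], coords[rc[k], 1], coords[rc[k], 2]
        ux, uy, uz = cx - bx, cy - by, cz - bz
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux / un, uy / un, uz / un
        abx, aby, abz = bx - ax, by - ay, bz - az
        nx = aby * uz - abz * uy
        ny = abz * ux - abx * uz
        nz = abx * uy - aby * ux
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        mx = ny * uz - nz * uy
        my = nz * ux - nx * uz
        mz = nx * uy - ny * ux
        b = bond[k]
        d1 = -b * np.cos(theta)
        d2 = b * np.sin(theta) * np.cos(phi)
        d3 = b * np.sin(theta) * np.sin(phi)
        coords[atom[k], 0] = cx + d1 * ux + d2 * mx + d3 * nx
        coords[atom[k], 1] = cy + d1 * uy + d2 * my + d3 * ny
        coords[atom[k], 2] = cz + d1 * uz + d2 * mz + d3 * nz


@njit(cache=True, fastmath=True)
def _energy(coords, pair_i, pair_j, sigma12, r_ai, r_aj, r_up, r_k):
    e = 0.0
    for p in range(pair_i.shape[0]):
        dx = coords[pair_i[p], 0] - coords[pair_j[p], 0]
        dy = coords[pair_i[p], 1] - coords[pair_j[p], 1]
        dz = coords[pair_i[p], 2] - coords[pair_j[p], 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-4:
            r2 = 1e-4
        r12 = r2 * r2 * r2
        r12 = r12 * r12
        ep = STERIC_EPS * sigma12[p] / r12
        if ep > STERIC_CAP:
            ep = STERIC_CAP
        e += ep
    for q in range(r_ai.shape[0]):
        dx = coords[r_ai[q], 0] - coords[r_aj[q], 0]
        dy = coords[r_ai[q], 1] - coords[r_aj[q], 1]
        dz = coords[r_ai[q], 2] - coords[r_aj[q], 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > r_up[q]:
            delta = r - r_up[q]
            e += r_k[q] * delta * delta
    return e


@njit(cache=True, fastmath=True)
def _build_cached(
    n_atoms, s0, s1, s2, sb01, sb12, sang,
    atom, ra, rb, rc, bond, cos_th, sin_th, cos_tor, sin_tor, coords,
):
    # as _build_coords, but with all trigonometry precomputed per step
    coords[s0, 0] = 0.0
    coords[s0, 1] = 0.0
    coords[s0, 2] = 0.0
    coords[s1, 0] = sb01
    coords[s1, 1] = 0.0
    coords[s1, 2] = 0.0
    th = np.radians(sang)
    coords[s2, 0] = sb01 - sb12 * np.cos(th)
    coords[s2, 1] = sb12 * np.sin(th)
    coords[s2, 2] = 0.0
    for k in range(atom.shape[0]):
        ax, ay, az = coords[ra[k], 0], coords[ra[k], 1], coords[ra[k], 2]
        bx, by, bz = coords[rb[k], 0], coords[rb[k], 1], coords[rb[k], 2]
        cx, cy, cz = coords[rc[k], 0], coords[rc[k], 1], coords[rc[k], 2]
        ux, uy, uz = cx - bx, cy - by, cz - bz
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux / un, uy / un, uz / un
        abx, aby, abz = bx - ax, by - ay, bz - az
        nx = aby * uz - abz * uy
        ny = abz * ux - abx * uz
        nz = abx * uy - aby * ux
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        mx = ny * uz - nz * uy
        my = nz * ux - nx * uz
        mz = nx * uy - ny * ux
        b = bond[k]
        d1 = -b * cos_th[k]
        d2 = b * sin_th[k] * cos_tor[k]
        d3 = b * sin_th[k] * sin_tor[k]
        coords[atom[k], 0] = cx + d1 * ux + d2 * mx + d3 * nx
        coords[atom[k], 1] = cy + d1 * uy + d2 * my + d3 * ny
        coords[atom[k], 2] = cz + d1 * uz + d2 * mz + d3 * nz


@njit(cache=True, fastmath=True)
def _energy_cut(coords, pair_i, pair_j, sigma12, cut2, r_ai, r_aj, r_up, r_k):
    e = 0.0
    for p in range(pair_i.shape[0]):
        dx = coords[pair_i[p], 0] - coords[pair_j[p], 0]
        dy = coords[pair_i[p], 1] - coords[pair_j[p], 1]
        dz = coords[pair_i[p], 2] - coords[pair_j[p], 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2[p]:
            continue
        if r2 < 1e-4:
            r2 = 1e-4
        r12 = r2 * r2 * r2
        r12 = r12 * r12
        ep = STERIC_EPS * sigma12[p] / r12
        if ep > STERIC_CAP:
            ep = STERIC_CAP
        e += ep
    for q in range(r_ai.shape[0]):
        dx = coords[r_ai[q], 0] - coords[r_aj[q], 0]
        dy = coords[r_ai[q], 1] - coords[r_aj[q], 1]
        dz = coords[r_ai[q], 2] - coords[r_aj[q], 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > r_up[q]:
            delta = r - r_up[q]
            e += r_k[q] * delta * delta
    return e


@njit(cache=True, fastmath=True)
def _mc_run(
    n_atoms, s0, s1, s2, sb01, sb12, sang,
    atom, ra, rb, rc, bond, angle, tbase, tidx,
    tvec, stage_steps, stage_t, stage_sigma,
    tor_choice, delta, u,
    pair_i, pair_j, sigma12, r_ai, r_aj, r_up, r_k, gas_r,
):
    n_prog = atom.shape[0]
    cos_th = np.empty(n_prog)
    sin_th = np.empty(n_prog)
    cos_tor = np.empty(n_prog)
    sin_tor = np.empty(n_prog)
    for k in range(n_prog):
        th = np.radians(angle[k])
        cos_th[k] = np.cos(th)
        sin_th[k] = np.sin(th)
        ti = tidx[k]
        tor = tbase[k] if ti < 0 else tvec[ti] + tbase[k]
        ph = np.radians(tor)
        cos_tor[k] = np.cos(ph)
        sin_tor[k] = np.sin(ph)
    # steps affected by each torsion (CSR layout)
    n_tor = 0
    for k in range(n_prog):
        if tidx[k] + 1 > n_tor:
            n_tor = tidx[k] + 1
    ts_count = np.zeros(n_tor + 1, dtype=np.int64)
    for k in range(n_prog):
        if tidx[k] >= 0:
            ts_count[tidx[k] + 1] += 1
    for j in range(1, n_tor + 1):
        ts_count[j] += ts_count[j - 1]
    ts_idx = np.empty(ts_count[n_tor], dtype=np.int64)
    fill = ts_count[:-1].copy()
    for k in range(n_prog):
        if tidx[k] >= 0:
            ts_idx[fill[tidx[k]]] = k
            fill[tidx[k]] += 1
    # tiny steric contributions beyond the cutoff are dropped
    cut2 = np.empty_like(sigma12)
    for p in range(sigma12.shape[0]):
        cut2[p] = 16.0 * sigma12[p] ** (1.0 / 6.0)

    coords = np.zeros((n_atoms, 3))
    trial = np.zeros((n_atoms, 3))
    _build_cached(
        n_atoms, s0, s1, s2, sb01, sb12, sang,
        atom, ra, rb, rc, bond, cos_th, sin_th, cos_tor, sin_tor, coords,
    )
    e = _energy_cut(coords, pair_i, pair_j, sigma12, cut2, r_ai, r_aj, r_up, r_k)
    n_steps = tor_choice.shape[0]
    energies = np.empty(n_steps)
    saved_cos = np.empty(8)
    saved_sin = np.empty(8)
    accepted = 0
    s = 0
    for st in range(stage_steps.shape[0]):
        temp = stage_t[st]
        sig = stage_sigma[st]
        for _ in range(stage_steps[st]):
            j = tor_choice[s]
            old = tvec[j]
            new = old + delta[s] * sig
            # wrap into (-180, 180]
            new = new - 360.0 * np.floor((new + 180.0) / 360.0)
            if new <= -180.0:
                new += 360.0
            tvec[j] = new
            lo, hi = ts_count[j], ts_count[j + 1]
            for q in range(lo, hi):
                k = ts_idx[q]
                saved_cos[q - lo] = cos_tor[k]
                saved_sin[q - lo] = sin_tor[k]
                ph = np.radians(new + tbase[k])
                cos_tor[k] = np.cos(ph)
                sin_tor[k] = np.sin(ph)
            _build_cached(
                n_atoms, s0, s1, s2, sb01, sb12, sang,
                atom, ra, rb, rc, bond, cos_th, sin_th, cos_tor, sin_tor, trial,
            )
            e_new = _energy_cut(
                trial, pair_i, pair_j, sigma12, cut2, r_ai, r_aj, r_up, r_k
            )
            de = e_new - e
            ok = False
            if de <= 0.0:
                ok = True
            elif temp > 0.0:
                if u[s] < np.exp(-de / (gas_r * temp)):
                    ok = True
            if ok:
                e = e_new
                accepted += 1
                tmp = coords
                coords = trial
                trial = tmp
            else:
                tvec[j] = old
                for q in range(lo, hi):
                    k = ts_idx[q]
                    cos_tor[k] = saved_cos[q - lo]
                    sin_tor[k] = saved_sin[q - lo]
            energies[s] = e
            s += 1
    return tvec, coords, accepted, energies


def _kernel_inputs(prog: Program, model: EnergyModel):
    return dict(
        n_atoms=prog.topology.n_atoms,
        s0=int(prog.seed_idx[0]), s1=int(prog.seed_idx[1]), s2=int(prog.seed_idx[2]),
        sb01=prog.seed_bond01, sb12=prog.seed_bond12, sang=prog.seed_angle,
        atom=prog.atom, ra=prog.ref_a, rb=prog.ref_b, rc=prog.ref_c,
        bond=prog.bond, angle=prog.angle, tbase=prog.tor_base, tidx=prog.tor_idx,
        pair_i=model.pair_i, pair_j=model.pair_j, sigma12=model.sigma12,
        r_ai=model.r_ai, r_aj=model.r_aj, r_up=model.r_up, r_k=model.r_k,
    )


def run_annealing(
    topology: FoldamerTopology,
    restraints: RestraintSet | None,
    schedule: AnnealSchedule,
    seed: int,
    start: TorsionState | None = None,
    move_params: MoveParams = MoveParams(),
    replica_id: int = 0,
    warn_penalty: float = 5.0,
) -> ReplicaResult:
    """One restrained annealing replica; deterministic given (inputs, seed)."""
    prog = compile_program(topology)
    model = EnergyModel(topology, restraints)
    if start is None:
        start = TorsionState.uniform(topology, 180.0, 180.0)
    tvec = start.to_vector(topology).copy()

    stage_steps = schedule.step_counts()
    n_steps = int(stage_steps.sum())
    stage_t = np.array([t for t, _ in schedule.stages], dtype=float)
    stage_sigma = np.array([move_params.sigma(t) for t in stage_t], dtype=float)

    rng = np.random.default_rng(seed)
    tor_choice = rng.integers(0, prog.n_torsions, size=n_steps)
    delta = rng.standard_normal(n_steps)
    u = rng.random(n_steps)

    tvec, coords, accepted, energies = _mc_run(
        tvec=tvec, stage_steps=stage_steps, stage_t=stage_t,
        stage_sigma=stage_sigma, tor_choice=tor_choice, delta=delta, u=u,
        gas_r=GAS_CONSTANT, **_kernel_inputs(prog, model),
    )

    final_t = TorsionState.from_vector(topology, tvec)
    conf = Conformation(
        topology, coords,
        provenance={"generator": "annealing", "seed": seed, "replica": replica_id},
    )
    breakdown = stand_in_energy(conf, restraints, model=model)
    if restraints is not None:
        _, all_pen = total_restraint_energy(restraints, conf)
        penalties = {rid: all_pen[rid] for rid in restraints.active_ids}
        worst = max(penalties.values(), default=0.0)
        if worst > max(warn_penalty, 0.0) and n_steps > 0:
            warnings.warn(
                f"replica {replica_id}: irreducible restraint penalty "
                f"{worst:.2f} kcal/mol (possibly infeasible restraints)",
                stacklevel=2,
            )
    else:
        penalties = {}
    return ReplicaResult(
        replica_id=replica_id,
        seed=seed,
        final_torsions=final_t,
        final_conformation=conf,
        energy=breakdown,
        penalties=penalties,
        acceptance_rate=(accepted / n_steps) if n_steps else 0.0,
        energy_trace=energies,
    )


def run_campaign(
    topology: FoldamerTopology,
    restraints: RestraintSet | None,
    schedule: AnnealSchedule,
    n_replicas: int = 100,
    base_seed: int = 0,
    start: TorsionState | None = None,
    move_params: MoveParams = MoveParams(),
) -> list[ReplicaResult]:
    """Independent annealing replicas; replica i uses seed base_seed + i."""
    if n_replicas < 1:
        raise ValueError(f"n_replicas must be >= 1, got {n_replicas}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-replica infeasibility noise
        return [
            run_annealing(
                topology, restraints, schedule, base_seed + i,
                start=start, move_params=move_params, replica_id=i,
            )
            for i in range(n_replicas)
        ]
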