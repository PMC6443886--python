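"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: template
conformers (helix / extended zigzag / twisted-S), two-state trajectory
mixtures with Gaussian torsional noise, ROESY peak tables from an r⁻⁶
forward model with multiplicative log-normal noise, and ideal-gas point
sets for RDF null tests.

The template torsion values are package fixtures chosen to be compact and
sterically clean on this coarse-grained backbone; they are NOT
experimentally determined structures (none are deposited).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .foldamer_model.builder import build_conformation
from .foldamer_model.topology import Conformation, FoldamerTopology, TorsionState
from .geometry import wrap_angle
from .nmr_restraints import PROTON_ROLES, RoesyPeak
from .trajectory_analysis import Trajectory

__all__ = [
    "TEMPLATE_TORSIONS",
    "GeneratorSpec",
    "template_torsions",
    "generate_trajectory",
    "forward_roesy",
    "ideal_gas_frames",
]

# per-kind (phi, psi) in degrees for the periodic templates
TEMPLATE_TORSIONS = {
    "extended": {"amide": (180.0, 180.0), "tz4n": (180.0, 180.0), "tz4c": (180.0, 180.0)},
    "helix": {"amide": (-90.0, -150.0), "tz4n": (-110.0, 150.0), "tz4c": (-105.0, -60.0)},
}


@dataclass
class GeneratorSpec:
    """Recipe for a synthetic trajectory / peak table."""

    template: str | TorsionState = "helix"
    templates: list[str | TorsionState] | None = None  # mixture states
    noise_sigma: float = 5.0  # degrees, i.i.d. Gaussian on every torsion
    n_frames: int = 100
    populations: tuple[float, ...] = (1.0,)
    seed: int = 0
    roesy_sigma_log: float = 0.1
    max_noe_distance: float = 5.0  # Å

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if abs(sum(self.populations) - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if self.templates is None:
            self.templates = [self.template]
        if len(self.templates) != len(self.populations):
            raise ValueError("one population per template state")


def template_torsions(name: str | TorsionState, topology: FoldamerTopology) -> TorsionState:
    """A fixed, documented torsion template for a topology.

    ``extended``: all (180, 180).  ``helix``: a compact period-2 pattern
    adapted to the alternating amide/triazole backbone.  ``twisted_s``:
    two helical blocks of opposite handedness.  A TorsionState passes
    through unchanged.
    """
    if isinstance(name, TorsionState):
        return name
    res = topology.residues
    if name in TEMPLATE_TORSIONS:
        pat = TEMPLATE_TORSIONS[name]
        return TorsionState(
            [(r.position_index,) + pat[r.kind] for r in res]
        )
    if name == "twisted_s":
        pat = TEMPLATE_TORSIONS["helix"]
        half = (len(res) + 1) // 2
        entries = []
        for i, r in enumerate(res):
            phi, psi = pat[r.kind]
            if i >= half:  # mirror-image handedness for the second block
                phi, psi = -phi, -psi
            entries.append((r.position_index, wrap_angle(phi), wrap_angle(psi)))
        return TorsionState(entries)
    raise ValueError(f"unknown template {name!r}")


def generate_trajectory(
    spec: GeneratorSpec, topology: FoldamerTopology
) -> tuple[Trajectory, np.ndarray]:
    """Noisy multi-state trajectory plus per-frame true state labels."""
    rng = np.random.default_rng(spec.seed)
    states = [
        template_torsions(t, topology).to_vector(topology) for t in spec.templates
    ]
    labels = rng.choice(len(states), size=spec.n_frames, p=list(spec.populations))
    frames = np.empty((spec.n_frames, topology.n_atoms, 3))
    for f in range(spec.n_frames):
        base = states[labels[f]]
        noisy = wrap_angle(base + rng.normal(0.0, spec.noise_sigma, size=base.shape))
        conf = build_conformation(
            topology, TorsionState.from_vector(topology, noisy)
        )
        frames[f] = conf.coords
    traj = Trajectory(topology, frames)
    return traj, labels


def _proton_atoms(topology: FoldamerTopology) -> list[str]:
    return [
        a.atom_id for a in topology.atoms if a.role in PROTON_ROLES
    ]


def forward_roesy(
    conf: Conformation,
    i_ref: float = 1.0e6,
    max_distance: float = 5.0,
    sigma_log: float = 0.0,
    seed: int = 0,
    min_separation: int = 1,
) -> list[RoesyPeak]:
    """Forward-model ROESY intensities from a conformer: I = I_ref·(r_ref/r)⁶.

    Emits every proton/pseudo-proton pair within ``max_distance``
    (positions at least ``min_separation`` apart), with multiplicative
    log-normal noise exp(N(0, σ_log²)).  The closest pair serves as the
    noise-free reference peak with r_ref equal to its true distance, so
    inverting with ``peaks_to_distances`` at σ_log = 0 recovers the true
    distances exactly.
    """
    if i_ref <= 0:
        raise ValueError("I_ref must be > 0")
    rng = np.random.default_rng(seed)
    top = conf.topology
    protons = _proton_atoms(top)
    cand: list[tuple[float, str, str]] = []
    for i in range(len(protons)):
        for j in range(i + 1, len(protons)):
            pa, pb = protons[i], protons[j]
            pos_a, pos_b = int(pa.split(":")[0]), int(pb.split(":")[0])
            if abs(pos_a - pos_b) < min_separation:
                continue
            r = conf.distance(pa, pb)
            if r <= max_distance:
                cand.append((r, pa, pb))
    if not cand:
        warnings.warn("no proton pair within the NOE distance ceiling", stacklevel=2)
        return []
    cand.sort()
    r_ref = cand[0][0]
    peaks = []
    for k, (r, pa, pb) in enumerate(cand):
        ref_a = tuple(pa.split(":"))
        ref_b = tuple(pb.split(":"))
        pra = (int(ref_a[0]), ref_a[1])
        prb = (int(ref_b[0]), ref_b[1])
        if k == 0:
            peaks.append(
                RoesyPeak(pra, prb, i_ref, is_reference=True, r_ref=r_ref)
            )
        else:
            noise = np.exp(rng.normal(0.0, sigma_log)) if sigma_log > 0 else 1.0
            peaks.append(RoesyPeak(pra, prb, i_ref * (r_ref / r) ** 6 * noise))
    return peaks


@dataclass
class IdealGasFrames:
    """Uniform point sets around a fixed origin reference."""

    target_frames: list[np.ndarray] = field(default_factory=list)
    reference: np.ndarray = field(default_factory=lambda: np.zeros((1, 3)))


def ideal_gas_frames(
    density: float,
    half_width: float,
    n_frames: int,
    seed: int = 0,
    planted_radius: float | None = None,
) -> IdealGasFrames:
    """Ideal-gas null input for RDF tests.

    Each frame holds Poisson(density·V) uniform points in a cube of side
    2·half_width centred on the origin reference atom; optionally one
    extra point is planted at a fixed radius (random direction) per frame.
    """
    if density <= 0 or half_width <= 0:
        raise ValueError("density and box half-width must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    volume = (2.0 * half_width) ** 3
    frames = []
    for _ in range(n_frames):
        n = rng.poisson(density * volume)
        pts = rng.uniform(-half_width, half_width, size=(n, 3))
        if planted_radius is not None:
            v = rng.normal(size=3)
            v *= planted_radius / np.linalg.norm(v)
            pts = np.vstack([pts, v])
        frames.append(pts)
    return IdealGasFrames(target_frames=frames, reference=np.zeros((1, 3)))
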