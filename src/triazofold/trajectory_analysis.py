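"""Trajectory analytics: RMSD, radius of gyration, torsion distributions,
hierarchical RMSD clustering with representative selection and merging,
and radial distribution functions.

All pairwise/trajectory RMSDs are superposed backbone RMSDs (Kabsch,
proper rotations only).  Clustering is average-linkage agglomerative on
the pairwise RMSD matrix, cut at a fixed cluster count (default 10);
single/complete linkage are available via ``linkage=``.  The cluster
representative is the medoid: the member frame minimising mean RMSD to
the rest of its cluster.  RDFs use a 0.1 Å bin spacing and are normalised
with the bulk number density of water, 0.033456 Å⁻³, by default; inputs
are treated as non-periodic point sets (no minimum-image handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .foldamer_model.builder import measure_torsions
from .foldamer_model.topology import Conformation, FoldamerTopology
from .geometry import kabsch

__all__ = [
    "WATER_NUMBER_DENSITY",
    "Trajectory",
    "ClusterResult",
    "RdfProfile",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "torsion_distribution",
    "pairwise_rmsd_matrix",
    "cluster_frames",
    "merge_similar_clusters",
    "compute_rdf",
    "compute_rdf_points",
]

WATER_NUMBER_DENSITY = 0.033456  # Å⁻³, conventional bulk water


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology."""

    topology: FoldamerTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times_ps: np.ndarray | None = None
    window: tuple[int, int] | None = None  # (first, last) inclusive frame indices

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("trajectory needs >= 1 frame of (n_atoms, 3) coords")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.window is not None:
            first, last = self.window
            if not (0 <= first <= last < self.n_frames):
                raise ValueError(f"window {self.window} out of bounds")

    @classmethod
    def from_conformations(cls, confs: list[Conformation], **kw) -> "Trajectory":
        if not confs:
            raise ValueError("empty conformation list")
        return cls(confs[0].topology, np.stack([c.coords for c in confs]), **kw)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def window_indices(self) -> np.ndarray:
        if self.window is None:
            return np.arange(self.n_frames)
        first, last = self.window
        return np.arange(first, last + 1)

    def windowed(self) -> np.ndarray:
        return self.coords[self.window_indices()]

    def with_window_fraction(self, first_frac: float, last_frac: float = 1.0):
        """Frame-index window from trajectory fractions (e.g. last half)."""
        n = self.n_frames
        first = int(np.floor(first_frac * n))
        last = min(n - 1, int(np.ceil(last_frac * n)) - 1)
        return replace(self, window=(first, last))

    def frame(self, i: int) -> Conformation:
        return Conformation(
            self.topology, self.coords[i], provenance={"frame": i}
        )


@dataclass
class ClusterResult:
    labels: np.ndarray  # per windowed frame, 0-based cluster label
    populations: np.ndarray  # fraction per cluster, sums to 1
    representatives: np.ndarray  # frame index (within window) per cluster
    rep_rmsd: np.ndarray  # pairwise representative RMSD matrix
    linkage: str
    merge_log: list = field(default_factory=list)

    def __post_init__(self):
        if abs(float(self.populations.sum()) - 1.0) > 1e-9:
            raise ValueError("cluster populations must sum to 1")
        for c, rep in enumerate(self.representatives):
            if self.labels[rep] != c:
                raise ValueError(f"representative of cluster {c} not a member")

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


@dataclass
class RdfProfile:
    bin_edges: np.ndarray  # Å, uniform spacing
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin
    density: float  # normalisation number density, Å⁻³
    n_frames: int
    n_ref: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# -- superposition ----------------------------------------------------------


def kabsch_superpose(mobile, reference, weights=None):
    """Least-squares rigid superposition; returns (rotation, translation, rmsd)."""
    return kabsch(mobile, reference, weights=weights)


def _sel_indices(topology: FoldamerTopology, selection) -> np.ndarray:
    if selection is None:
        return topology.selection_indices()
    if isinstance(selection, np.ndarray) and selection.dtype != object:
        return selection.astype(int)
    return topology.selection_indices(list(selection))


def rmsd_series(
    traj: Trajectory, reference: Conformation | np.ndarray, selection=None
) -> np.ndarray:
    """Per-frame superposed RMSD against a fixed reference conformer."""
    idx = _sel_indices(traj.topology, selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    ref_xyz = reference.coords if isinstance(reference, Conformation) else np.asarray(reference)
    if ref_xyz.shape[0] == traj.topology.n_atoms:
        ref_xyz = ref_xyz[idx]
    elif ref_xyz.shape[0] != len(idx):
        raise ValueError("reference does not match selection")
    out = np.empty(len(traj.window_indices()))
    for k, fi in enumerate(traj.window_indices()):
        _, _, out[k] = kabsch(traj.coords[fi][idx], ref_xyz)
    return out


def radius_of_gyration(
    conf: Conformation | np.ndarray,
    selection=None,
    topology: FoldamerTopology | None = None,
    mass_weighted: bool = True,
) -> float:
    """Root-mean-square distance of selected atoms from their centroid (Å)."""
    if isinstance(conf, Conformation):
        topology = conf.topology
        xyz = conf.coords
    else:
        xyz = np.asarray(conf, dtype=float)
    if topology is not None:
        idx = _sel_indices(topology, selection)
        if len(idx) == 0:
            raise ValueError("empty selection")
        xyz = xyz[idx]
        w = topology.masses()[idx] if mass_weighted else np.ones(len(idx))
    else:
        if xyz.shape[0] == 0:
            raise ValueError("empty selection")
        w = np.ones(xyz.shape[0])
    centroid = (w[:, None] * xyz).sum(axis=0) / w.sum()
    d2 = ((xyz - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def rog_series(traj: Trajectory, selection=None, mass_weighted=True) -> np.ndarray:
    idx = _sel_indices(traj.topology, selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    w = traj.topology.masses()[idx] if mass_weighted else np.ones(len(idx))
    xyz = traj.coords[traj.window_indices()][:, idx]
    centroid = (w[None, :, None] * xyz).sum(axis=1) / w.sum()
    d2 = ((xyz - centroid[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((w[None, :] * d2).sum(axis=1) / w.sum())


# -- torsion distributions --------------------------------------------------


def torsion_distribution(traj: Trajectory, bin_width: float = 5.0):
    """Per-residue (ϕ, ψ) samples plus a pooled 2-D histogram.

    Returns ``(per_residue, hist, edges, n_undefined)`` where
    ``per_residue[pos]`` is an (n_frames, 2) array; undefined (NaN)
    dihedrals are excluded from the pooled histogram and counted.
    """
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    per_residue: dict[int, np.ndarray] = {
        r.position_index: np.empty((len(traj.window_indices()), 2))
        for r in traj.topology.residues
    }
    for k, fi in enumerate(traj.window_indices()):
        ts = measure_torsions(traj.frame(fi))
        for pos, phi, psi in ts.entries:
            per_residue[pos][k] = (phi, psi)
    pooled = np.concatenate(list(per_residue.values()), axis=0)
    defined = np.isfinite(pooled).all(axis=1)
    n_undefined = int((~defined).sum())
    # shift 180 onto the last bin's upper edge semantics of histogram2d
    hist, _, _ = np.histogram2d(
        pooled[defined, 0], pooled[defined, 1], bins=[edges, edges]
    )
    return per_residue, hist, edges, n_undefined


# -- clustering -------------------------------------------------------------


def pairwise_rmsd_matrix(coords_sel: np.ndarray) -> np.ndarray:
    """Symmetric superposed-RMSD matrix over frames of selected coords.

    Uses the singular-value identity for the Kabsch minimum,
    ``n·rmsd² = ssd_i + ssd_j − 2(σ1 + σ2 ± σ3)``, with the sign of σ3
    fixed by det(H) to exclude reflections; batched over frame pairs.
    """
    coords_sel = np.asarray(coords_sel, dtype=float)
    n, m, _ = coords_sel.shape
    x = coords_sel - coords_sel.mean(axis=1, keepdims=True)
    ssd = (x**2).sum(axis=(1, 2))
    mat = np.zeros((n, n))
    for i in range(n - 1):
        h = np.einsum("ak,nal->nkl", x[i], x[i + 1:])
        s = np.linalg.svd(h, compute_uv=False)
        d = np.sign(np.linalg.det(h))
        trace = s[:, 0] + s[:, 1] + d * s[:, 2]
        msd = (ssd[i] + ssd[i + 1:] - 2.0 * trace) / m
        r = np.sqrt(np.maximum(msd, 0.0))
        mat[i, i + 1:] = r
        mat[i + 1:, i] = r
    return mat


def cluster_frames(
    traj: Trajectory,
    n_clusters: int,
    selection=None,
    linkage: str = "average",
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Hierarchical agglomerative clustering on backbone RMSD."""
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    idx = _sel_indices(traj.topology, selection)
    frames = traj.coords[traj.window_indices()][:, idx]
    n = frames.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} frames in window")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(frames)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        z = scipy_linkage(squareform(rmsd_matrix, checks=False), method=linkage)
        labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    # relabel by decreasing population, ties broken by first occurrence
    sizes = np.bincount(labels, minlength=labels.max() + 1)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[labels]
    k = int(labels.max()) + 1
    populations = np.bincount(labels, minlength=k) / n
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sub = rmsd_matrix[np.ix_(members, members)]
        reps[c] = members[np.argmin(sub.mean(axis=1))]
    rep_rmsd = rmsd_matrix[np.ix_(reps, reps)]
    return ClusterResult(
        labels=labels,
        populations=populations,
        representatives=reps,
        rep_rmsd=rep_rmsd,
        linkage=linkage,
    )


def merge_similar_clusters(
    result: ClusterResult,
    traj: Trajectory,
    threshold: float = 1.0,
    selection=None,
) -> ClusterResult:
    """Iteratively merge cluster pairs whose representatives are closer
    than ``threshold`` Å backbone RMSD; populations re-sum and the merged
    representative (medoid) is recomputed."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    idx = _sel_indices(traj.topology, selection)
    frames = traj.coords[traj.window_indices()][:, idx]
    rmsd_matrix = pairwise_rmsd_matrix(frames)

    labels = result.labels.copy()
    merge_log = list(result.merge_log)
    while True:
        k = int(labels.max()) + 1
        if k < 2:
            break
        reps = np.empty(k, dtype=int)
        for c in range(k):
            members = np.flatnonzero(labels == c)
            sub = rmsd_matrix[np.ix_(members, members)]
            reps[c] = members[np.argmin(sub.mean(axis=1))]
        rep_rmsd = rmsd_matrix[np.ix_(reps, reps)]
        tri = rep_rmsd + np.diag(np.full(k, np.inf))
        a, b = np.unravel_index(np.argmin(tri), tri.shape)
        if tri[a, b] >= threshold or tri[a, b] == np.inf:
            break
        lo, hi = min(a, b), max(a, b)
        merge_log.append(
            {"merged": [int(lo), int(hi)], "rep_rmsd": float(tri[a, b])}
        )
        labels[labels == hi] = lo
        labels[labels > hi] -= 1

    # rebuild result (relabel by population again)
    k = int(labels.max()) + 1
    n = len(labels)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[labels]
    populations = np.bincount(labels, minlength=k) / n
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sub = rmsd_matrix[np.ix_(members, members)]
        reps[c] = members[np.argmin(sub.mean(axis=1))]
    return ClusterResult(
        labels=labels,
        populations=populations,
        representatives=reps,
        rep_rmsd=rmsd_matrix[np.ix_(reps, reps)],
        linkage=result.linkage,
        merge_log=merge_log,
    )


# -- radial distribution functions -----------------------------------------


def compute_rdf_points(
    ref_frames: list[np.ndarray],
    target_frames: list[np.ndarray],
    bin_width: float = 0.1,
    density: float = WATER_NUMBER_DENSITY,
    r_max: float = 12.0,
) -> RdfProfile:
    """g(r) between per-frame reference and target point sets.

    ``g(r) = counts / (n_frames * n_ref * 4π r² Δr * density)`` with r the
    bin centre; non-periodic geometry.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if len(ref_frames) == 0:
        raise ValueError("zero frames in window")
    if len(ref_frames) != len(target_frames):
        raise ValueError("reference and target frame counts differ")
    nbins = int(np.ceil(r_max / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    counts = np.zeros(nbins)
    n_ref_total = 0
    for ref, tgt in zip(ref_frames, target_frames):
        ref = np.atleast_2d(np.asarray(ref, dtype=float))
        tgt = np.atleast_2d(np.asarray(tgt, dtype=float))
        if ref.shape[0] == 0 or tgt.shape[0] == 0:
            raise ValueError("empty selection")
        n_ref_total += ref.shape[0]
        d = np.linalg.norm(ref[:, None, :] - tgt[None, :, :], axis=2).ravel()
        h, _ = np.histogram(d, bins=edges)
        counts += h
    n_frames = len(ref_frames)
    n_ref = n_ref_total // n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width
    g = counts / (n_frames * n_ref * shell * density)
    return RdfProfile(
        bin_edges=edges, g=g, counts=counts, density=density,
        n_frames=n_frames, n_ref=n_ref,
    )


def compute_rdf(
    traj: Trajectory,
    reference_selection,
    target_selection,
    bin_width: float = 0.1,
    density: float = WATER_NUMBER_DENSITY,
    r_max: float = 12.0,
) -> RdfProfile:
    """RDF between two atom selections of a trajectory."""
    ref_idx = _sel_indices(traj.topology, reference_selection)
    tgt_idx = _sel_indices(traj.topology, target_selection)
    if len(ref_idx) == 0 or len(tgt_idx) == 0:
        raise ValueError("empty selection")
    frames = traj.coords[traj.window_indices()]
    if frames.shape[0] == 0:
        raise ValueError("zero frames in window")
    return compute_rdf_points(
        [f[ref_idx] for f in frames],
        [f[tgt_idx] for f in frames],
        bin_width=bin_width,
        density=density,
        r_max=r_max,
    )
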