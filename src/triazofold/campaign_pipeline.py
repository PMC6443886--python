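"""End-to-end orchestration: build → restraints → annealing → pruning →
representative selection → production stand-in → analysis → report.

The campaign planner enumerates (molecule × solvent × replica) run
matrices with deterministic seed assignment.  "Solvent" is a metadata tag
at desk scale — the production stand-in (constant-temperature torsional
Monte Carlo at 300 K) has no solvent model; the tag selects analysis
conventions (e.g. RDF normalisation density) and labels outputs.

Every pipeline stage writes text artifacts under the output directory and
registers them in a manifest with SHA-256 hashes; re-running with an
unchanged config is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annealing_sampler import AnnealSchedule, run_annealing
from .foldamer_model.builder import build_conformation, measure_torsions
from .foldamer_model.io import write_pdb
from .foldamer_model.topology import parse_sequence
from .nmr_restraints import (
    DEFAULT_FORCE_CONSTANT,
    distances_to_restraints,
    peaks_to_distances,
    write_peak_table,
    write_restraint_table,
)
from .restraint_refinement import PruningConfig, refine
from .synthetic_data import forward_roesy, template_torsions
from .trajectory_analysis import (
    Trajectory,
    WATER_NUMBER_DENSITY,
    cluster_frames,
    merge_similar_clusters,
    rmsd_series,
    rog_series,
)

__all__ = [
    "CampaignPlan",
    "PipelineConfig",
    "ConfigError",
    "StageError",
    "plan_campaign",
    "run_pipeline",
    "summarize",
]

log = logging.getLogger("triazofold")

DMSO_NUMBER_DENSITY = 0.00846  # Å⁻³, bulk DMSO molecules


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved."""


@dataclass(frozen=True)
class CampaignRun:
    molecule: str
    solvent: str
    replica: int
    seed: int
    duration_tag: str = "production"


@dataclass
class CampaignPlan:
    runs: list[CampaignRun]

    def __post_init__(self):
        triplets = [(r.molecule, r.solvent, r.replica) for r in self.runs]
        if len(set(triplets)) != len(triplets):
            raise ValueError("duplicate (molecule, solvent, replica) triplets")
        seeds = [r.seed for r in self.runs]
        if len(set(seeds)) != len(seeds):
            raise ValueError("seeds must be unique across runs")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def plan_campaign(
    molecules: list[str],
    solvents: list[str],
    replicas_per_cell: int,
    base_seed: int = 0,
    duration_tag: str = "production",
) -> CampaignPlan:
    """Cartesian (molecule × solvent × replica) enumeration, stable order,
    deterministic unique seeds."""
    if not molecules or not solvents:
        raise ValueError("molecule and solvent lists must be non-empty")
    if len(set(molecules)) != len(molecules):
        raise ValueError("duplicate molecule ids")
    if replicas_per_cell < 1:
        raise ValueError("replicas_per_cell must be >= 1")
    runs = []
    counter = 0
    for mol in molecules:
        for solv in solvents:
            for rep in range(replicas_per_cell):
                runs.append(
                    CampaignRun(mol, solv, rep, base_seed + counter, duration_tag)
                )
                counter += 1
    return CampaignPlan(runs)


# -- configuration ----------------------------------------------------------

_DEFAULT_CONFIG = {
    "schema_version": 1,
    "sequence": "Boc-Ala-ValΨ[4Tz]Phe-LeuΨ[4Tz]Phe-LeuΨ[4Tz]Val-OAll",
    "molecule_id": "10a",
    "solvent": "DMSO",
    "seed": 0,
    "synthetic": {
        "template": "helix",
        "roesy_sigma_log": 0.1,
        "max_noe_distance": 5.0,
    },
    "restraints": {"force_constant": DEFAULT_FORCE_CONSTANT, "slack": 0.5},
    "annealing": {
        "schedule": "gas_phase_sa",
        "steps_per_ps": 20,
        "n_replicas": 20,
    },
    "pruning": {
        "penalty_ceiling": 5.0,
        "statistic": "per-replica-minimum",
        "max_iterations": None,
    },
    "production": {"temperature": 300.0, "n_steps": 20000, "stride": 50},
    "clustering": {"n_clusters": 10, "merge_threshold": 1.0},
    "analysis": {"window_first_fraction": 0.5},
    "rdf": {"bin_width": 0.1, "density": "water"},
}

_ALLOWED_KEYS = {
    "": set(_DEFAULT_CONFIG),
    "synthetic": set(_DEFAULT_CONFIG["synthetic"]),
    "restraints": set(_DEFAULT_CONFIG["restraints"]),
    "annealing": set(_DEFAULT_CONFIG["annealing"]),
    "pruning": set(_DEFAULT_CONFIG["pruning"]),
    "production": set(_DEFAULT_CONFIG["production"]),
    "clustering": set(_DEFAULT_CONFIG["clustering"]),
    "analysis": set(_DEFAULT_CONFIG["analysis"]),
    "rdf": set(_DEFAULT_CONFIG["rdf"]),
}


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_CONFIG)))

    def __post_init__(self):
        self._check(self.data, "")
        if self.data.get("schema_version") != 1:
            raise ConfigError(
                f"unsupported schema_version {self.data.get('schema_version')!r}"
            )

    def _check(self, block: dict, prefix: str) -> None:
        allowed = _ALLOWED_KEYS.get(prefix)
        if allowed is None:
            return
        unknown = set(block) - allowed
        if unknown:
            raise ConfigError(
                f"unknown config key(s) {sorted(unknown)} in section {prefix or 'root'!r}"
            )
        for k, v in block.items():
            if isinstance(v, dict):
                self._check(v, k)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        data = json.loads(json.dumps(_DEFAULT_CONFIG))
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(data.get(key), dict):
                data[key].update(val)
            else:
                data[key] = val
        return cls(data)

    def __getitem__(self, key):
        return self.data[key]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()

    def schedule(self) -> AnnealSchedule:
        name = self.data["annealing"]["schedule"]
        spp = int(self.data["annealing"]["steps_per_ps"])
        if name == "gas_phase_sa":
            return AnnealSchedule.gas_phase_sa(steps_per_ps=spp)
        if name == "solvent_heatup":
            return AnnealSchedule.solvent_heatup(steps_per_ps=spp)
        if isinstance(name, list):
            return AnnealSchedule(tuple(tuple(s) for s in name), steps_per_ps=spp)
        raise ConfigError(f"unknown schedule {name!r}")

    def rdf_density(self) -> float:
        d = self.data["rdf"]["density"]
        if d == "water":
            return WATER_NUMBER_DENSITY
        if d == "DMSO":
            return DMSO_NUMBER_DENSITY
        return float(d)


# -- pipeline ---------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _constant_t_production(topology, start, temperature, n_steps, stride, seed):
    """Constant-temperature torsional MC production stand-in; returns a
    Trajectory sampled every ``stride`` accepted-or-not steps."""
    # run as a sequence of short constant-T schedules to reuse run_annealing
    frames = []
    state = start
    chunk = max(1, stride)
    n_chunks = max(1, n_steps // chunk)
    for c in range(n_chunks):
        sched = AnnealSchedule(((temperature, 1.0),), steps_per_ps=chunk)
        res = run_annealing(
            topology, None, sched, seed=seed + c, start=state, replica_id=c
        )
        state = res.final_torsions
        frames.append(res.final_conformation.coords)
    return Trajectory(topology, np.stack(frames))


def run_pipeline(
    cfg: PipelineConfig, outdir, force: bool = False
) -> dict:
    """Execute the full desk-scale pipeline; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg.config_hash():
            log.info("pipeline already complete for this config; use force to re-run")
            return old

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": int(cfg["seed"]),
        "files": {},
    }

    def register(name: str, path: Path):
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    stage = "build"
    try:
        seed = int(cfg["seed"])
        topology = parse_sequence(cfg["sequence"])
        template = template_torsions(cfg["synthetic"]["template"], topology)
        template_conf = build_conformation(topology, template)
        pdb = out / "template.pdb"
        write_pdb(pdb, topology, [template_conf], remarks=["synthetic template"])
        register("template_pdb", pdb)

        stage = "peaks"
        peaks = forward_roesy(
            template_conf,
            max_distance=float(cfg["synthetic"]["max_noe_distance"]),
            sigma_log=float(cfg["synthetic"]["roesy_sigma_log"]),
            seed=seed,
        )
        peaks_path = out / "roesy_peaks.tsv"
        write_peak_table(peaks_path, peaks)
        register("roesy_peaks", peaks_path)

        stage = "restraints"
        dists = peaks_to_distances(peaks)
        rset = distances_to_restraints(
            dists,
            k=float(cfg["restraints"]["force_constant"]),
            slack=float(cfg["restraints"]["slack"]),
        )
        rs_path = out / "restraints_initial.tsv"
        write_restraint_table(rs_path, rset)
        register("restraints_initial", rs_path)

        stage = "refine"
        schedule = cfg.schedule()
        max_it = cfg["pruning"]["max_iterations"]
        pruning = PruningConfig(
            penalty_ceiling=float(cfg["pruning"]["penalty_ceiling"]),
            penalty_statistic=cfg["pruning"]["statistic"],
            max_iterations=int(max_it) if max_it else None,
        )
        refined = refine(
            topology, rset, schedule,
            cfg=pruning,
            n_replicas=int(cfg["annealing"]["n_replicas"]),
            base_seed=seed + 1,
        )
        rs_final = out / "restraints_refined.tsv"
        write_restraint_table(rs_final, refined.restraints)
        register("restraints_refined", rs_final)
        (out / "refinement_report.json").write_text(refined.report())
        register("refinement_report", out / "refinement_report.json")
        manifest["refinement_converged"] = refined.converged

        stage = "representative"
        finals = Trajectory.from_conformations(
            [r.final_conformation for r in refined.results]
        )
        n_rep_clusters = min(
            int(cfg["clustering"]["n_clusters"]), finals.n_frames
        )
        sa_clusters = cluster_frames(finals, n_rep_clusters)
        rep_frame = int(sa_clusters.representatives[0])
        rep_conf = finals.frame(rep_frame)
        rep_path = out / "sa_representative.pdb"
        write_pdb(rep_path, topology, [rep_conf], remarks=["SA main-cluster medoid"])
        register("sa_representative", rep_path)
        sa_finals_path = out / "sa_finals.pdb"
        write_pdb(sa_finals_path, topology, list(finals.coords))
        register("sa_finals", sa_finals_path)

        stage = "production"
        prod = cfg["production"]
        start_state = measure_torsions(rep_conf)
        traj = _constant_t_production(
            topology, start_state,
            float(prod["temperature"]), int(prod["n_steps"]),
            int(prod["stride"]), seed + 7000,
        )
        traj_path = out / "production.pdb"
        write_pdb(traj_path, topology, list(traj.coords))
        register("production_trajectory", traj_path)

        stage = "analysis"
        win = traj.with_window_fraction(
            float(cfg["analysis"]["window_first_fraction"])
        )
        rmsd = rmsd_series(win, rep_conf)
        rog = rog_series(win)
        series = pd.DataFrame(
            {"frame": win.window_indices(), "rmsd": rmsd, "rog": rog}
        )
        series_path = out / "series.tsv"
        series.to_csv(series_path, sep="\t", index=False)
        register("series", series_path)

        n_clusters = min(int(cfg["clustering"]["n_clusters"]),
                         len(win.window_indices()))
        clusters = cluster_frames(win, n_clusters)
        merged = merge_similar_clusters(
            clusters, win, threshold=float(cfg["clustering"]["merge_threshold"])
        )
        cluster_report = {
            "populations": merged.populations.tolist(),
            "representative_frames": merged.representatives.tolist(),
            "merge_log": merged.merge_log,
            "linkage": merged.linkage,
        }
        cl_path = out / "clusters.json"
        cl_path.write_text(json.dumps(cluster_report, indent=2))
        register("clusters", cl_path)
        main_rep = win.frame(win.window_indices()[merged.representatives[0]])
        main_rep_path = out / "main_representative.pdb"
        write_pdb(main_rep_path, topology, [main_rep])
        register("main_representative", main_rep_path)

        stage = "summary"
        torsion_table = [
            {
                "label": topology.residue_at(pos).label,
                "phi": round(phi, 1),
                "psi": round(psi, 1),
            }
            for pos, phi, psi in measure_torsions(main_rep).entries
        ]
        summary = {
            "molecule": cfg["molecule_id"],
            "solvent": cfg["solvent"],
            "populations": merged.populations.tolist(),
            "representative_torsions": torsion_table,
            "rmsd_mean": float(np.mean(rmsd)),
            "rmsd_sd": float(np.std(rmsd)),
            "rog_mean": float(np.mean(rog)),
            "rog_sd": float(np.std(rog)),
            "refinement": {
                "converged": refined.converged,
                "iterations": refined.iterations,
                "n_active_restraints": len(refined.restraints.active),
            },
        }
        sm_path = out / "summary.json"
        sm_path.write_text(json.dumps(summary, indent=2))
        register("summary", sm_path)
    except (ConfigError, ValueError) as err:
        raise
    except Exception as err:  # preserve partial artifacts, name the stage
        raise StageError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def summarize(bundle_dir) -> dict[str, pd.DataFrame]:
    """Summary tables from a completed pipeline bundle."""
    out = Path(bundle_dir)
    sm_path = out / "summary.json"
    if not sm_path.exists():
        raise FileNotFoundError(f"missing stage output: {sm_path}")
    summary = json.loads(sm_path.read_text())
    populations = pd.DataFrame(
        {
            "molecule": summary["molecule"],
            "solvent": summary["solvent"],
            "cluster": range(len(summary["populations"])),
            "population": summary["populations"],
        }
    )
    torsions = pd.DataFrame(summary["representative_torsions"])
    stats = pd.DataFrame(
        [
            {
                "metric": "rmsd",
                "mean": summary["rmsd_mean"],
                "sd": summary["rmsd_sd"],
            },
            {
                "metric": "rog",
                "mean": summary["rog_mean"],
                "sd": summary["rog_sd"],
            },
        ]
    )
    return {"populations": populations, "torsions": torsions, "stats": stats}
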