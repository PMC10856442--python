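"""Campaign enumeration, per-run execution and replicate aggregation.

A campaign is the Cartesian product of oligomer models, raft types and
replicate indices; each run gets a deterministic id and a per-run seed
derived from the campaign master seed by stable hashing of the run id, so
replicates are independent but the whole campaign is reproducible. Runs
execute every analysis stage on synthetic fixtures (or user-supplied
trajectories); failures are isolated per run.
"""

from __future__ import annotations

import json
import traceback
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, domains, energetics, order, protein, synthetic
from .core import MoleculeType, Trajectory
from .sequences import OLIGOMERS, oligomer_residue_count

__all__ = [
    "CampaignConfig",
    "ResultBundle",
    "enumerate_campaign",
    "campaign_totals",
    "run_single",
    "run_pipeline",
    "aggregate_replicates",
]

#: CG water diffuses ~4x faster than real water; effective real time factor
CG_TIME_SPEEDUP = 4.0


@dataclass
class CampaignConfig:
    """Study layout plus every analysis threshold, with standard defaults."""

    oligomers: list[str] = field(default_factory=lambda: ["1tam", "2tam"])
    rafts: list[str] = field(default_factory=lambda: ["PS", "GM"])
    replicates: int = 3
    scale: int = 8                  # fixture reduction factor (1 = full scale)
    sim_length: float = 15.0        # per-run CG simulated time, us
    n_frames: int = 30
    window_cg: float = 5.0          # analysis window: last 5 us of CG
    d_domain: float = 0.5
    d_shell: float = 0.5
    d_contact: float = 2.0
    d_bind: float = 0.6
    energy_cutoff: float = 1.2
    ss_fractions: tuple = (0.25, 0.2, 0.15, 0.4)  # beta, alpha, turn, random
    master_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        for name in ("d_domain", "d_shell", "d_contact", "d_bind", "energy_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for o in self.oligomers:
            if o not in OLIGOMERS:
                raise ValueError(f"unknown oligomer {o!r}")

    @classmethod
    def load(cls, path: str | Path) -> "CampaignConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "ss_fractions" in d:
            d["ss_fractions"] = tuple(d["ss_fractions"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["ss_fractions"] = list(d["ss_fractions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def run_seed(run_id: str, master_seed: int) -> int:
    return (zlib.crc32(run_id.encode()) ^ master_seed) % (2 ** 31)


def enumerate_campaign(config: CampaignConfig) -> pd.DataFrame:
    """Run table: oligomers x rafts x replicates with ids and seeds."""
    rows = []
    for olig in config.oligomers:
        for raft in config.rafts:
            for rep in range(1, config.replicates + 1):
                rid = f"{olig}-{raft}-r{rep}"
                rows.append({"run_id": rid, "oligomer": olig, "raft": raft,
                             "replicate": rep,
                             "seed": run_seed(rid, config.master_seed)})
    return pd.DataFrame(rows, columns=["run_id", "oligomer", "raft",
                                       "replicate", "seed"])


def campaign_totals(config: CampaignConfig) -> dict:
    """Campaign arithmetic: run count, total simulated and effective real time."""
    n = len(config.oligomers) * len(config.rafts) * config.replicates
    total = n * config.sim_length
    return {"n_runs": n, "total_cg_time": total,
            "effective_real_time": total * CG_TIME_SPEEDUP}


def _synthesize_run(config: CampaignConfig, oligomer: str, raft: str,
                    seed: int) -> Trajectory:
    rng = np.random.default_rng(seed)
    raft_spec = synthetic.RaftSpec.from_raft_type(raft, scale=config.scale,
                                                  seed=int(rng.integers(2 ** 31)))
    system = synthetic.build_raft(raft_spec)
    system = synthetic.assemble_complex(system, oligomer)
    spacing = config.sim_length / config.n_frames
    # oligomers bind within the first ~8 us in every replicate
    t_bind = float(rng.uniform(0.5, min(8.0, config.sim_length - config.window_cg)))
    traj_spec = synthetic.TrajectorySpec(
        n_frames=config.n_frames, frame_spacing=spacing, t_bind=t_bind,
        tilt_target=None, seed=int(rng.integers(2 ** 31)))
    return synthetic.generate_binding_trajectory(system, traj_spec)


def run_single(config: CampaignConfig, oligomer: str, raft: str, seed: int,
               traj: Trajectory | None = None) -> dict[str, pd.DataFrame]:
    """Execute every analysis stage for one run; returns named tidy tables."""
    if traj is None:
        traj = _synthesize_run(config, oligomer, raft, seed)
    system = traj.system
    table = synthetic.emit_forcefield_table()
    out: dict[str, pd.DataFrame] = {}

    comp = domains.domain_composition([traj], window=config.window_cg,
                                      d_domain=config.d_domain)
    out["domain_composition"] = comp.table

    lipid_types = [t for t in (MoleculeType.DPPC, MoleculeType.DLPC,
                               MoleculeType.CHOL, MoleculeType.POPS,
                               MoleculeType.GM1)
                   if system.atoms_of_type(t).size]
    prot = system.protein_atom_indices()
    bind_rows, mind_frames, cont_frames = [], [], []
    for lt in lipid_types:
        ms = binding.mindist_series(traj, prot, lt)
        cs = binding.contact_count_series(traj, prot, lt, config.d_contact)
        t_mind = binding.detect_binding_time(ms, config.d_bind, "persistent_suffix")
        t_cont = binding.detect_binding_time(cs, mode="contact_onset")
        bind_rows.append({"target": lt.value,
                          "t_bind_mindist": np.nan if t_mind is None else t_mind,
                          "t_bind_contacts": np.nan if t_cont is None else t_cont})
        mind_frames.append(ms.to_frame())
        cont_frames.append(cs.to_frame())
    out["binding_times"] = pd.DataFrame(bind_rows)
    out["mindist_series"] = pd.concat(mind_frames, ignore_index=True)
    out["contact_series"] = pd.concat(cont_frames, ignore_index=True)

    monomers = sorted({r.monomer_type for r in system.protein_records})
    spec_frames = []
    for mono in monomers:
        for lt in lipid_types:
            sp = binding.mindist_spectrum([traj], mono, lt, window=config.window_cg)
            spec_frames.append(sp.to_frame())
    out["mindist_spectra"] = pd.concat(spec_frames, ignore_index=True)

    shell = binding.classify_annular_shell(system, traj.frames[-1], config.d_shell)
    out["annular_shell"] = shell.to_frame()

    prof_frames = []
    for lt in lipid_types:
        if lt is MoleculeType.CHOL:
            chains = ["sn1"]
        else:
            chains = ["sn1", "sn2"]
        for ch in chains:
            for sh in ("AL", "nAL"):
                try:
                    prof = order.order_profile([traj], lt, ch, shell=sh,
                                               window=config.window_cg,
                                               d_shell=config.d_shell)
                except ValueError:
                    continue  # empty shell for this type
                prof_frames.append(prof.to_frame())
    out["order_profiles"] = (pd.concat(prof_frames, ignore_index=True)
                             if prof_frames else pd.DataFrame())

    inter = energetics.interchain_energy([traj], table, window=config.window_cg,
                                         cutoff=config.energy_cutoff)
    out["interchain_energy"] = (inter.to_frame() if inter is not None
                                else pd.DataFrame())
    out["protein_lipid_energy"] = energetics.protein_lipidtype_energy(
        [traj], table, lipid_types, window=config.window_cg,
        cutoff=config.energy_cutoff)

    n_res = oligomer_residue_count(oligomer)
    ss_spec = synthetic.SSTraceSpec(config.ss_fractions, n_res, traj.n_frames,
                                    seed=seed + 1)
    trace = synthetic.generate_ss_trace(ss_spec)
    out["ss_counts"] = protein.ss_summary([trace])

    cmap = protein.residue_contact_map(traj, window=config.window_cg)
    mean_df, sd_df = cmap.to_frames()
    out["contact_map_mean"] = mean_df
    out["contact_map_sd"] = sd_df
    return out


@dataclass
class ResultBundle:
    config: CampaignConfig
    runs: dict[str, dict[str, pd.DataFrame]]
    failures: dict[str, str]
    run_table: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.save(outdir / "config.yaml")
        self.run_table.to_csv(outdir / "runs.tsv", sep="\t", index=False)
        manifest = {"runs": {}, "failures": self.failures}
        for rid, tables in self.runs.items():
            rdir = outdir / rid
            rdir.mkdir(exist_ok=True)
            manifest["runs"][rid] = sorted(tables)
            for name, df in tables.items():
                use_index = name.startswith("contact_map")
                df.to_csv(rdir / f"{name}.tsv", sep="\t", index=use_index)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: CampaignConfig,
                 inputs: dict[str, Trajectory] | None = None) -> ResultBundle:
    """Run the full campaign; per-run failures are logged, not fatal."""
    run_table = enumerate_campaign(config)
    runs: dict[str, dict[str, pd.DataFrame]] = {}
    failures: dict[str, str] = {}
    for row in run_table.itertuples():
        traj = (inputs or {}).get(row.run_id)
        try:
            runs[row.run_id] = run_single(config, row.oligomer, row.raft,
                                          int(row.seed), traj)
        except Exception:
            failures[row.run_id] = traceback.format_exc(limit=5)
    return ResultBundle(config, runs, failures, run_table)


def _sem(x: pd.Series) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def aggregate_replicates(bundle: ResultBundle) -> dict[tuple[str, str], dict[str, pd.DataFrame]]:
    """Mean +/- SEM over replicates, per (oligomer, raft) condition.

    Every tidy per-run table is grouped by its non-numeric key columns;
    numeric columns aggregate to ``<col>`` (mean) and ``<col>_sem``.
    Conditions with no completed run are flagged absent (empty dict).
    """
    out: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    rt = bundle.run_table
    for (olig, raft), grp in rt.groupby(["oligomer", "raft"], sort=False):
        rids = [r for r in grp["run_id"] if r in bundle.runs]
        if not rids:
            out[(olig, raft)] = {}
            continue
        cond: dict[str, pd.DataFrame] = {}
        table_names = set().union(*(bundle.runs[r] for r in rids))
        for name in sorted(table_names):
            if name.startswith("contact_map"):
                mats = [bundle.runs[r][name].to_numpy() for r in rids
                        if name in bundle.runs[r]]
                ref = bundle.runs[rids[0]][name]
                cond[name] = pd.DataFrame(np.mean(mats, axis=0),
                                          index=ref.index, columns=ref.columns)
                continue
            frames = [bundle.runs[r][name] for r in rids
                      if name in bundle.runs[r] and not bundle.runs[r][name].empty]
            if not frames:
                cond[name] = pd.DataFrame()
                continue
            cat = pd.concat(frames, ignore_index=True)
            keys = [c for c in cat.columns
                    if not pd.api.types.is_numeric_dtype(cat[c])]
            vals = [c for c in cat.columns if c not in keys]
            if keys:
                g = cat.groupby(keys, sort=False)[vals]
                agg = g.mean().reset_index()
                sems = g.agg(_sem).reset_index(drop=True)
            else:
                agg = cat[vals].mean().to_frame().T
                sems = cat[vals].agg(_sem).to_frame().T
            for c in vals:
                agg[f"{c}_sem"] = sems[c].values
            cond[name] = agg
        out[(olig, raft)] = cond
    return out
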