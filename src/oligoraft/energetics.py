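"""Cutoff-bounded nonbonded interaction energies between atom groups.

Pairwise 12-6 Lennard-Jones plus vacuum Coulomb, summed over all
cross-group atom pairs within a plain truncation cutoff (default 1.2 nm,
no shift/switch, no long-range corrections): the quantities are raw
interaction energies, not free energies. Lorentz-Berthelot combining
(arithmetic sigma, geometric epsilon); the electrostatic prefactor
f = 1/(4 pi eps0) = 138.935458 kJ mol^-1 nm e^-2. Truncation makes the
energy a discontinuous but deterministic function of positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Frame, MoleculeType, System, Trajectory
from .geometry import periodic_tree, min_image_distance

__all__ = [
    "ForceFieldTable",
    "EnergyBreakdown",
    "ParameterError",
    "pair_lj",
    "pair_coulomb",
    "group_interaction_energy",
    "interchain_energy",
    "protein_lipidtype_energy",
    "F_ELECTRO",
]

#: 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (CODATA-derived)
F_ELECTRO = 138.935458


class ParameterError(KeyError):
    pass


@dataclass
class ForceFieldTable:
    """Per-atom-type sigma (nm), epsilon (kJ/mol) and partial charge (e)."""

    sigma: dict[str, float]
    epsilon: dict[str, float]
    charge: dict[str, float]
    f_electro: float = F_ELECTRO
    combining_rule: str = "lorentz-berthelot"

    def __post_init__(self):
        for k, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{k}] must be positive")
        for k, e in self.epsilon.items():
            if e < 0:
                raise ValueError(f"epsilon[{k}] must be non-negative")
        if self.f_electro <= 0:
            raise ValueError("f_electro must be positive")

    def params(self, type_key: str) -> tuple[float, float, float]:
        try:
            return (self.sigma[type_key], self.epsilon[type_key],
                    self.charge[type_key])
        except KeyError:
            raise ParameterError(f"atom type {type_key!r} missing from table") from None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "sigma": self.sigma, "epsilon": self.epsilon, "charge": self.charge,
            "f_electro": self.f_electro, "combining_rule": self.combining_rule,
        }, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ForceFieldTable":
        d = yaml.safe_load(Path(path).read_text())
        return cls(sigma=d["sigma"], epsilon=d["epsilon"], charge=d["charge"],
                   f_electro=d.get("f_electro", F_ELECTRO),
                   combining_rule=d.get("combining_rule", "lorentz-berthelot"))

    def molecule_charge(self, system: System, molecule_id: int) -> float:
        idx = system.molecule_atoms(molecule_id)
        return float(sum(self.charge[k] for k in system.type_keys[idx]))


@dataclass
class EnergyBreakdown:
    group_pair: str
    e_lj: float                   # kJ/mol
    e_coulomb: float              # kJ/mol
    cutoff: float = 1.2
    n_pairs: int = 0
    sem_lj: float = float("nan")
    sem_coulomb: float = float("nan")

    @property
    def e_total(self) -> float:
        return self.e_lj + self.e_coulomb

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group_pair": self.group_pair, "e_lj": self.e_lj,
            "e_coulomb": self.e_coulomb, "e_total": self.e_total,
            "sem_lj": self.sem_lj, "sem_coulomb": self.sem_coulomb,
            "cutoff": self.cutoff}])


def pair_lj(r: float, sigma_ij: float, epsilon_ij: float) -> float:
    """12-6 Lennard-Jones energy: 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    if np.any(np.asarray(r) <= 0):
        raise ZeroDivisionError("LJ energy is singular at r = 0")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


def pair_coulomb(r: float, q_i: float, q_j: float, f: float = F_ELECTRO) -> float:
    """Vacuum Coulomb energy f q_i q_j / r."""
    if np.any(np.asarray(r) <= 0):
        raise ZeroDivisionError("Coulomb energy is singular at r = 0")
    return f * q_i * q_j / r


def group_interaction_energy(system: System, frame: Frame,
                             group_a: np.ndarray, group_b: np.ndarray,
                             table: ForceFieldTable, cutoff: float = 1.2,
                             pair_name: str = "") -> EnergyBreakdown:
    """Sum pair LJ + Coulomb over all cross pairs within the cutoff.

    Groups must be disjoint atom-index arrays; distances use the lateral
    minimum image. Pairs beyond the cutoff contribute nothing (plain
    truncation).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    pa = np.array([table.params(k) for k in system.type_keys[group_a]])
    pb = np.array([table.params(k) for k in system.type_keys[group_b]])
    tree = periodic_tree(frame.positions[group_b], frame.box,
                         other=frame.positions[group_a])
    neigh = tree.tree.query_ball_point(tree.wrap(frame.positions[group_a]), cutoff)
    e_lj = e_c = 0.0
    n_pairs = 0
    for i, js in enumerate(neigh):
        if not js:
            continue
        js = np.asarray(js, dtype=int)
        r = min_image_distance(frame.positions[group_a[i]],
                               frame.positions[group_b[js]], frame.box)
        r = np.atleast_1d(r)
        sig = 0.5 * (pa[i, 0] + pb[js, 0])
        eps = np.sqrt(pa[i, 1] * pb[js, 1])
        e_lj += float(np.sum(pair_lj(r, sig, eps)))
        e_c += float(np.sum(table.f_electro * pa[i, 2] * pb[js, 2] / r))
        n_pairs += len(js)
    return EnergyBreakdown(pair_name, e_lj, e_c, cutoff, n_pairs)


def _window_average(per_frame: list[tuple[float, float]]):
    arr = np.asarray(per_frame)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def interchain_energy(replicates: list[Trajectory], table: ForceFieldTable,
                      window: float | None = None,
                      cutoff: float = 1.2) -> EnergyBreakdown | None:
    """Total interchain protein-protein interaction energy of the oligomer.

    Sums the group energy over all unordered distinct chain pairs, averages
    over window frames per replicate, then across replicates with SEM.
    Returns None for a monomer (no chain pairs to evaluate).
    """
    per_rep = []
    for traj in replicates:
        system = traj.system
        chains = system.protein_chain_ids()
        if len(chains) < 2:
            return None
        sub = traj if window is None else traj.last_window(window)
        idx = {c: system.protein_atom_indices(c) for c in chains}
        per_frame = []
        for fr in sub.frames:
            lj = co = 0.0
            for a, bnd in itertools.combinations(chains, 2):
                e = group_interaction_energy(system, fr, idx[a], idx[bnd],
                                             table, cutoff)
                lj += e.e_lj
                co += e.e_coulomb
            per_frame.append((lj, co))
        per_rep.append(_window_average(per_frame))
    arr = np.asarray(per_rep)
    n = arr.shape[0]
    sems = (arr.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else (np.nan, np.nan)
    return EnergyBreakdown("interchain", float(arr[:, 0].mean()),
                           float(arr[:, 1].mean()), cutoff,
                           sem_lj=float(sems[0]), sem_coulomb=float(sems[1]))


def protein_lipidtype_energy(replicates: list[Trajectory], table: ForceFieldTable,
                             lipid_types=None, window: float | None = None,
                             cutoff: float = 1.2) -> pd.DataFrame:
    """Protein-lipid interaction energy resolved per lipid type.

    One row per lipid type with time-averaged LJ, Coulomb and total energy
    (kJ/mol) and the SEM across replicates.
    """
    system0 = replicates[0].system
    if lipid_types is None:
        lipid_types = [t for t in (MoleculeType.DPPC, MoleculeType.DLPC,
                                   MoleculeType.CHOL, MoleculeType.POPS,
                                   MoleculeType.GM1)
                       if system0.atoms_of_type(t).size]
    rows = []
    for lt in lipid_types:
        lt = MoleculeType(lt)
        per_rep = []
        for traj in replicates:
            system = traj.system
            prot = system.protein_atom_indices()
            lip = system.atoms_of_type(lt)
            if prot.size == 0 or lip.size == 0:
                continue
            sub = traj if window is None else traj.last_window(window)
            per_frame = [
                (e.e_lj, e.e_coulomb)
                for e in (group_interaction_energy(system, fr, prot, lip,
                                                   table, cutoff)
                          for fr in sub.frames)
            ]
            per_rep.append(_window_average(per_frame))
        if not per_rep:
            continue
        arr = np.asarray(per_rep)
        n = arr.shape[0]
        sems = (arr.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else (np.nan, np.nan)
        rows.append({"lipid_type": lt.value, "e_lj": float(arr[:, 0].mean()),
                     "e_coulomb": float(arr[:, 1].mean()),
                     "e_total": float(arr.sum(axis=1).mean()),
                     "sem_lj": float(sems[0]), "sem_coulomb": float(sems[1]),
                     "cutoff": cutoff})
    return pd.DataFrame(rows)
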