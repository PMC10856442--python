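"""Acyl-chain orientational order profiles.

The order parameter reported here is the second-Legendre average of the
local chain-axis tilt: for interior carbon n the axis is the vector from
carbon n-1 to carbon n+1 and S(n) = <(3 cos^2 theta_n - 1)/2> with theta_n
measured against the bilayer normal (the z axis). This is the
molecular-axis construction from three sequentially connected carbons — not
the deuterium order parameter S_CD, which differs in sign and scale.
S(n) is defined for carbons 2 .. N-1 and bounded in [-0.5, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChainDefinition, Frame, MoleculeType, System, Trajectory, TopologyError
from .geometry import min_image_displacement
from .binding import classify_annular_shell

__all__ = ["OrderProfile", "carbon_axis_angles", "order_profile"]


@dataclass
class OrderProfile:
    """S(n) per interior carbon with SEM, keyed by lipid, chain and shell."""

    lipid_type: str
    chain_label: str
    shell: str                    # "AL" | "nAL" | "all"
    carbons: np.ndarray           # interior carbon numbers 2..N-1
    values: np.ndarray
    sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon": self.carbons, "order_parameter": self.values,
                             "sem": self.sem, "lipid_type": self.lipid_type,
                             "chain": self.chain_label, "shell": self.shell})


def _chain_indices(system: System, molecule_id: int, chain: ChainDefinition) -> np.ndarray:
    idx = system.molecule_atoms(molecule_id)
    names = system.atom_names[idx]
    sel = []
    for nm in chain.carbon_atom_names:
        hit = idx[names == nm]
        if hit.size == 0:
            raise TopologyError(
                f"molecule {molecule_id}: missing chain atom {nm!r}")
        sel.append(int(hit[0]))
    return np.array(sel, dtype=int)


def carbon_axis_angles(system: System, molecule_id: int, chain: ChainDefinition,
                       frame: Frame) -> np.ndarray:
    """Polar tilt of each interior carbon's local axis against the normal.

    The axis of carbon n is position(n+1) - position(n-1) under the lateral
    minimum image; the returned angles are folded into [0, pi/2] (the order
    parameter is insensitive to the axis sign).
    """
    sel = _chain_indices(system, molecule_id, chain)
    p = frame.positions[sel]
    axes = np.array([min_image_displacement(p[i - 1], p[i + 1], frame.box)
                     for i in range(1, len(sel) - 1)])
    norm = np.linalg.norm(axes, axis=1)
    cos = np.abs(axes[:, 2]) / np.where(norm > 0, norm, np.inf)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _frame_chain_cos2(system: System, frame: Frame, mols: np.ndarray,
                      chain: ChainDefinition) -> np.ndarray:
    """(n_mols, n_interior) squared cosines, vectorised over molecules."""
    idx = np.array([_chain_indices(system, m, chain) for m in mols])
    p = frame.positions[idx]                     # (M, C, 3)
    d = p[:, 2:, :] - p[:, :-2, :]
    for ax in (0, 1):                            # lateral minimum image
        d[:, :, ax] -= frame.box[ax] * np.round(d[:, :, ax] / frame.box[ax])
    norm2 = np.sum(d * d, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(norm2 > 0, d[:, :, 2] ** 2 / norm2, 0.0)
    return cos2


def order_profile(replicates: list[Trajectory], lipid_type: MoleculeType | str,
                  chain_label: str = "sn1", shell: str = "all",
                  window: float | None = None,
                  d_shell: float = 0.5) -> OrderProfile:
    """Order profile averaged over molecules and window frames, SEM across
    replicates.

    ``shell`` restricts to annular ("AL") or non-annular ("nAL") lipids,
    re-evaluated per frame against the protein; "all" applies no filter.
    """
    lipid_type = MoleculeType(lipid_type)
    per_rep = []
    carbons = None
    for traj in replicates:
        sub = traj if window is None else traj.last_window(window)
        system = sub.system
        chain = system.chain_definitions.get((lipid_type, chain_label))
        if chain is None:
            raise TopologyError(
                f"no chain definition for {lipid_type.value}/{chain_label}")
        mols = system.molecules_of_type(lipid_type)
        if mols.size == 0:
            raise ValueError(f"no {lipid_type.value} molecules")
        acc = []
        for fr in sub.frames:
            keep = mols
            if shell in ("AL", "nAL"):
                shell_assign = classify_annular_shell(system, fr, d_shell)
                members = shell_assign.al if shell == "AL" else shell_assign.nal
                keep = np.array([m for m in mols if int(m) in members], dtype=int)
                if keep.size == 0:
                    continue
            acc.append(_frame_chain_cos2(system, fr, keep, chain))
        if not acc:
            raise ValueError(
                f"no {lipid_type.value} molecules pass the {shell} filter")
        cos2 = np.vstack(acc)                    # (frames*mols, n_interior)
        per_rep.append((3.0 * cos2.mean(axis=0) - 1.0) / 2.0)
        carbons = np.arange(2, 2 + cos2.shape[1])
    arr = np.vstack(per_rep)
    mean = arr.mean(axis=0)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.full(arr.shape[1], np.nan))
    return OrderProfile(lipid_type.value, chain_label, shell, carbons, mean, sem)
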