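"""Lipid phase-domain classification (Lo / Ld / Lod) and compositions.

A DPPC with any atom within the proximity threshold (default 0.5 nm,
inclusive) of any DLPC atom sits at the phase boundary and is labelled Lod,
otherwise Lo; symmetrically a DLPC contacting DPPC is Lod, otherwise Ld.
Cholesterol inherits the label of the PC phase it touches: one phase class
-> that class, two or more -> Lod (it straddles the boundary), none -> the
class of the nearest PC molecule. Distances are 3D minimum-image over both
leaflets; inter-leaflet contacts are geometrically excluded by bilayer
thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, MoleculeType, System, Trajectory
from .geometry import periodic_tree

__all__ = [
    "DomainAssignment",
    "DomainComposition",
    "classify_pc",
    "classify_chol",
    "classify_frame",
    "frame_composition",
    "domain_composition",
]

LO, LD, LOD = "Lo", "Ld", "Lod"


@dataclass
class DomainAssignment:
    """Per-frame labels: lipid molecule_id -> {Lo, Ld, Lod}."""

    labels: dict[int, str]
    d_domain: float = 0.5


def _type_atoms(system: System, lt: MoleculeType):
    idx = system.atoms_of_type(lt)
    return idx, system.molecule_ids[idx]


def classify_pc(system: System, frame: Frame, d_domain: float = 0.5) -> dict[int, str]:
    """Label every DPPC and DLPC molecule as Lo, Ld or Lod."""
    dppc_idx, dppc_mol = _type_atoms(system, MoleculeType.DPPC)
    dlpc_idx, dlpc_mol = _type_atoms(system, MoleculeType.DLPC)
    if dppc_idx.size + dlpc_idx.size == 0:
        raise ValueError("system contains no PC lipids")
    labels: dict[int, str] = {}
    if dppc_idx.size and dlpc_idx.size:
        tree = periodic_tree(frame.positions[dlpc_idx], frame.box,
                             other=frame.positions[dppc_idx])
        hits = tree.tree.query_ball_point(tree.wrap(frame.positions[dppc_idx]),
                                          d_domain, return_length=True)
        touching = set(dppc_mol[hits > 0].tolist())
        for m in np.unique(dppc_mol):
            labels[int(m)] = LOD if m in touching else LO
        tree2 = periodic_tree(frame.positions[dppc_idx], frame.box,
                              other=frame.positions[dlpc_idx])
        hits2 = tree2.tree.query_ball_point(tree2.wrap(frame.positions[dlpc_idx]),
                                            d_domain, return_length=True)
        touching2 = set(dlpc_mol[hits2 > 0].tolist())
        for m in np.unique(dlpc_mol):
            labels[int(m)] = LOD if m in touching2 else LD
    else:
        for m in np.unique(dppc_mol):
            labels[int(m)] = LO
        for m in np.unique(dlpc_mol):
            labels[int(m)] = LD
    return labels


def classify_chol(system: System, frame: Frame, pc_labels: dict[int, str],
                  d_domain: float = 0.5) -> dict[int, str]:
    """Label every CHOL molecule from the PC phases it contacts."""
    chol_idx, chol_mol = _type_atoms(system, MoleculeType.CHOL)
    if chol_idx.size == 0:
        return {}
    from .core import isin_types
    pc_mask = isin_types(system.molecule_types,
                         (MoleculeType.DPPC, MoleculeType.DLPC))
    pc_idx = np.flatnonzero(pc_mask)
    if pc_idx.size == 0:
        raise ValueError("cannot classify CHOL without PC lipids")
    pc_mols = system.molecule_ids[pc_idx]
    tree = periodic_tree(frame.positions[pc_idx], frame.box,
                         other=frame.positions[chol_idx])
    wrapped = tree.wrap(frame.positions[chol_idx])
    neighbours = tree.tree.query_ball_point(wrapped, d_domain)
    labels: dict[int, str] = {}
    # nearest PC atom per CHOL atom, for the no-contact fallback
    dist, nearest = tree.tree.query(wrapped)
    for m in np.unique(chol_mol):
        rows = np.flatnonzero(chol_mol == m)
        classes = {pc_labels[int(pc_mols[j])]
                   for r in rows for j in neighbours[r]}
        if len(classes) == 1:
            labels[int(m)] = classes.pop()
        elif len(classes) >= 2:
            labels[int(m)] = LOD
        else:
            r_best = rows[int(np.argmin(dist[rows]))]
            labels[int(m)] = pc_labels[int(pc_mols[nearest[r_best]])]
    return labels


def classify_frame(system: System, frame: Frame,
                   d_domain: float = 0.5) -> DomainAssignment:
    """Joint PC + CHOL domain assignment for one frame."""
    pc = classify_pc(system, frame, d_domain)
    chol = classify_chol(system, frame, pc, d_domain)
    return DomainAssignment({**pc, **chol}, d_domain)


def frame_composition(system: System, assignment: DomainAssignment) -> pd.DataFrame:
    """Composition percentages of one frame.

    CHOL percentages are per-domain counts over total CHOL; the PC triple is
    (Lo-DPPC, Ld-DLPC, Lod-PC) over total DPPC + DLPC, where Lod-PC pools
    boundary DPPC and DLPC. Each triple sums to 100.
    """
    labels = assignment.labels
    chol = [m for m in system.molecules_of_type(MoleculeType.CHOL)]
    dppc = [m for m in system.molecules_of_type(MoleculeType.DPPC)]
    dlpc = [m for m in system.molecules_of_type(MoleculeType.DLPC)]
    rows = []
    n_chol = len(chol)
    if n_chol:
        for dom in (LO, LD, LOD):
            pct = 100.0 * sum(labels[int(m)] == dom for m in chol) / n_chol
            rows.append(("CHOL", dom, pct))
    n_pc = len(dppc) + len(dlpc)
    if n_pc:
        lo_dppc = sum(labels[int(m)] == LO for m in dppc)
        ld_dlpc = sum(labels[int(m)] == LD for m in dlpc)
        lod_pc = (sum(labels[int(m)] == LOD for m in dppc)
                  + sum(labels[int(m)] == LOD for m in dlpc))
        rows.extend([("PC", "Lo-DPPC", 100.0 * lo_dppc / n_pc),
                     ("PC", "Ld-DLPC", 100.0 * ld_dlpc / n_pc),
                     ("PC", "Lod-PC", 100.0 * lod_pc / n_pc)])
    return pd.DataFrame(rows, columns=["species", "domain", "percent"])


@dataclass
class DomainComposition:
    """Replicate-averaged domain composition with SEM per entry."""

    table: pd.DataFrame  # species, domain, percent, sem, n_replicates


def domain_composition(replicates: list[Trajectory], window: float | None = None,
                       d_domain: float = 0.5) -> DomainComposition:
    """Time-average compositions per replicate, then average across replicates.

    ``window`` keeps only frames within that duration of each trajectory's
    end (the equilibrated analysis window); None uses every frame. The SEM
    is across replicates (absent for a single replicate).
    """
    per_rep = []
    for traj in replicates:
        sub = traj if window is None else traj.last_window(window)
        frames = [frame_composition(sub.system, classify_frame(sub.system, fr, d_domain))
                  for fr in sub.frames]
        rep = pd.concat(frames).groupby(["species", "domain"], sort=False,
                                        as_index=False)["percent"].mean()
        per_rep.append(rep)
    allrep = pd.concat(per_rep)
    g = allrep.groupby(["species", "domain"], sort=False)["percent"]
    out = g.mean().reset_index()
    n = len(per_rep)
    out["sem"] = (g.std(ddof=1) / np.sqrt(n)).values if n > 1 else np.nan
    out["n_replicates"] = n
    return DomainComposition(out)
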