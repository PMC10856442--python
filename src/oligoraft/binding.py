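"""Protein-membrane binding analysis.

Minimum-distance (mindist) kinetics between atom groups, contact counting
within an interaction threshold (default 2 nm), binding-time detection from
the onset of the persistent low-mindist plateau, per-residue time-averaged
mindist spectra, and annular-lipid (AL) shell extraction at the 0.5 nm
proximity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, LIPID_TYPES, MoleculeType, System, Trajectory, isin_types
from .geometry import periodic_tree

__all__ = [
    "MindistSeries",
    "ContactSeries",
    "MindistSpectrum",
    "ShellAssignment",
    "select_atoms",
    "mindist_series",
    "contact_count_series",
    "detect_binding_time",
    "mindist_spectrum",
    "classify_annular_shell",
    "moving_average",
]


class SelectionError(ValueError):
    pass


def select_atoms(system: System, group: str | MoleculeType) -> np.ndarray:
    """Atom indices for a named group.

    ``"protein"`` selects all protein atoms; a :class:`MoleculeType` (or its
    name) selects all atoms of that molecule type.
    """
    if isinstance(group, str) and group.lower() == "protein":
        idx = system.protein_atom_indices()
    else:
        idx = system.atoms_of_type(MoleculeType(group))
    if idx.size == 0:
        raise SelectionError(f"empty selection {group!r}")
    return idx


@dataclass
class MindistSeries:
    times: np.ndarray
    values: np.ndarray            # nm, per frame
    target: str = ""
    resolution_tag: str = "CG"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "mindist": self.values,
                             "target": self.target})


@dataclass
class ContactSeries:
    times: np.ndarray
    counts: np.ndarray            # atom pairs within d_contact, per frame
    d_contact: float = 2.0
    target: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "contacts": self.counts,
                             "target": self.target})


def _frame_mindist(frame: Frame, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    a, b = frame.positions[idx_a], frame.positions[idx_b]
    # query the smaller group against a tree over the larger
    if len(a) > len(b):
        a, b = b, a
    tree = periodic_tree(b, frame.box, other=a)
    d, _ = tree.tree.query(tree.wrap(a))
    return float(np.min(d))


def mindist_series(traj: Trajectory, group_a, group_b) -> MindistSeries:
    """Per-frame minimum over all cross-group atom pairs of the distance."""
    idx_a = group_a if isinstance(group_a, np.ndarray) else select_atoms(traj.system, group_a)
    idx_b = group_b if isinstance(group_b, np.ndarray) else select_atoms(traj.system, group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("empty selection")
    vals = np.array([_frame_mindist(fr, idx_a, idx_b) for fr in traj.frames])
    name = group_b if isinstance(group_b, str) else getattr(group_b, "value", "")
    return MindistSeries(traj.times, vals, str(name), traj.resolution_tag)


def contact_count_series(traj: Trajectory, group_a, group_b,
                         d_contact: float = 2.0) -> ContactSeries:
    """Per-frame count of cross-group atom pairs within ``d_contact`` (inclusive)."""
    if d_contact <= 0:
        raise ValueError("d_contact must be positive")
    idx_a = group_a if isinstance(group_a, np.ndarray) else select_atoms(traj.system, group_a)
    idx_b = group_b if isinstance(group_b, np.ndarray) else select_atoms(traj.system, group_b)
    counts = np.empty(traj.n_frames, dtype=int)
    for k, fr in enumerate(traj.frames):
        tree = periodic_tree(fr.positions[idx_b], fr.box, other=fr.positions[idx_a])
        hits = tree.tree.query_ball_point(tree.wrap(fr.positions[idx_a]),
                                          d_contact, return_length=True)
        counts[k] = int(hits.sum())
    name = group_b if isinstance(group_b, str) else getattr(group_b, "value", "")
    return ContactSeries(traj.times, counts, d_contact, str(name))


def detect_binding_time(series: MindistSeries | ContactSeries,
                        d_bind: float = 0.6,
                        mode: str = "persistent_suffix",
                        dwell_frames: int | None = None) -> float | None:
    """Time of transition from fluctuating to stabilised values.

    ``persistent_suffix`` (for a :class:`MindistSeries`): earliest frame t*
    with value <= d_bind from t* through the trajectory end — the onset of a
    plateau that persists for the rest of the run. With ``dwell_frames`` set,
    the requirement relaxes to the earliest frame followed by that many
    consecutive bound frames (for transiently bound cases).

    ``contact_onset`` (for a :class:`ContactSeries`): earliest frame of the
    trailing run of nonzero contact counts.

    Returns the frame time, or None when no frame qualifies ("unbound").
    """
    if mode == "persistent_suffix":
        v = np.asarray(series.values)
        bound = v <= d_bind
        if dwell_frames is not None:
            k = min(dwell_frames, len(v))
            for i in range(len(v) - k + 1):
                if bound[i:i + k].all():
                    return float(series.times[i])
            return None
        if not bound[-1]:
            return None
        idx = np.flatnonzero(~bound)
        start = int(idx[-1]) + 1 if idx.size else 0
        return float(series.times[start])
    if mode == "contact_onset":
        c = np.asarray(series.counts)
        if c[-1] == 0:
            return None
        idx = np.flatnonzero(c == 0)
        start = int(idx[-1]) + 1 if idx.size else 0
        return float(series.times[start])
    raise ValueError(f"unknown mode {mode!r}")


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with truncated (shrinking) windows at termini."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass
class MindistSpectrum:
    """Per-residue time-, chain- and replicate-averaged minimum distance."""

    residues: np.ndarray          # 1-based residue index
    values: np.ndarray            # nm
    sem: np.ndarray
    target: str = ""
    monomer_type: str = ""
    smoothed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"residue": self.residues, "mindist": self.values, "sem": self.sem,
             "target": self.target, "monomer": self.monomer_type}
        if self.smoothed is not None:
            d["smoothed"] = self.smoothed
        return pd.DataFrame(d)


def _chain_residue_mindists(traj: Trajectory, chain_id: str,
                            idx_target: np.ndarray) -> np.ndarray:
    """(n_frames, n_residues) per-frame minima for one chain."""
    system = traj.system
    idx_chain = system.protein_atom_indices(chain_id)
    res = system.residue_indices[idx_chain]
    n_res = int(res.max())
    out = np.empty((traj.n_frames, n_res))
    for k, fr in enumerate(traj.frames):
        tree = periodic_tree(fr.positions[idx_target], fr.box,
                             other=fr.positions[idx_chain])
        d, _ = tree.tree.query(tree.wrap(fr.positions[idx_chain]))
        for r in range(1, n_res + 1):
            out[k, r - 1] = float(np.min(d[res == r]))
    return out


def mindist_spectrum(replicates: list[Trajectory], monomer_type: str,
                     target, window: float | None = None,
                     smooth: int | None = 5) -> MindistSpectrum:
    """Residue-resolved mindist spectrum for one constituent monomer type.

    Per replicate: per-frame residue minima against the target group,
    averaged over the window frames, then over all chains of the monomer
    type (which share one sequence); the mean and SEM are across replicates.
    ``smooth`` attaches a centred moving-average curve for presentation.
    """
    per_rep = []
    tname = ""
    for traj in replicates:
        sub = traj if window is None else traj.last_window(window)
        system = sub.system
        chains = [r.chain_id for r in system.protein_records
                  if r.monomer_type == monomer_type]
        if not chains:
            raise SelectionError(f"no chains of monomer type {monomer_type!r}")
        lengths = {len(r.sequence) for r in system.protein_records
                   if r.monomer_type == monomer_type}
        if len(lengths) != 1:
            raise ValueError("chains of unequal length in one averaging group")
        idx_t = target if isinstance(target, np.ndarray) else select_atoms(system, target)
        tname = target if isinstance(target, str) else getattr(target, "value", "")
        chain_means = [
            _chain_residue_mindists(sub, c, idx_t).mean(axis=0) for c in chains
        ]
        per_rep.append(np.mean(chain_means, axis=0))
    arr = np.vstack(per_rep)
    mean = arr.mean(axis=0)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.full(arr.shape[1], np.nan))
    residues = np.arange(1, arr.shape[1] + 1)
    smoothed = moving_average(mean, smooth) if smooth else None
    return MindistSpectrum(residues, mean, sem, str(tname), monomer_type, smoothed)


@dataclass
class ShellAssignment:
    """Annular (AL) vs non-annular (nAL) lipid split for one frame."""

    al: set[int]
    nal: set[int]
    d_shell: float = 0.5
    per_type_counts: dict = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float] | None:
        """Per-type share of the AL shell (absent when the shell is empty)."""
        total = sum(self.per_type_counts.values())
        if total == 0:
            return None
        return {t: 100.0 * c / total for t, c in self.per_type_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages or {}
        rows = [(t, c, pct.get(t, np.nan)) for t, c in self.per_type_counts.items()]
        return pd.DataFrame(rows, columns=["lipid_type", "al_count", "al_percent"])


def classify_annular_shell(system: System, frame: Frame,
                           d_shell: float = 0.5) -> ShellAssignment:
    """Assign each lipid to the AL shell iff any of its atoms lies within
    ``d_shell`` of any protein atom (inclusive)."""
    prot = system.protein_atom_indices()
    if prot.size == 0:
        raise SelectionError("no protein present")
    lipid_mask = isin_types(system.molecule_types, LIPID_TYPES)
    lipid_idx = np.flatnonzero(lipid_mask)
    lipid_mols = system.molecule_ids[lipid_idx]
    tree = periodic_tree(frame.positions[prot], frame.box,
                         other=frame.positions[lipid_idx])
    hits = tree.tree.query_ball_point(tree.wrap(frame.positions[lipid_idx]),
                                      d_shell, return_length=True)
    al = {int(m) for m in np.unique(lipid_mols[hits > 0])}
    all_lipids = {int(m) for m in np.unique(lipid_mols)}
    counts: dict[str, int] = {}
    for m in al:
        t = system.molecule_type_of(m).value
        counts[t] = counts.get(t, 0) + 1
    return ShellAssignment(al, all_lipids - al, d_shell, counts)
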