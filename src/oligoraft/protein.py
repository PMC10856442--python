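"""Protein-side analyses: hydropathy profiles, secondary-structure
regrouping, and residue-residue contact maps.

Hydropathy uses the Kyte-Doolittle scale with a centred moving average
(default 5 residues, truncated at the termini). DSSP one-letter codes are
consumed, not computed, and regrouped: beta <- {E, B}, alpha <- {H, G, I},
turn <- {T}, random <- {S, C, blank} (blank is the standard DSSP coil
output). Contact maps hold the time-mean and standard deviation of
residue-residue minimum atom distances; no diagonal or sequence-adjacent
exclusions are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import System, Trajectory
from .geometry import pairwise_min_image

__all__ = [
    "KYTE_DOOLITTLE",
    "HydropathyProfile",
    "SSCounts",
    "ContactMap",
    "hydropathy_profile",
    "local_maxima",
    "regroup_dssp",
    "ss_summary",
    "residue_contact_map",
    "interface_map",
]

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

SS_CATEGORIES = ("beta", "alpha", "turn", "random")
_SS_MAP = {"E": "beta", "B": "beta", "H": "alpha", "G": "alpha", "I": "alpha",
           "T": "turn", "S": "random", "C": "random", " ": "random",
           "": "random"}


@dataclass
class HydropathyProfile:
    residues: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    window: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "hydropathy": self.raw,
                             "smoothed": self.smoothed})


def hydropathy_profile(sequence: str, window: int = 5) -> HydropathyProfile:
    """Kyte-Doolittle hydropathy profile with centred moving-average smoothing.

    The window shrinks at the termini rather than padding the sequence.
    ``window=1`` returns the raw scale lookup.
    """
    try:
        raw = np.array([KYTE_DOOLITTLE[a] for a in sequence], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid letter {exc.args[0]!r}") from None
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    smoothed = (pd.Series(raw).rolling(window, center=True, min_periods=1)
                .mean().to_numpy())
    return HydropathyProfile(np.arange(1, len(raw) + 1), raw, smoothed, window)


def local_maxima(values: np.ndarray) -> list[int]:
    """1-based positions of local maxima, plateau-aware.

    A plateau counts once, at its first position; endpoints count when the
    profile falls away from them.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            peaks.append(i + 1)
        i = j + 1
    return peaks


@dataclass
class SSCounts:
    """Per-frame regrouped secondary-structure counts."""

    counts: pd.DataFrame          # columns beta, alpha, turn, random; row per frame
    n_residues: int

    def time_mean(self) -> pd.Series:
        return self.counts.mean(axis=0)


def regroup_dssp(trace: np.ndarray) -> SSCounts:
    """Regroup a (n_frames, n_residues) DSSP code matrix into four categories."""
    trace = np.asarray(trace, dtype="<U1")
    if trace.ndim == 1:
        trace = trace[None, :]
    bad = sorted(set(trace.ravel()) - set(_SS_MAP))
    if bad:
        raise ValueError(f"unknown DSSP code(s): {bad}")
    n_frames, n_res = trace.shape
    data = {}
    for cat in SS_CATEGORIES:
        codes = [c for c, v in _SS_MAP.items() if v == cat and c]
        data[cat] = np.isin(trace, codes).sum(axis=1)
    # blanks regroup as coil
    data["random"] = data["random"] + (trace == "").sum(axis=1)
    df = pd.DataFrame(data)
    assert (df.sum(axis=1) == n_res).all()
    return SSCounts(df, n_res)


def ss_summary(replicate_traces: list[np.ndarray],
               last_frames: int | None = None,
               residue_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Mean +/- SEM of regrouped category counts across replicates.

    Each trace is time-averaged over its ``last_frames`` frames (all frames
    when None); ``residue_subset`` (0-based column indices) restricts to a
    constituent chain set, enabling extraction of e.g. the amylin chains
    inside a hetero-oligomer, or stacked-sum comparisons after concatenating
    traces along the residue axis.
    """
    per_rep = []
    for trace in replicate_traces:
        trace = np.asarray(trace, dtype="<U1")
        if trace.ndim == 1:
            trace = trace[None, :]
        if last_frames is not None:
            if last_frames > trace.shape[0]:
                raise ValueError(
                    f"window of {last_frames} frames exceeds trace length "
                    f"{trace.shape[0]}")
            trace = trace[-last_frames:]
        if residue_subset is not None:
            trace = trace[:, np.asarray(residue_subset, dtype=int)]
        per_rep.append(regroup_dssp(trace).time_mean())
    arr = pd.DataFrame(per_rep)
    n = len(per_rep)
    out = pd.DataFrame({"category": arr.columns, "mean": arr.mean(axis=0).values})
    out["sem"] = (arr.std(axis=0, ddof=1) / np.sqrt(n)).values if n > 1 else np.nan
    out["n_replicates"] = n
    return out


@dataclass
class ContactMap:
    """Time-mean and SD of residue-residue minimum distances (nm)."""

    mean: np.ndarray
    sd: np.ndarray
    residue_chains: np.ndarray    # chain_id per matrix row
    residue_indices: np.ndarray   # 1-based within-chain residue index per row

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        labels = [f"{c}{r}" for c, r in zip(self.residue_chains, self.residue_indices)]
        return (pd.DataFrame(self.mean, index=labels, columns=labels),
                pd.DataFrame(self.sd, index=labels, columns=labels))


def _protein_residue_blocks(system: System):
    idx = system.protein_atom_indices()
    keys = list(zip(system.chain_ids[idx], system.residue_indices[idx]))
    uniq: list[tuple[str, int]] = []
    starts = []
    prev = None
    for k, key in enumerate(keys):
        if key != prev:
            uniq.append(key)
            starts.append(k)
            prev = key
    return idx, np.array(starts), uniq


def residue_contact_map(traj: Trajectory, window: float | None = None) -> ContactMap:
    """Residue-residue minimum-distance map averaged over trajectory frames.

    Entry (i, j) is the time-mean over the window of the minimum atom-pair
    distance between residues i and j; the companion matrix is the standard
    deviation over the same frames. Both matrices are symmetric and the mean
    diagonal is zero.
    """
    sub = traj if window is None else traj.last_window(window)
    system = sub.system
    idx, starts, uniq = _protein_residue_blocks(system)
    if idx.size == 0:
        raise ValueError("no protein present")
    n_res = len(uniq)
    s1 = np.zeros((n_res, n_res))
    s2 = np.zeros((n_res, n_res))
    for fr in sub.frames:
        d = pairwise_min_image(fr.positions[idx], fr.positions[idx], fr.box)
        d = np.minimum.reduceat(d, starts, axis=0)
        d = np.minimum.reduceat(d, starts, axis=1)
        s1 += d
        s2 += d * d
    k = sub.n_frames
    mean = s1 / k
    var = np.maximum(s2 / k - mean * mean, 0.0)
    chains = np.array([c for c, _ in uniq], dtype=object)
    resi = np.array([r for _, r in uniq], dtype=int)
    return ContactMap(mean, np.sqrt(var), chains, resi)


def interface_map(cmap: ContactMap, chain_a: str, chain_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Cross-chain block of the mean/SD maps (chain_a rows, chain_b columns)."""
    if chain_a == chain_b:
        raise ValueError("interface requires two disjoint residue ranges")
    rows = np.flatnonzero(cmap.residue_chains == chain_a)
    cols = np.flatnonzero(cmap.residue_chains == chain_b)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(f"chain {chain_a!r} or {chain_b!r} absent from the map")
    return cmap.mean[np.ix_(rows, cols)], cmap.sd[np.ix_(rows, cols)]
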