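"""Synthetic membrane/trajectory generator with planted ground truth.

Stands in for coarse-grained MD output: builds phase-separated asymmetric
raft bilayers (an Lo disc of saturated PC + cholesterol carrying an anionic
PS or GM1 cluster in the upper leaflet, surrounded by an unsaturated-PC Ld
region), a bead-chain oligomer, and binding trajectories in which the
protein-membrane minimum distance follows a prescribed schedule: detached
and fluctuating before the planted binding time, then stable at the planted
plateau. Acyl chains are drawn with a prescribed orientational order
parameter so that every analysis module can be closed against the planted
value.

Lipids are rendered as one headgroup reference bead plus ordered chain
beads per acyl chain; the geometry is what the analyses need, not the
chemistry, and no physical dynamics is simulated. All generators are
deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ChainDefinition,
    Frame,
    MoleculeType,
    ProteinRecord,
    System,
    Trajectory,
)
from .io import AA3, Manifest
from .sequences import oligomer_chains

__all__ = [
    "RaftSpec",
    "TrajectorySpec",
    "SSTraceSpec",
    "build_raft",
    "build_oligomer",
    "assemble_complex",
    "generate_binding_trajectory",
    "sample_chain_tilts",
    "generate_ss_trace",
    "emit_forcefield_table",
    "default_manifest",
    "FULL_SCALE_COUNTS",
]

# Full-scale raft compositions (molecule counts per raft type).
FULL_SCALE_COUNTS = {
    "PS": {MoleculeType.POPS: 162, MoleculeType.DPPC: 666,
           MoleculeType.DLPC: 540, MoleculeType.CHOL: 576},
    "GM": {MoleculeType.GM1: 36, MoleculeType.DPPC: 709,
           MoleculeType.DLPC: 407, MoleculeType.CHOL: 410},
    "CO": {MoleculeType.DPPC: 666, MoleculeType.DLPC: 540,
           MoleculeType.CHOL: 576},
}

ANIONIC = (MoleculeType.POPS, MoleculeType.GM1)

#: default acyl-chain bead counts per lipid type (CHOL has a single short
#: "chain" standing in for its ring stack)
DEFAULT_CHAIN_LENGTHS = {
    MoleculeType.DPPC: 4, MoleculeType.DLPC: 4, MoleculeType.POPS: 4,
    MoleculeType.GM1: 4, MoleculeType.CHOL: 3,
}

#: default planted chain order parameters: ordered Lo species vs disordered DLPC
DEFAULT_TILT_TARGETS = {
    MoleculeType.DPPC: 0.85, MoleculeType.CHOL: 0.90, MoleculeType.POPS: 0.85,
    MoleculeType.GM1: 0.85, MoleculeType.DLPC: 0.45,
}

HEAD_NAMES = {
    MoleculeType.DPPC: "NC3", MoleculeType.DLPC: "NC3",
    MoleculeType.POPS: "CNO", MoleculeType.GM1: "SUG",
    MoleculeType.CHOL: "ROH",
}

_BASIC = set("KR")
_ACIDIC = set("DE")


def _chain_names(lipid_type: MoleculeType, n: int) -> list[tuple[str, ...]]:
    if lipid_type is MoleculeType.CHOL:
        return [tuple(f"C{j + 1}" for j in range(n))]
    return [tuple(f"C{j + 1}A" for j in range(n)),
            tuple(f"C{j + 1}B" for j in range(n))]


def default_manifest(proteins: list[ProteinRecord] = (),
                     chain_lengths: dict | None = None) -> Manifest:
    """Manifest matching the synthetic fixtures' residue and atom naming."""
    cl = dict(DEFAULT_CHAIN_LENGTHS)
    if chain_lengths:
        cl.update(chain_lengths)
    chain_defs = []
    for lt in (MoleculeType.DPPC, MoleculeType.DLPC, MoleculeType.POPS,
               MoleculeType.GM1, MoleculeType.CHOL):
        names = _chain_names(lt, cl[lt])
        labels = ["sn1", "sn2"][: len(names)]
        for lab, ns in zip(labels, names):
            chain_defs.append(ChainDefinition(lt, lab, ns))
    type_keys = {"NC3": "PC-H", "CNO": "PS-H", "SUG": "GM-H", "ROH": "CH-H",
                 "W": "W", "NA": "NA", "CL": "CL",
                 "BB": "PR0", "BBK": "PR+", "BBD": "PR-"}
    for lt in cl:
        for ns in _chain_names(lt, cl[lt]):
            for nm in ns:
                type_keys[nm] = "CT"
    return Manifest(
        residue_types={"DPPC": "DPPC", "DLPC": "DLPC", "CHOL": "CHOL",
                       "POPS": "POPS", "GM1": "GM1", "W": "WATER",
                       "NA": "ION", "CL": "ION"},
        reference_atoms={lt.value: n for lt, n in HEAD_NAMES.items()},
        chain_definitions=chain_defs,
        proteins=list(proteins),
        type_keys=type_keys,
    )


@dataclass
class RaftSpec:
    """Geometry and composition of a synthetic phase-separated raft.

    ``counts`` maps lipid type -> (upper, lower) molecule counts; anionic
    species must appear in exactly one leaflet. The Lo disc is centred in
    the box and sized to hold the Lo species (DPPC, CHOL and the anionic
    cluster, which sits innermost); DLPC fills the region outside, with an
    optional radial exclusion ring ``lod_gap`` separating the phases.
    """

    counts: dict[MoleculeType, tuple[int, int]]
    area_per_lipid: float = 0.64          # nm^2
    box_xy: float | None = None           # nm; derived from counts if None
    lod_gap: float = 0.0                  # nm; radial Lo/Ld separation
    chain_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHAIN_LENGTHS))
    bead_spacing: float = 0.25            # nm between chain beads
    head_protrusion: float = 0.3          # nm; anionic heads above PC heads
    tilt_targets: dict = field(default_factory=lambda: dict(DEFAULT_TILT_TARGETS))
    n_water: int = 0
    seed: int = 0

    def __post_init__(self):
        for lt, (u, lo) in self.counts.items():
            if u < 0 or lo < 0:
                raise ValueError(f"negative count for {lt}")
            if lt in ANIONIC and u > 0 and lo > 0:
                raise ValueError(f"anionic {lt.value} must occupy exactly one leaflet")

    @classmethod
    def from_raft_type(cls, raft_type: str, scale: int = 8, **kwargs) -> "RaftSpec":
        """Reduced (1/scale) or full-scale (scale=1) standard composition.

        Non-anionic species split evenly between leaflets (odd molecule to
        the upper leaflet); the anionic species occupies the upper leaflet
        only.
        """
        full = FULL_SCALE_COUNTS[raft_type]
        counts = {}
        for lt, n in full.items():
            n = int(math.floor(n / scale + 0.5)) if scale != 1 else n
            if lt in ANIONIC:
                counts[lt] = (n, 0)
            else:
                counts[lt] = (n - n // 2, n // 2)
        return cls(counts=counts, **kwargs)


def sample_chain_tilts(s_target: float, n: int,
                       rng: np.random.Generator | int = 0) -> np.ndarray:
    """Polar tilt angles whose second-Legendre mean converges to ``s_target``.

    Angles are drawn from a two-component mixture: a perfectly aligned
    (s_target >= 0) or perfectly in-plane (s_target < 0) component with the
    weight that fixes the expectation, and an isotropic component whose
    P2 expectation is zero. Degenerate targets return exact angles.
    """
    if not -0.5 <= s_target <= 1.0:
        raise ValueError(f"order-parameter target {s_target} outside [-0.5, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if s_target == 1.0:
        return np.zeros(n)
    if s_target == -0.5:
        return np.full(n, np.pi / 2)
    if s_target >= 0:
        p = s_target
        aligned_angle = 0.0
    else:
        p = -2.0 * s_target
        aligned_angle = np.pi / 2
    take = rng.random(n) < p
    iso = np.arccos(rng.random(n))  # isotropic in the upper hemisphere
    return np.where(take, aligned_angle, iso)


# ---------------------------------------------------------------------------
# raft construction
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.mol_ids: list[int] = []
        self.mol_types: list[MoleculeType] = []
        self.chain_ids: list[str] = []
        self.res_idx: list[int] = []
        self.pos: list[np.ndarray] = []
        self._mol = -1

    def new_molecule(self) -> int:
        self._mol += 1
        return self._mol

    def add(self, name, resname, mol_id, mol_type, chain_id, res_i, xyz):
        self.names.append(name)
        self.resnames.append(resname)
        self.mol_ids.append(mol_id)
        self.mol_types.append(mol_type)
        self.chain_ids.append(chain_id)
        self.res_idx.append(res_i)
        self.pos.append(np.asarray(xyz, dtype=float))


def _chain_direction(theta: float, phi: float, sign: float) -> np.ndarray:
    return np.array([math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     -sign * math.cos(theta)])


def build_raft(spec: RaftSpec, manifest: Manifest | None = None) -> System:
    """Lattice-build a phase-separated asymmetric bilayer.

    Each leaflet is a square lattice at the spec's area per lipid; sites are
    assigned inside-out so that the anionic cluster sits at the disc centre,
    DPPC and CHOL fill the rest of the Lo disc, and DLPC fills the outside.
    Chain tilts are drawn per chain from the spec's planted order targets.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = manifest or default_manifest()
    a = math.sqrt(spec.area_per_lipid)
    n_upper = sum(u for u, _ in spec.counts.values())
    n_lower = sum(lo for _, lo in spec.counts.values())
    n_max = max(n_upper, n_lower, 1)
    L = spec.box_xy or a * math.ceil(math.sqrt(n_max))
    n_side = int(L / a)
    if n_side * n_side < n_max:
        raise ValueError(
            f"lattice capacity {n_side * n_side} < leaflet count {n_max}; "
            "enlarge box_xy or area_per_lipid")

    max_ext = max(spec.chain_lengths[lt] * spec.bead_spacing
                  for lt in spec.counts if spec.counts[lt][0] + spec.counts[lt][1] > 0)
    h = max(1.0, max_ext + 0.3)           # head-plane height above midplane
    box_z = 2 * h + 12.0                  # headroom for a detached oligomer
    z_mid = box_z / 2.0
    box = np.array([L, L, box_z])
    centre = np.array([L / 2.0, L / 2.0])

    grid = (np.stack(np.meshgrid(np.arange(n_side), np.arange(n_side)),
                     axis=-1).reshape(-1, 2) + 0.5) * a
    radii = np.linalg.norm(grid - centre, axis=1)
    order = np.argsort(radii, kind="stable")

    b = _Builder()
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        col = 0 if leaflet == "upper" else 1
        anion = [(lt, spec.counts[lt][col]) for lt in spec.counts if lt in ANIONIC]
        anion_seq = [lt for lt, n in anion for _ in range(n)]
        n_dppc = spec.counts.get(MoleculeType.DPPC, (0, 0))[col]
        n_chol = spec.counts.get(MoleculeType.CHOL, (0, 0))[col]
        n_dlpc = spec.counts.get(MoleculeType.DLPC, (0, 0))[col]
        # interleave DPPC and CHOL through the Lo disc
        lo_seq: list[MoleculeType] = []
        i = j = 0
        while i < n_dppc or j < n_chol:
            if i * max(n_chol, 1) <= j * max(n_dppc, 1) and i < n_dppc:
                lo_seq.append(MoleculeType.DPPC)
                i += 1
            elif j < n_chol:
                lo_seq.append(MoleculeType.CHOL)
                j += 1
            else:
                lo_seq.append(MoleculeType.DPPC)
                i += 1
        inner = anion_seq + lo_seq
        sites = list(order)
        if len(inner) + n_dlpc > len(sites):
            raise ValueError("counts exceed lattice capacity")
        lo_sites = sites[: len(inner)]
        r_lo = radii[lo_sites[-1]] if lo_sites else 0.0
        outer_sites = [s for s in sites[len(inner):]
                       if radii[s] > r_lo + spec.lod_gap]
        if n_dlpc > len(outer_sites):
            raise ValueError(
                f"lod_gap={spec.lod_gap} leaves {len(outer_sites)} sites for "
                f"{n_dlpc} DLPC; enlarge box_xy")
        placements = ([(lt, s) for lt, s in zip(inner, lo_sites)]
                      + [(MoleculeType.DLPC, s) for s in outer_sites[:n_dlpc]])
        for lt, site in placements:
            x, y = grid[site]
            z_head = z_mid + sign * h
            if lt in ANIONIC:
                z_head += sign * spec.head_protrusion
            mol = b.new_molecule()
            head = np.array([x, y, z_head])
            b.add(HEAD_NAMES[lt], lt.value, mol, lt, "", 1, head)
            n_c = spec.chain_lengths[lt]
            s_t = spec.tilt_targets.get(lt, 0.85)
            for names in _chain_names(lt, n_c):
                theta = float(sample_chain_tilts(s_t, 1, rng)[0])
                phi = float(rng.uniform(0, 2 * np.pi))
                d = _chain_direction(theta, phi, sign)
                for k, nm in enumerate(names, start=1):
                    b.add(nm, lt.value, mol, lt, "", 1,
                          head + d * spec.bead_spacing * k)

    for _ in range(spec.n_water):
        mol = b.new_molecule()
        side = 1.0 if rng.random() < 0.5 else -1.0
        z = z_mid + side * rng.uniform(h + 1.0, h + 4.0)
        b.add("W", "W", mol, MoleculeType.WATER, "", 1,
              np.array([rng.uniform(0, L), rng.uniform(0, L), z]))

    system = System(
        atom_names=b.names,
        type_keys=[manifest.type_key(n) for n in b.names],
        molecule_ids=b.mol_ids,
        molecule_types=b.mol_types,
        chain_ids=b.chain_ids,
        residue_indices=b.res_idx,
        residue_names=b.resnames,
        positions=np.array(b.pos),
        box=box,
        protein_records=[],
        chain_definitions=manifest.chain_definitions,
        reference_atoms={MoleculeType(k): v
                         for k, v in manifest.reference_atoms.items()},
    )
    system.raft_meta = _raft_meta(system, spec)
    return system


def _raft_meta(system: System, spec: RaftSpec) -> dict:
    """Per-lipid chain bookkeeping used for per-frame chain re-tilting."""
    z_mid = system.box[2] / 2.0
    chains = []
    for mol in system.lipid_molecule_ids():
        idx = system.molecule_atoms(mol)
        lt = system.molecule_types[idx[0]]
        head = int(idx[0])
        sign = 1.0 if system.positions[head, 2] >= z_mid else -1.0
        chain_idx = []
        for names in _chain_names(lt, spec.chain_lengths[lt]):
            sel = [int(i) for nm in names for i in idx[system.atom_names[idx] == nm]]
            chain_idx.append(np.array(sel, dtype=int))
        chains.append((head, sign, chain_idx, lt))
    return {"chains": chains, "spacing": spec.bead_spacing,
            "tilt_targets": dict(spec.tilt_targets)}


# ---------------------------------------------------------------------------
# oligomer construction and complex assembly
# ---------------------------------------------------------------------------

def build_oligomer(name: str, anchor_residues: dict[str, list[int]] | None = None,
                   spacing: float = 0.38):
    """Bead-per-residue oligomer blob in local coordinates.

    Chains are stacked along z (chain A at the bottom); within a chain the
    residues run on a serpentine lattice in the x-y plane. ``anchor_residues``
    (chain_id -> 1-based residue indices) lowers the named residues of a
    chain by one layer so they form the membrane-contacting face.

    Returns (records, names, resnames, chain_ids, res_idx, positions).
    """
    anchor_residues = anchor_residues or {}
    chains = oligomer_chains(name)
    records = [ProteinRecord(cid, seq, mono) for cid, mono, seq in chains]
    names: list[str] = []
    resnames: list[str] = []
    chain_ids: list[str] = []
    res_idx: list[int] = []
    pos: list[list[float]] = []
    z_chain = 0.0
    for cid, _mono, seq in chains:
        anchors = set(anchor_residues.get(cid, []))
        w = math.ceil(math.sqrt(len(seq)))
        for r, aa in enumerate(seq, start=1):
            row, colm = divmod(r - 1, w)
            x = (colm if row % 2 == 0 else w - 1 - colm) * spacing
            y = row * spacing
            z = z_chain if (not anchors or r in anchors) else z_chain + 0.5
            bead = "BBK" if aa in _BASIC else ("BBD" if aa in _ACIDIC else "BB")
            names.append(bead)
            resnames.append(AA3[aa])
            chain_ids.append(cid)
            res_idx.append(r)
            pos.append([x, y, z])
        z_chain += 0.45
    return records, names, resnames, chain_ids, res_idx, np.array(pos)


def assemble_complex(raft: System, oligomer: str,
                     anchor_residues: dict[str, list[int]] | None = None,
                     initial_height: float = 5.0,
                     manifest: Manifest | None = None) -> System:
    """Append one oligomer above the raft's anionic cluster.

    The oligomer's lowest bead is placed ``initial_height`` nm directly above
    the membrane's topmost lipid atom (which is an anionic headgroup when the
    cluster protrudes), so the initial protein-membrane minimum distance is
    exactly ``initial_height``.
    """
    manifest = manifest or default_manifest()
    records, names, resnames, chain_ids, res_idx, ppos = build_oligomer(
        oligomer, anchor_residues)
    from .core import LIPID_TYPES, isin_types
    lipid_atoms = np.flatnonzero(isin_types(raft.molecule_types, LIPID_TYPES))
    top = lipid_atoms[np.argmax(raft.positions[lipid_atoms, 2])]
    attach = raft.positions[top].copy()
    low = int(np.argmin(ppos[:, 2]))
    offset = attach + np.array([0.0, 0.0, initial_height]) - ppos[low]
    ppos = ppos + offset

    mol_offset = int(raft.molecule_ids.max()) + 1 if raft.n_atoms else 0
    mol_ids = list(raft.molecule_ids)
    chain_mol = {}
    for cid in chain_ids:
        if cid not in chain_mol:
            chain_mol[cid] = mol_offset + len(chain_mol)
    system = System(
        atom_names=np.concatenate([raft.atom_names, np.array(names, dtype=object)]),
        type_keys=np.concatenate([raft.type_keys,
                                  np.array([manifest.type_key(n) for n in names],
                                           dtype=object)]),
        molecule_ids=mol_ids + [chain_mol[c] for c in chain_ids],
        molecule_types=np.concatenate([raft.molecule_types,
                                       np.array([MoleculeType.PROTEIN] * len(names),
                                                dtype=object)]),
        chain_ids=np.concatenate([raft.chain_ids, np.array(chain_ids, dtype=object)]),
        residue_indices=np.concatenate([raft.residue_indices, res_idx]),
        residue_names=np.concatenate([raft.residue_names,
                                      np.array(resnames, dtype=object)]),
        positions=np.vstack([raft.positions, ppos]),
        box=raft.box,
        protein_records=records,
        chain_definitions=list(raft.chain_definitions.values()),
        reference_atoms=raft.reference_atoms,
    )
    meta = dict(getattr(raft, "raft_meta", {}))
    system.raft_meta = meta
    return system


@dataclass
class TrajectorySpec:
    """Schedule of a synthetic binding trajectory.

    Before ``t_bind`` the protein-membrane minimum distance fluctuates
    uniformly in [detach_floor, detach_ceiling]; from ``t_bind`` on it is
    ``stable_mindist`` plus truncated Gaussian noise (clipped at two standard
    deviations, so a detector threshold above the plateau plus 2*noise_sd
    recovers the planted time exactly). ``tilt_target`` != None resamples
    every acyl-chain tilt each frame from the given order-parameter target
    (float, or dict per lipid type).
    """

    n_frames: int = 30
    frame_spacing: float = 0.5      # time units between frames (us for CG)
    t_bind: float = 3.0
    detach_floor: float = 2.5       # nm; above the contact threshold
    detach_ceiling: float = 5.0
    stable_mindist: float = 0.5     # nm; the bound-state plateau
    noise_sd: float = 0.03          # nm
    tilt_target: float | dict | None = None
    resolution_tag: str = "CG"
    seed: int = 0

    def __post_init__(self):
        t_final = (self.n_frames - 1) * self.frame_spacing
        if not 0 <= self.t_bind <= t_final:
            raise ValueError(f"t_bind={self.t_bind} outside [0, {t_final}]")
        if self.detach_floor > self.detach_ceiling:
            raise ValueError("detach_floor > detach_ceiling")


def _tilt_for(spec_target, lt: MoleculeType, meta_targets: dict) -> float:
    if spec_target is None:
        return meta_targets.get(lt, 0.85)
    if isinstance(spec_target, dict):
        return spec_target.get(lt, meta_targets.get(lt, 0.85))
    return float(spec_target)


def generate_binding_trajectory(system: System, spec: TrajectorySpec) -> Trajectory:
    """Generate frames realising the spec's minimum-distance schedule.

    The oligomer is rigid; each frame it is translated so that its lowest
    bead sits exactly the scheduled distance above the membrane's topmost
    lipid atom, which realises the scheduled value as the exact
    protein-membrane minimum distance. Lipid chains are optionally re-tilted
    each frame (see :class:`TrajectorySpec`). Deterministic given the seed.
    """
    meta = getattr(system, "raft_meta", None)
    if meta is None or "chains" not in meta:
        raise ValueError("system lacks raft metadata; build it with build_raft")
    prot_idx = system.protein_atom_indices()
    if prot_idx.size == 0:
        raise ValueError("system contains no protein group")
    if len({c for c in system.chain_ids[prot_idx]}) != len(system.protein_records):
        raise ValueError("protein chains inconsistent with records")
    rng = np.random.default_rng(spec.seed)
    from .core import LIPID_TYPES, isin_types
    lipid_atoms = np.flatnonzero(isin_types(system.molecule_types, LIPID_TYPES))
    base = system.positions
    prot_local = base[prot_idx] - base[prot_idx[int(np.argmin(base[prot_idx, 2]))]]

    frames = []
    for i in range(spec.n_frames):
        t = i * spec.frame_spacing
        pos = base.copy()
        if spec.tilt_target is not None:
            for head, sign, chain_idx, lt in meta["chains"]:
                s_t = _tilt_for(spec.tilt_target, lt, meta["tilt_targets"])
                for sel in chain_idx:
                    if sel.size == 0:
                        continue
                    theta = float(sample_chain_tilts(s_t, 1, rng)[0])
                    phi = float(rng.uniform(0, 2 * np.pi))
                    d = _chain_direction(theta, phi, sign)
                    ks = np.arange(1, sel.size + 1)[:, None]
                    pos[sel] = pos[head] + d[None, :] * meta["spacing"] * ks
        if t >= spec.t_bind:
            noise = float(np.clip(rng.normal(0.0, spec.noise_sd),
                                  -2 * spec.noise_sd, 2 * spec.noise_sd)) \
                if spec.noise_sd > 0 else 0.0
            target = max(0.05, spec.stable_mindist + noise)
        else:
            target = float(rng.uniform(spec.detach_floor, spec.detach_ceiling))
        top = lipid_atoms[int(np.argmax(pos[lipid_atoms, 2]))]
        attach = pos[top] + np.array([0.0, 0.0, target])
        pos[prot_idx] = prot_local + attach
        frames.append(Frame(t, pos, system.box))
    return Trajectory(system, frames, spec.resolution_tag)


# ---------------------------------------------------------------------------
# secondary-structure streams
# ---------------------------------------------------------------------------

@dataclass
class SSTraceSpec:
    """Planted per-category fractions for a synthetic DSSP code stream."""

    fractions: tuple[float, float, float, float]  # beta, alpha, turn, random
    n_residues: int
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")


_CATEGORY_CODES = {
    "beta": (("E", 0.8), ("B", 0.2)),
    "alpha": (("H", 0.7), ("G", 0.2), ("I", 0.1)),
    "turn": (("T", 1.0),),
    "random": (("S", 0.4), ("C", 0.6)),
}
_CATEGORIES = ("beta", "alpha", "turn", "random")


def generate_ss_trace(spec: SSTraceSpec) -> np.ndarray:
    """(n_frames, n_residues) array of DSSP one-letter codes.

    Each residue-frame draws its category independently from the planted
    fractions, then a concrete DSSP letter within the category, so regrouped
    per-frame counts are multinomial around fractions * n_residues.
    """
    rng = np.random.default_rng(spec.seed)
    cats = rng.choice(4, size=(spec.n_frames, spec.n_residues),
                      p=np.asarray(spec.fractions, dtype=float))
    out = np.empty((spec.n_frames, spec.n_residues), dtype="<U1")
    for ci, cat in enumerate(_CATEGORIES):
        letters, probs = zip(*[(l, p) for l, p in _CATEGORY_CODES[cat]])
        mask = cats == ci
        out[mask] = rng.choice(letters, size=int(mask.sum()), p=probs)
    return out


# ---------------------------------------------------------------------------
# toy force field
# ---------------------------------------------------------------------------

def emit_forcefield_table():
    """Small bead-level force-field table with correct formal charges.

    Whole-molecule charges: PC, CHOL and water are neutral, PS and GM1 carry
    -1 on the headgroup bead; protein beads carry the side-chain formal
    charge (+1 Lys/Arg, -1 Asp/Glu). Lennard-Jones parameters are
    Martini-flavoured bead values (sigma ~0.47 nm).
    """
    from .energetics import ForceFieldTable

    sigma = {"PC-H": 0.47, "PS-H": 0.47, "GM-H": 0.52, "CH-H": 0.43,
             "CT": 0.47, "W": 0.47, "NA": 0.33, "CL": 0.40,
             "PR0": 0.47, "PR+": 0.47, "PR-": 0.47}
    epsilon = {"PC-H": 4.0, "PS-H": 4.5, "GM-H": 4.5, "CH-H": 3.5,
               "CT": 3.5, "W": 4.0, "NA": 3.0, "CL": 3.0,
               "PR0": 4.0, "PR+": 4.0, "PR-": 4.0}
    charge = {"PC-H": 0.0, "PS-H": -1.0, "GM-H": -1.0, "CH-H": 0.0,
              "CT": 0.0, "W": 0.0, "NA": 1.0, "CL": -1.0,
              "PR0": 0.0, "PR+": 1.0, "PR-": -1.0}
    return ForceFieldTable(sigma=sigma, epsilon=epsilon, charge=charge)
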