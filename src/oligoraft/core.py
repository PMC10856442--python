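"""Core domain types: atoms, systems, frames, trajectories.

Positions are stored in nanometres throughout; simulation boxes are
orthorhombic (three edge lengths). Atoms are held in flat numpy arrays on
the :class:`System`, grouped into whole molecules by ``molecule_id``;
:class:`Atom` is a lightweight per-atom view used at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MoleculeType",
    "Atom",
    "Frame",
    "Trajectory",
    "ChainDefinition",
    "ProteinRecord",
    "System",
    "LIPID_TYPES",
    "TopologyError",
]

LATERAL_PERIODIC = (True, True, False)


def isin_types(values: np.ndarray, types) -> np.ndarray:
    """Boolean mask of membership in ``types`` for an object array of enums."""
    ts = set(types)
    return np.fromiter((v in ts for v in values), dtype=bool, count=len(values))


class TopologyError(ValueError):
    """A molecule is missing an atom or annotation an analysis requires."""


class MoleculeType(str, Enum):
    DPPC = "DPPC"
    DLPC = "DLPC"
    CHOL = "CHOL"
    POPS = "POPS"
    GM1 = "GM1"
    WATER = "WATER"
    ION = "ION"
    PROTEIN = "PROTEIN"


#: Membrane lipid species (everything classify/shell analyses operate on).
LIPID_TYPES = (
    MoleculeType.DPPC,
    MoleculeType.DLPC,
    MoleculeType.CHOL,
    MoleculeType.POPS,
    MoleculeType.GM1,
)


@dataclass(frozen=True)
class Atom:
    atom_index: int
    atom_name: str
    type_key: str
    position: np.ndarray
    molecule_id: int
    molecule_type: MoleculeType
    chain_id: str
    residue_index: int
    residue_name: str


@dataclass(frozen=True)
class ChainDefinition:
    """Ordered acyl-carbon names of one chain (sn-1 or sn-2) of a lipid type."""

    lipid_type: MoleculeType
    chain_label: str  # "sn1" | "sn2"
    carbon_atom_names: tuple[str, ...]

    def __post_init__(self):
        if self.chain_label not in ("sn1", "sn2"):
            raise ValueError(f"chain_label must be sn1 or sn2, got {self.chain_label!r}")
        if len(self.carbon_atom_names) < 3:
            raise ValueError("a chain needs at least 3 carbons (interior carbons required)")


@dataclass(frozen=True)
class ProteinRecord:
    chain_id: str
    sequence: str
    monomer_type: str  # "tau" | "amylin"


@dataclass
class Frame:
    """One trajectory frame: a time stamp, positions (nm) and the box (nm)."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")


class System:
    """A molecular system: annotated atoms plus reference coordinates.

    Parameters
    ----------
    atom_names, type_keys, residue_names, chain_ids
        Per-atom string annotations (chain_id is "" for non-protein atoms).
    molecule_ids
        Integer id shared by every atom of one molecule.
    molecule_types
        Per-atom :class:`MoleculeType`.
    residue_indices
        1-based residue index within the owning chain (proteins) or 1 for
        single-residue molecules.
    positions, box
        Reference coordinates (nm) and orthorhombic box.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        type_keys: Sequence[str],
        molecule_ids: Sequence[int],
        molecule_types: Sequence[MoleculeType],
        chain_ids: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        positions: np.ndarray,
        box: np.ndarray,
        protein_records: Sequence[ProteinRecord] = (),
        chain_definitions: Sequence[ChainDefinition] = (),
        reference_atoms: dict[MoleculeType, str] | None = None,
    ):
        n = len(atom_names)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.type_keys = np.asarray(type_keys, dtype=object)
        self.molecule_ids = np.asarray(molecule_ids, dtype=int)
        self.molecule_types = np.asarray(molecule_types, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.positions = np.asarray(positions, dtype=float)
        self.box = np.asarray(box, dtype=float)
        for arr in (self.type_keys, self.molecule_ids, self.molecule_types,
                    self.chain_ids, self.residue_indices, self.residue_names):
            if len(arr) != n:
                raise ValueError("all per-atom arrays must have equal length")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if np.any(self.residue_indices < 1):
            raise ValueError("residue indices are 1-based")
        self.protein_records = list(protein_records)
        self.chain_definitions = {
            (cd.lipid_type, cd.chain_label): cd for cd in chain_definitions
        }
        #: per-lipid-type reference atom name (headgroup bead / phosphorus)
        self.reference_atoms = dict(reference_atoms or {})
        self._validate_protein_records()

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        return Atom(
            atom_index=int(i),
            atom_name=str(self.atom_names[i]),
            type_key=str(self.type_keys[i]),
            position=self.positions[i].copy(),
            molecule_id=int(self.molecule_ids[i]),
            molecule_type=self.molecule_types[i],
            chain_id=str(self.chain_ids[i]),
            residue_index=int(self.residue_indices[i]),
            residue_name=str(self.residue_names[i]),
        )

    def atoms_of_type(self, mol_type: MoleculeType) -> np.ndarray:
        """Indices of all atoms belonging to molecules of ``mol_type``."""
        return np.flatnonzero(isin_types(self.molecule_types, (mol_type,)))

    def molecules_of_type(self, mol_type: MoleculeType) -> np.ndarray:
        """Sorted unique molecule ids of the given type."""
        return np.unique(self.molecule_ids[isin_types(self.molecule_types, (mol_type,))])

    def molecule_atoms(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_ids == molecule_id)

    def lipid_molecule_ids(self) -> np.ndarray:
        mask = isin_types(self.molecule_types, LIPID_TYPES)
        return np.unique(self.molecule_ids[mask])

    def molecule_type_of(self, molecule_id: int) -> MoleculeType:
        idx = self.molecule_atoms(molecule_id)
        if idx.size == 0:
            raise KeyError(f"no molecule with id {molecule_id}")
        return self.molecule_types[idx[0]]

    def protein_atom_indices(self, chain_id: str | None = None) -> np.ndarray:
        mask = isin_types(self.molecule_types, (MoleculeType.PROTEIN,))
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        return np.flatnonzero(mask)

    def protein_chain_ids(self) -> list[str]:
        idx = self.protein_atom_indices()
        seen: list[str] = []
        for c in self.chain_ids[idx]:
            if c not in seen:
                seen.append(c)
        return seen

    def reference_atom_index(self, molecule_id: int) -> int:
        """Index of the leaflet reference atom of one lipid molecule."""
        idx = self.molecule_atoms(molecule_id)
        mtype = self.molecule_types[idx[0]]
        name = self.reference_atoms.get(mtype)
        if name is None:
            # convention: first atom of the molecule is the headgroup bead
            return int(idx[0])
        hits = idx[self.atom_names[idx] == name]
        if hits.size == 0:
            raise TopologyError(
                f"molecule {molecule_id} ({mtype.value}) has no reference atom {name!r}"
            )
        return int(hits[0])

    def _validate_protein_records(self) -> None:
        for rec in self.protein_records:
            idx = self.protein_atom_indices(rec.chain_id)
            if idx.size == 0:
                raise TopologyError(f"protein record for absent chain {rec.chain_id!r}")
            n_res = len(np.unique(self.residue_indices[idx]))
            if n_res != len(rec.sequence):
                raise TopologyError(
                    f"chain {rec.chain_id!r}: sequence length {len(rec.sequence)} "
                    f"!= residue count {n_res}"
                )

    def with_positions(self, positions: np.ndarray, box: np.ndarray | None = None) -> "System":
        """Shallow copy sharing annotations but with new coordinates."""
        new = object.__new__(System)
        new.__dict__ = dict(self.__dict__)
        new.positions = np.asarray(positions, dtype=float)
        if box is not None:
            new.box = np.asarray(box, dtype=float)
        return new


@dataclass
class Trajectory:
    """An ordered sequence of frames over one :class:`System`.

    ``resolution_tag`` records the spatial resolution ("CG" or "AA"); frame
    times are in the natural unit of that resolution (microseconds for CG,
    nanoseconds for AA) and must be strictly increasing.
    """

    system: System
    frames: list[Frame] = field(default_factory=list)
    resolution_tag: str = "CG"

    def __post_init__(self):
        if self.resolution_tag not in ("CG", "AA"):
            raise ValueError("resolution_tag must be 'CG' or 'AA'")
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for k, fr in enumerate(self.frames):
            if fr.positions.shape[0] != self.system.n_atoms:
                raise ValueError(
                    f"frame {k}: {fr.positions.shape[0]} atoms, system has "
                    f"{self.system.n_atoms}"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterable[Frame]:
        return iter(self.frames)

    def window(self, t_start: float | None = None, t_end: float | None = None) -> "Trajectory":
        """Sub-trajectory with times in [t_start, t_end] (inclusive)."""
        times = self.times
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        keep = [fr for fr, t in zip(self.frames, times) if lo <= t <= hi]
        if not keep:
            raise ValueError(f"empty window [{t_start}, {t_end}] for trajectory "
                             f"spanning [{times.min() if len(times) else '∅'}, "
                             f"{times.max() if len(times) else '∅'}]")
        return Trajectory(self.system, keep, self.resolution_tag)

    def last_window(self, duration: float) -> "Trajectory":
        """Frames within ``duration`` of the final time (the analysis window)."""
        if not self.frames:
            raise ValueError("empty trajectory")
        t_end = self.times[-1]
        return self.window(t_end - duration, t_end)
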