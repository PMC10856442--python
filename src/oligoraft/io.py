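"""Structure and trajectory I/O.

Single-frame GRO and PDB structures are parsed through MDAnalysis; the
multi-frame GRO trajectory dialect used throughout this package (frame time
carried as a ``t=`` token in each frame's title line) plus the GRO writer
are implemented here, so that synthetic fixtures round-trip bitwise at the
printed precision without binary formats. PDB coordinates (Å) are converted
to nm on read. Only orthorhombic boxes are accepted.

A *topology manifest* (YAML) maps residue names to molecule types, declares
leaflet reference atoms, acyl-chain carbon orderings and protein chains; it
is what turns a bare coordinate file into an annotated :class:`System`.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import (
    ChainDefinition,
    Frame,
    MoleculeType,
    ProteinRecord,
    System,
    Trajectory,
)

__all__ = [
    "Manifest",
    "ParseError",
    "ClassificationError",
    "StructuralError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]


class ParseError(ValueError):
    """A record could not be parsed; the message names the offending line."""


class ClassificationError(ValueError):
    """A residue name has no molecule-type entry in the manifest."""


class StructuralError(ValueError):
    """A frame is inconsistent with the system it claims to describe."""


AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}


@dataclass
class Manifest:
    """Topology manifest: residue-name classification plus chain metadata.

    ``residue_types`` maps residue names (as written in the coordinate file)
    to molecule-type names; the 20 standard amino-acid residue names are
    implicitly PROTEIN. ``proteins`` lists the protein chains in file order.
    """

    residue_types: dict[str, str] = field(default_factory=dict)
    reference_atoms: dict[str, str] = field(default_factory=dict)
    chain_definitions: list[ChainDefinition] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)
    type_keys: dict[str, str] = field(default_factory=dict)

    def molecule_type(self, residue_name: str) -> MoleculeType:
        if residue_name in self.residue_types:
            return MoleculeType(self.residue_types[residue_name])
        if residue_name in AA1:
            return MoleculeType.PROTEIN
        raise ClassificationError(
            f"residue name {residue_name!r} is not in the manifest"
        )

    def type_key(self, atom_name: str) -> str:
        return self.type_keys.get(atom_name, atom_name)

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "residue_types": dict(self.residue_types),
            "reference_atoms": dict(self.reference_atoms),
            "chain_definitions": [
                {"lipid_type": cd.lipid_type.value, "chain_label": cd.chain_label,
                 "carbons": list(cd.carbon_atom_names)}
                for cd in self.chain_definitions
            ],
            "proteins": [
                {"chain_id": p.chain_id, "monomer_type": p.monomer_type,
                 "sequence": p.sequence}
                for p in self.proteins
            ],
            "type_keys": dict(self.type_keys),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Manifest":
        return cls(
            residue_types=dict(d.get("residue_types", {})),
            reference_atoms=dict(d.get("reference_atoms", {})),
            chain_definitions=[
                ChainDefinition(MoleculeType(c["lipid_type"]), c["chain_label"],
                                tuple(c["carbons"]))
                for c in d.get("chain_definitions", [])
            ],
            proteins=[
                ProteinRecord(p["chain_id"], p["sequence"], p["monomer_type"])
                for p in d.get("proteins", [])
            ],
            type_keys=dict(d.get("type_keys", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# GRO parsing (fixed width, nm)
# ---------------------------------------------------------------------------

def _parse_gro_frames(text: str, path: str = "<string>"):
    """Yield (time, resids, resnames, atomnames, positions, box) per frame."""
    lines = text.splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                raise ParseError(f"{path}, line {i + 1}: malformed t= token in title")
        try:
            n_atoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"{path}, line {i + 2}: expected atom count")
        start = i + 2
        end = start + n_atoms
        if end > len(lines) - 1:
            raise ParseError(f"{path}: frame {frame_no} truncated "
                             f"(expected {n_atoms} atom records)")
        resids = np.empty(n_atoms, dtype=int)
        resnames = np.empty(n_atoms, dtype=object)
        atomnames = np.empty(n_atoms, dtype=object)
        pos = np.empty((n_atoms, 3), dtype=float)
        for k in range(n_atoms):
            ln = lines[start + k]
            try:
                resids[k] = int(ln[0:5])
                resnames[k] = ln[5:10].strip()
                atomnames[k] = ln[10:15].strip()
                pos[k, 0] = float(ln[20:28])
                pos[k, 1] = float(ln[28:36])
                pos[k, 2] = float(ln[36:44])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}, line {start + k + 1}: malformed fixed-width atom record"
                )
        box_fields = lines[end].split()
        if len(box_fields) < 3:
            raise ParseError(f"{path}, line {end + 1}: malformed box record")
        if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise ParseError(f"{path}, line {end + 1}: triclinic boxes are not supported")
        box = np.array([float(v) for v in box_fields[:3]])
        yield time, resids, resnames, atomnames, pos, box
        frame_no += 1
        i = end + 1


def _annotate(resids, resnames, atomnames, manifest: Manifest):
    """Derive molecule ids/types, chains and 1-based residue indices."""
    n = len(resids)
    mol_types = np.array([manifest.molecule_type(r) for r in resnames], dtype=object)
    molecule_ids = np.empty(n, dtype=int)
    chain_ids = np.empty(n, dtype=object)
    residue_idx = np.empty(n, dtype=int)

    # contiguous residues in file order (GRO resid wraps at 100000)
    res_break = np.ones(n, dtype=bool)
    res_break[1:] = (resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1])
    res_ordinal = np.cumsum(res_break) - 1  # 0-based residue ordinal

    proteins = list(manifest.proteins)
    chain_lengths = [len(p.sequence) for p in proteins]
    chain_pos = 0        # residues consumed in current protein chain
    chain_no = 0
    mol_counter = -1
    prot_mol_id: int | None = None
    prev_ord = -1
    for k in range(n):
        new_res = res_ordinal[k] != prev_ord
        prev_ord = res_ordinal[k]
        if mol_types[k] is MoleculeType.PROTEIN:
            if new_res:
                if chain_no >= len(proteins):
                    raise ClassificationError(
                        "more protein residues in file than the manifest declares"
                    )
                if chain_pos == 0:
                    mol_counter += 1
                    prot_mol_id = mol_counter
                chain_pos += 1
            molecule_ids[k] = prot_mol_id
            chain_ids[k] = proteins[chain_no].chain_id
            residue_idx[k] = chain_pos
            if new_res and chain_pos == chain_lengths[chain_no]:
                chain_no += 1
                chain_pos = 0
        else:
            if new_res:
                mol_counter += 1
            molecule_ids[k] = mol_counter
            chain_ids[k] = ""
            residue_idx[k] = 1
    if chain_no < len(proteins) and chain_pos != 0:
        raise ClassificationError(
            f"protein chain {proteins[chain_no].chain_id!r} is incomplete in the file"
        )
    return mol_types, molecule_ids, chain_ids, residue_idx


def _system_from_arrays(resids, resnames, atomnames, pos, box, manifest) -> System:
    mol_types, molecule_ids, chain_ids, residue_idx = _annotate(
        resids, resnames, atomnames, manifest)
    return System(
        atom_names=atomnames,
        type_keys=[manifest.type_key(a) for a in atomnames],
        molecule_ids=molecule_ids,
        molecule_types=mol_types,
        chain_ids=chain_ids,
        residue_indices=residue_idx,
        residue_names=resnames,
        positions=pos,
        box=box,
        protein_records=manifest.proteins,
        chain_definitions=manifest.chain_definitions,
        reference_atoms={MoleculeType(k): v
                         for k, v in manifest.reference_atoms.items()},
    )


def read_structure(path: str | Path, format: str | None = None,
                   manifest: Manifest | None = None) -> System:
    """Read a GRO or PDB structure into an annotated :class:`System`.

    ``format`` defaults to the file extension. PDB coordinates are converted
    from Å to nm; the CRYST1 record must be orthorhombic.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    manifest = manifest or Manifest()
    if fmt == "GRO":
        frames = list(_parse_gro_frames(path.read_text(), str(path)))
        if not frames:
            raise ParseError(f"{path}: no frames found")
        _, resids, resnames, atomnames, pos, box = frames[0]
        return _system_from_arrays(resids, resnames, atomnames, pos, box, manifest)
    if fmt == "PDB":
        import MDAnalysis as mda
        u = mda.Universe(str(path))
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise ParseError(f"{path}: missing CRYST1 box record")
        if not np.allclose(dims[3:], 90.0):
            raise ParseError(f"{path}: triclinic boxes are not supported")
        ag = u.atoms
        return _system_from_arrays(
            ag.resids, np.array(ag.resnames, dtype=object),
            np.array(ag.names, dtype=object),
            ag.positions / 10.0, dims[:3] / 10.0, manifest)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _format_gro_frame(out, title: str, resids, resnames, atomnames, pos, box):
    out.write(title.rstrip("\n") + "\n")
    out.write(f"{len(resids):>5d}\n")
    for k in range(len(resids)):
        out.write(
            f"{int(resids[k]) % 100000:>5d}{str(resnames[k]):<5.5s}"
            f"{str(atomnames[k]):>5.5s}{(k + 1) % 100000:>5d}"
            f"{pos[k, 0]:8.3f}{pos[k, 1]:8.3f}{pos[k, 2]:8.3f}\n"
        )
    out.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def _gro_resids(system: System) -> np.ndarray:
    """Sequential residue numbers in file order (new number per residue)."""
    n = system.n_atoms
    key_prev = None
    resid = np.empty(n, dtype=int)
    count = 0
    for k in range(n):
        key = (int(system.molecule_ids[k]), int(system.residue_indices[k]))
        if key != key_prev:
            count += 1
            key_prev = key
        resid[k] = count
    return resid


def write_structure(system: System, path: str | Path, title: str = "oligoraft system",
                    time: float | None = None) -> None:
    """Write a System (reference coordinates) as a single-frame GRO file."""
    with open(path, "w") as out:
        t = title if time is None else f"{title} t= {time:g}"
        _format_gro_frame(out, t, _gro_resids(system), system.residue_names,
                          system.atom_names, system.positions, system.box)


def write_trajectory(traj: Trajectory, path: str | Path,
                     title: str = "oligoraft frame") -> None:
    """Write a trajectory as concatenated GRO frames with ``t=`` time tokens."""
    system = traj.system
    resids = _gro_resids(system)
    with open(path, "w") as out:
        for fr in traj.frames:
            _format_gro_frame(out, f"{title} t= {fr.time:g}", resids,
                              system.residue_names, system.atom_names,
                              fr.positions, fr.box)


def read_trajectory(paths: Sequence[str | Path] | str | Path, system: System,
                    resolution_tag: str = "CG") -> Trajectory:
    """Read one or more trajectory files into a :class:`Trajectory`.

    Multi-frame GRO files are read natively; ``.xtc`` and ``.dcd`` go through
    MDAnalysis behind the same contract. Frames from all files are ordered by
    time; duplicate times and atom-count mismatches are rejected.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[Frame] = []
    counter = 0
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in (".xtc", ".dcd"):
            import MDAnalysis as mda
            u = mda.Universe.empty(system.n_atoms, trajectory=True)
            u.load_new(str(p))
            for ts in u.trajectory:
                if ts.positions.shape[0] != system.n_atoms:
                    raise StructuralError(
                        f"{p}: frame {counter} has {ts.positions.shape[0]} atoms, "
                        f"system has {system.n_atoms}")
                frames.append(Frame(float(ts.time), ts.positions / 10.0,
                                    ts.dimensions[:3] / 10.0))
                counter += 1
        else:
            for time, _, _, _, pos, box in _parse_gro_frames(p.read_text(), str(p)):
                if pos.shape[0] != system.n_atoms:
                    raise StructuralError(
                        f"{p}: frame {counter} has {pos.shape[0]} atoms, "
                        f"system has {system.n_atoms}")
                t = float(time) if time is not None else float(counter)
                frames.append(Frame(t, pos, box))
                counter += 1
    frames.sort(key=lambda fr: fr.time)
    times = [fr.time for fr in frames]
    for a, b in zip(times, times[1:]):
        if b == a:
            raise StructuralError(f"duplicate frame time t={a:g}")
    return Trajectory(system, frames, resolution_tag)
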