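"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's neighbour-search machinery:
minimum-image distances are exhaustive minima over the 9 lateral periodic
images, and every group quantity is an explicit O(N^2) double loop, so they
can certify the tree-based implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from oligoraft.core import MoleculeType, System

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_min_image(a, b, box):
    """Exhaustive minimum over the 9 lateral periodic images (z unwrapped)."""
    best = np.inf
    for ix, iy in itertools.product((-1, 0, 1), repeat=2):
        shift = np.array([ix * box[0], iy * box[1], 0.0])
        best = min(best, float(np.linalg.norm(b + shift - a)))
    return best


def brute_group_mindist(pos_a, pos_b, box):
    return min(brute_min_image(a, b, box) for a in pos_a for b in pos_b)


def brute_contact_count(pos_a, pos_b, box, d):
    return sum(brute_min_image(a, b, box) <= d for a in pos_a for b in pos_b)


def brute_pc_labels(system, frame, d):
    """Reference Lo/Ld/Lod labels for DPPC and DLPC by exhaustive pairs."""
    labels = {}
    for lt, self_lab in ((MoleculeType.DPPC, "Lo"), (MoleculeType.DLPC, "Ld")):
        other = MoleculeType.DLPC if lt is MoleculeType.DPPC else MoleculeType.DPPC
        other_pos = frame.positions[system.atoms_of_type(other)]
        for m in system.molecules_of_type(lt):
            mine = frame.positions[system.molecule_atoms(m)]
            if len(other_pos) and brute_group_mindist(mine, other_pos, frame.box) <= d:
                labels[int(m)] = "Lod"
            else:
                labels[int(m)] = self_lab
    return labels


def brute_chol_labels(system, frame, pc_labels, d):
    pc_idx = [i for i in range(system.n_atoms)
              if system.molecule_types[i] in (MoleculeType.DPPC, MoleculeType.DLPC)]
    labels = {}
    for m in system.molecules_of_type(MoleculeType.CHOL):
        mine = frame.positions[system.molecule_atoms(m)]
        touched, best, best_mol = set(), np.inf, None
        for i in pc_idx:
            dist = min(brute_min_image(a, frame.positions[i], frame.box) for a in mine)
            pm = int(system.molecule_ids[i])
            if dist <= d:
                touched.add(pc_labels[pm])
            if dist < best:
                best, best_mol = dist, pm
        if len(touched) == 1:
            labels[int(m)] = touched.pop()
        elif len(touched) >= 2:
            labels[int(m)] = "Lod"
        else:
            labels[int(m)] = pc_labels[best_mol]
    return labels


def brute_shell(system, frame, d):
    prot = frame.positions[system.protein_atom_indices()]
    al = set()
    for m in system.lipid_molecule_ids():
        mine = frame.positions[system.molecule_atoms(m)]
        if brute_group_mindist(mine, prot, frame.box) <= d:
            al.add(int(m))
    return al


def brute_group_energy(system, frame, idx_a, idx_b, table, cutoff):
    e_lj = e_c = 0.0
    for i in idx_a:
        si, ei, qi = table.params(system.type_keys[i])
        for j in idx_b:
            sj, ej, qj = table.params(system.type_keys[j])
            r = brute_min_image(frame.positions[i], frame.positions[j], frame.box)
            if r <= cutoff:
                sig, eps = 0.5 * (si + sj), np.sqrt(ei * ej)
                sr6 = (sig / r) ** 6
                e_lj += 4 * eps * (sr6 * sr6 - sr6)
                e_c += table.f_electro * qi * qj / r
    return e_lj, e_c


def brute_contact_map(system, traj):
    """Per-frame residue min distances averaged by hand."""
    idx = system.protein_atom_indices()
    keys = []
    for i in idx:
        k = (system.chain_ids[i], int(system.residue_indices[i]))
        if k not in keys:
            keys.append(k)
    n = len(keys)
    stack = []
    for fr in traj.frames:
        d = np.full((n, n), np.inf)
        for ai in idx:
            for aj in idx:
                ri = keys.index((system.chain_ids[ai], int(system.residue_indices[ai])))
                rj = keys.index((system.chain_ids[aj], int(system.residue_indices[aj])))
                v = brute_min_image(fr.positions[ai], fr.positions[aj], fr.box)
                d[ri, rj] = min(d[ri, rj], v)
        stack.append(d)
    stack = np.array(stack)
    return stack.mean(axis=0), stack.std(axis=0)


# ---------------------------------------------------------------------------
# random-system factory
# ---------------------------------------------------------------------------

def make_random_system(rng, n_lipids=60, atoms_per_lipid=3, box=(6.0, 6.0, 8.0),
                       types=(MoleculeType.DPPC, MoleculeType.DLPC, MoleculeType.CHOL),
                       with_protein=0):
    """Small random membrane-like System for oracle-equivalence tests."""
    box = np.asarray(box, dtype=float)
    names, resnames, mol_ids, mol_types, chain_ids, res_idx, pos = \
        [], [], [], [], [], [], []
    mol = 0
    for _ in range(n_lipids):
        lt = types[int(rng.integers(len(types)))]
        centre = rng.uniform(0, 1, 3) * box
        for a in range(atoms_per_lipid):
            names.append(f"X{a}")
            resnames.append(lt.value)
            mol_ids.append(mol)
            mol_types.append(lt)
            chain_ids.append("")
            res_idx.append(1)
            pos.append(centre + rng.normal(0, 0.2, 3))
        mol += 1
    records = []
    if with_protein:
        from oligoraft.core import ProteinRecord
        records = [ProteinRecord("A", "A" * with_protein, "amylin")]
        centre = rng.uniform(0, 1, 3) * box
        for r in range(1, with_protein + 1):
            names.append("BB")
            resnames.append("ALA")
            mol_ids.append(mol)
            mol_types.append(MoleculeType.PROTEIN)
            chain_ids.append("A")
            res_idx.append(r)
            pos.append(centre + rng.normal(0, 0.4, 3))
        mol += 1
    return System(
        atom_names=names, type_keys=["XT" if m is not MoleculeType.PROTEIN else "PR0"
                                     for m in mol_types],
        molecule_ids=mol_ids, molecule_types=mol_types, chain_ids=chain_ids,
        residue_indices=res_idx, residue_names=resnames,
        positions=np.array(pos), box=box, protein_records=records)


@pytest.fixture(scope="session")
def ps_complex():
    """Reduced PS-raft with a bound hetero-dimer and a short trajectory."""
    from oligoraft import synthetic as syn

    spec = syn.RaftSpec.from_raft_type("PS", scale=8, seed=11)
    system = syn.assemble_complex(syn.build_raft(spec), "1tam")
    tspec = syn.TrajectorySpec(n_frames=12, frame_spacing=1.25, t_bind=5.0, seed=12)
    traj = syn.generate_binding_trajectory(system, tspec)
    return system, traj
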