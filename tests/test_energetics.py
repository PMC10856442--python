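"""Pair potentials and group energies against analytic values and oracles."""

import numpy as np
import pytest

from oligoraft import synthetic as syn
from oligoraft.core import Frame, MoleculeType, ProteinRecord, System, Trajectory
from oligoraft.energetics import (
    F_ELECTRO,
    EnergyBreakdown,
    ForceFieldTable,
    ParameterError,
    group_interaction_energy,
    interchain_energy,
    pair_coulomb,
    pair_lj,
    protein_lipidtype_energy,
)

from conftest import brute_group_energy, make_random_system


def test_lj_roots_and_minimum():
    sigma, eps = 0.47, 3.0
    assert pair_lj(sigma, sigma, eps) == pytest.approx(0.0, abs=1e-12)
    r_min = 2 ** (1 / 6) * sigma
    assert pair_lj(r_min, sigma, eps) == pytest.approx(-eps)
    tail = pair_lj(10 * sigma, sigma, eps)
    assert tail < 0
    # direct evaluation: 4 eps (10^-12 - 10^-6) ~ -4e-6 eps
    assert tail == pytest.approx(4 * eps * (1e-12 - 1e-6), rel=1e-9)


def test_lj_singular_at_zero():
    with pytest.raises(ZeroDivisionError):
        pair_lj(0.0, 0.47, 1.0)


def test_coulomb_unit_charges_at_one_nm():
    # f = 1/(4 pi eps0) converted to kJ mol^-1 nm e^-2:
    # e^2 N_A / (4 pi eps0 * 1 nm) = 138.935 kJ/mol
    e = 1.602176634e-19
    na = 6.02214076e23
    eps0 = 8.8541878128e-12
    f_expected = e * e * na / (4 * np.pi * eps0 * 1e-9) / 1000.0
    assert F_ELECTRO == pytest.approx(f_expected, rel=1e-6)
    assert pair_coulomb(1.0, 1.0, 1.0) == pytest.approx(138.935, abs=1e-3)
    assert pair_coulomb(1.0, 1.0, -1.0) == pytest.approx(-138.935, abs=1e-3)
    assert pair_coulomb(2.0, 0.0, 1.0) == 0.0


def _pair_system(r, q=0.0):
    table = ForceFieldTable(sigma={"T1": 0.4}, epsilon={"T1": 2.0},
                            charge={"T1": q})
    system = System(
        atom_names=["X", "Y"], type_keys=["T1", "T1"], molecule_ids=[0, 1],
        molecule_types=[MoleculeType.PROTEIN, MoleculeType.DPPC],
        chain_ids=["A", ""], residue_indices=[1, 1],
        residue_names=["ALA", "DPPC"],
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]),
        box=np.array([10.0, 10.0, 10.0]),
        protein_records=[ProteinRecord("A", "A", "amylin")])
    return system, table


def test_group_energy_zero_beyond_cutoff():
    system, table = _pair_system(3.0)
    e = group_interaction_energy(system, Frame(0, system.positions, system.box),
                                 np.array([0]), np.array([1]), table, cutoff=1.2)
    assert e.e_lj == 0.0 and e.e_coulomb == 0.0 and e.n_pairs == 0


def test_group_energy_at_lj_minimum():
    r = 2 ** (1 / 6) * 0.4
    system, table = _pair_system(r)
    e = group_interaction_energy(system, Frame(0, system.positions, system.box),
                                 np.array([0]), np.array([1]), table)
    assert e.e_lj == pytest.approx(-2.0)
    assert e.e_total == pytest.approx(e.e_lj + e.e_coulomb, rel=1e-9)


def test_missing_type_key_raises_parameter_error():
    system, table = _pair_system(0.5)
    bad = ForceFieldTable(sigma={"Z": 0.4}, epsilon={"Z": 1.0}, charge={"Z": 0.0})
    with pytest.raises(ParameterError, match="T1"):
        group_interaction_energy(system, Frame(0, system.positions, system.box),
                                 np.array([0]), np.array([1]), bad)


def test_overlapping_groups_rejected():
    system, table = _pair_system(0.5)
    with pytest.raises(ValueError, match="disjoint"):
        group_interaction_energy(system, Frame(0, system.positions, system.box),
                                 np.array([0, 1]), np.array([1]), table)


@pytest.mark.parametrize("seed", range(5))
def test_group_energy_matches_brute_force(seed):
    rng = np.random.default_rng(500 + seed)
    system = make_random_system(rng, n_lipids=25, atoms_per_lipid=2,
                                with_protein=10)
    table = ForceFieldTable(sigma={"XT": 0.45, "PR0": 0.40},
                            epsilon={"XT": 2.0, "PR0": 3.0},
                            charge={"XT": -0.1, "PR0": 0.2})
    fr = Frame(0, system.positions, system.box)
    prot = system.protein_atom_indices()
    lip = np.array([i for i in range(system.n_atoms) if i not in prot])
    e = group_interaction_energy(system, fr, prot, lip, table, cutoff=1.2)
    lj, co = brute_group_energy(system, fr, prot, lip, table, 1.2)
    assert e.e_lj == pytest.approx(lj, rel=1e-9, abs=1e-9)
    assert e.e_coulomb == pytest.approx(co, rel=1e-9, abs=1e-9)


def test_group_energy_symmetric_and_additive():
    rng = np.random.default_rng(60)
    system = make_random_system(rng, n_lipids=30, with_protein=6)
    table = ForceFieldTable(sigma={"XT": 0.45, "PR0": 0.40},
                            epsilon={"XT": 2.0, "PR0": 3.0},
                            charge={"XT": -0.1, "PR0": 0.2})
    fr = Frame(0, system.positions, system.box)
    prot = system.protein_atom_indices()
    lip = np.array([i for i in range(system.n_atoms) if i not in prot])
    ab = group_interaction_energy(system, fr, prot, lip, table)
    ba = group_interaction_energy(system, fr, lip, prot, table)
    assert ab.e_total == pytest.approx(ba.e_total, rel=1e-9)
    half = len(lip) // 2
    e1 = group_interaction_energy(system, fr, prot, lip[:half], table)
    e2 = group_interaction_energy(system, fr, prot, lip[half:], table)
    assert e1.e_total + e2.e_total == pytest.approx(ab.e_total, rel=1e-9)


def test_doubling_charges_quadruples_coulomb():
    rng = np.random.default_rng(61)
    system = make_random_system(rng, n_lipids=20, with_protein=5)
    fr = Frame(0, system.positions, system.box)
    prot = system.protein_atom_indices()
    lip = np.array([i for i in range(system.n_atoms) if i not in prot])
    t1 = ForceFieldTable(sigma={"XT": 0.45, "PR0": 0.40},
                         epsilon={"XT": 2.0, "PR0": 3.0},
                         charge={"XT": -0.2, "PR0": 0.3})
    t2 = ForceFieldTable(sigma=t1.sigma, epsilon=t1.epsilon,
                         charge={k: 2 * v for k, v in t1.charge.items()})
    e1 = group_interaction_energy(system, fr, prot, lip, t1)
    e2 = group_interaction_energy(system, fr, prot, lip, t2)
    assert e2.e_coulomb == pytest.approx(4 * e1.e_coulomb, rel=1e-9)
    assert e2.e_lj == pytest.approx(e1.e_lj, rel=1e-9)


# -- oligomer-level sums ------------------------------------------------------

def _stacked_chains(n_chains, dz=0.4):
    """n single-residue chains stacked vertically at the LJ-minimum spacing."""
    names, mol_ids, chain_ids, res_idx, resnames, pos = [], [], [], [], [], []
    records = []
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        records.append(ProteinRecord(cid, "A", "amylin"))
        names.append("BB")
        mol_ids.append(c)
        chain_ids.append(cid)
        res_idx.append(1)
        resnames.append("ALA")
        pos.append([1.0, 1.0, 1.0 + c * dz])
    return System(
        atom_names=names, type_keys=["PR0"] * n_chains, molecule_ids=mol_ids,
        molecule_types=[MoleculeType.PROTEIN] * n_chains, chain_ids=chain_ids,
        residue_indices=res_idx, residue_names=resnames,
        positions=np.array(pos), box=np.array([10.0, 10.0, 10.0]),
        protein_records=records)


def _traj(system):
    return Trajectory(system, [Frame(0.0, system.positions, system.box)])


def test_monomer_has_no_interchain_energy():
    table = ForceFieldTable(sigma={"PR0": 0.4}, epsilon={"PR0": 1.0},
                            charge={"PR0": 0.0})
    assert interchain_energy([_traj(_stacked_chains(1))], table) is None


def test_interchain_pair_combinatorics():
    """A planted two-chain contact at the LJ minimum gives exactly -epsilon;
    the tetramer sums all six chain pairs."""
    r_min = 2 ** (1 / 6) * 0.4
    table = ForceFieldTable(sigma={"PR0": 0.4}, epsilon={"PR0": 2.0},
                            charge={"PR0": 0.0})
    dimer = _stacked_chains(2, dz=r_min)
    e2 = interchain_energy([_traj(dimer)], table)
    assert e2.e_lj == pytest.approx(-2.0)
    # tetramer at wide spacing: only the 3 adjacent pairs are inside the
    # cutoff; farther pairs contribute their (tiny) tail or nothing
    tet = _stacked_chains(4, dz=r_min)
    e4 = interchain_energy([_traj(tet)], table)
    expect = (3 * pair_lj(r_min, 0.4, 2.0)
              + 2 * pair_lj(2 * r_min, 0.4, 2.0))  # 2r_min < 1.2 cutoff
    # the 3 * r_min pairs exceed the 1.2 nm cutoff
    assert 3 * r_min > 1.2
    assert e4.e_lj == pytest.approx(expect, rel=1e-9)


def test_protein_touching_ps_cluster_ranks_pops_first(ps_complex):
    system, traj = ps_complex
    table = syn.emit_forcefield_table()
    df = protein_lipidtype_energy([traj], table, window=5.0)
    ranked = df.set_index("lipid_type")["e_total"].abs().sort_values(ascending=False)
    assert ranked.index[0] == "POPS"
    others = df[df.lipid_type != "POPS"]["e_total"].abs()
    pops = float(df[df.lipid_type == "POPS"]["e_total"].abs().iloc[0])
    assert pops > 5 * others.max()
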