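"""Mindist kinetics, binding-time detection, spectra and annular shells."""

import numpy as np
import pytest

from oligoraft import synthetic as syn
from oligoraft.binding import (
    ContactSeries,
    MindistSeries,
    SelectionError,
    classify_annular_shell,
    contact_count_series,
    detect_binding_time,
    mindist_series,
    mindist_spectrum,
    moving_average,
)
from oligoraft.core import Frame, MoleculeType, ProteinRecord, System, Trajectory

from conftest import (
    brute_contact_count,
    brute_group_mindist,
    brute_shell,
    make_random_system,
)


def _static_traj(system, n_frames=3):
    frames = [Frame(float(t), system.positions, system.box)
              for t in range(n_frames)]
    return Trajectory(system, frames)


def _two_atom_system(d=1.0):
    return System(
        atom_names=["BB", "C1A"], type_keys=["PR0", "CT"],
        molecule_ids=[0, 1],
        molecule_types=[MoleculeType.PROTEIN, MoleculeType.DPPC],
        chain_ids=["A", ""], residue_indices=[1, 1],
        residue_names=["ALA", "DPPC"],
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]),
        box=np.array([10.0, 10.0, 10.0]),
        protein_records=[ProteinRecord("A", "A", "amylin")])


def test_mindist_single_pair():
    traj = _static_traj(_two_atom_system(1.0))
    ms = mindist_series(traj, "protein", MoleculeType.DPPC)
    assert np.allclose(ms.values, 1.0)


def test_mindist_coincident_atoms_is_zero():
    traj = _static_traj(_two_atom_system(0.0))
    ms = mindist_series(traj, "protein", MoleculeType.DPPC)
    assert np.allclose(ms.values, 0.0)


def test_empty_selection_raises():
    traj = _static_traj(_two_atom_system())
    with pytest.raises(SelectionError):
        mindist_series(traj, "protein", MoleculeType.GM1)


@pytest.mark.parametrize("seed", range(5))
def test_mindist_and_contacts_match_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    system = make_random_system(rng, n_lipids=30, atoms_per_lipid=3,
                                with_protein=10)
    traj = _static_traj(system, 2)
    prot = system.protein_atom_indices()
    lip = np.array([i for i in range(system.n_atoms) if i not in prot])
    fr = traj.frames[0]
    expect_min = brute_group_mindist(fr.positions[prot], fr.positions[lip], fr.box)
    ms = mindist_series(traj, prot, lip)
    assert ms.values[0] == pytest.approx(expect_min, abs=1e-10)
    for d in (0.5, 1.0, 2.0):
        cs = contact_count_series(traj, prot, lip, d)
        assert cs.counts[0] == brute_contact_count(fr.positions[prot],
                                                   fr.positions[lip], fr.box, d)


def test_contact_counting_is_pairwise():
    # 2 protein atoms each within threshold of 3 lipid atoms -> 6 pairs
    names = ["BB", "BB"] + ["C1A"] * 3
    system = System(
        atom_names=names, type_keys=["PR0"] * 2 + ["CT"] * 3,
        molecule_ids=[0, 0, 1, 2, 3],
        molecule_types=[MoleculeType.PROTEIN] * 2 + [MoleculeType.DPPC] * 3,
        chain_ids=["A", "A", "", "", ""], residue_indices=[1, 2, 1, 1, 1],
        residue_names=["ALA", "ALA", "DPPC", "DPPC", "DPPC"],
        positions=np.array([[0, 0, 0], [0, 0, 0.2],
                            [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.7]], dtype=float),
        box=np.array([10.0, 10.0, 10.0]),
        protein_records=[ProteinRecord("A", "AA", "amylin")])
    traj = _static_traj(system, 1)
    cs = contact_count_series(traj, "protein", MoleculeType.DPPC, d_contact=1.0)
    assert cs.counts[0] == 6


def test_contact_count_monotone_in_threshold():
    rng = np.random.default_rng(8)
    system = make_random_system(rng, n_lipids=20, with_protein=5)
    traj = _static_traj(system, 1)
    prot = system.protein_atom_indices()
    lip = np.array([i for i in range(system.n_atoms) if i not in prot])
    counts = [contact_count_series(traj, prot, lip, d).counts[0]
              for d in (0.3, 0.6, 1.0, 2.0)]
    assert counts == sorted(counts)


# -- binding-time detection ---------------------------------------------------

def _series(values, times=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float) if times is None else np.asarray(times)
    return MindistSeries(times, values)


def test_constant_low_series_binds_at_first_frame():
    assert detect_binding_time(_series([0.5] * 5), 0.6) == 0.0


def test_plateau_onset_detected():
    assert detect_binding_time(_series([5, 4, 0.5, 0.5, 0.5]), 0.6) == 2.0


def test_unbound_series_returns_none():
    assert detect_binding_time(_series([5, 4, 3, 2.5, 5]), 0.6) is None


def test_late_excursion_moves_persistent_onset():
    # a single excursion above threshold restarts the persistent suffix
    assert detect_binding_time(_series([0.5, 0.9, 0.5, 0.5]), 0.6) == 2.0
    # ... but a dwell-window detector tolerates it
    assert detect_binding_time(_series([0.5, 0.9, 0.5, 0.5]), 0.6,
                               dwell_frames=1) == 0.0


def test_binding_time_monotone_in_threshold():
    s = _series([3.0, 1.1, 0.7, 0.55, 0.5, 0.5])
    ts = [detect_binding_time(s, d) for d in (0.5, 0.6, 0.8, 1.2)]
    assert ts == sorted(ts, reverse=True)


def test_contact_onset_trailing_run():
    cs = ContactSeries(np.arange(5.0), np.array([0, 3, 0, 7, 9]))
    assert detect_binding_time(cs, mode="contact_onset") == 3.0
    cs0 = ContactSeries(np.arange(3.0), np.array([4, 2, 0]))
    assert detect_binding_time(cs0, mode="contact_onset") is None


def test_planted_binding_time_recovered_by_both_modes(ps_complex):
    system, _ = ps_complex
    spec = syn.TrajectorySpec(n_frames=150, frame_spacing=0.1, t_bind=3.0, seed=21)
    traj = syn.generate_binding_trajectory(system, spec)
    prot = system.protein_atom_indices()
    lip = np.concatenate([system.atoms_of_type(t) for t in
                          (MoleculeType.DPPC, MoleculeType.DLPC,
                           MoleculeType.CHOL, MoleculeType.POPS)])
    ms = mindist_series(traj, prot, lip)
    cs = contact_count_series(traj, prot, lip, 2.0)
    t_mind = detect_binding_time(ms, 0.6)
    t_cont = detect_binding_time(cs, mode="contact_onset")
    assert t_mind == pytest.approx(3.0, abs=spec.frame_spacing)
    assert t_cont == t_mind


# -- spectra ------------------------------------------------------------------

def test_single_residue_static_spectrum():
    traj = _static_traj(_two_atom_system(0.7))
    sp = mindist_spectrum([traj], "amylin", MoleculeType.DPPC, smooth=None)
    assert sp.values == pytest.approx([0.7])


def test_chain_averaging_arithmetic():
    # two identical two-residue chains at different distances from the lipid
    names = ["BB"] * 4 + ["C1A"]
    pos = np.array([[0, 0, 0.2], [0, 0, 0.6],     # chain A residues 1,2
                    [0, 0, 0.4], [0, 0, 0.8],     # chain B residues 1,2
                    [0, 0, 0.0]], dtype=float)    # lipid atom
    system = System(
        atom_names=names, type_keys=["PR0"] * 4 + ["CT"],
        molecule_ids=[0, 0, 1, 1, 2],
        molecule_types=[MoleculeType.PROTEIN] * 4 + [MoleculeType.DPPC],
        chain_ids=["A", "A", "B", "B", ""], residue_indices=[1, 2, 1, 2, 1],
        residue_names=["ALA"] * 4 + ["DPPC"],
        positions=pos, box=np.array([10.0, 10.0, 10.0]),
        protein_records=[ProteinRecord("A", "AA", "amylin"),
                         ProteinRecord("B", "AA", "amylin")])
    traj = _static_traj(system, 2)
    sp = mindist_spectrum([traj], "amylin", MoleculeType.DPPC, smooth=None)
    assert sp.values == pytest.approx([0.3, 0.7])


def test_planted_anchor_residues_are_spectrum_minima(ps_complex):
    system0, _ = ps_complex
    raft = syn.build_raft(syn.RaftSpec.from_raft_type("PS", scale=8, seed=31))
    anchors = {"B": [12, 13, 14, 15]}  # amylin chain of the hetero-dimer
    system = syn.assemble_complex(raft, "1tam", anchor_residues=anchors)
    spec = syn.TrajectorySpec(n_frames=10, frame_spacing=1.0, t_bind=2.0, seed=32)
    traj = syn.generate_binding_trajectory(system, spec)
    lip = np.concatenate([system.atoms_of_type(t) for t in
                          (MoleculeType.DPPC, MoleculeType.DLPC,
                           MoleculeType.CHOL, MoleculeType.POPS)])
    sp = mindist_spectrum([traj], "amylin", lip, window=5.0, smooth=None)
    best = set(np.argsort(sp.values)[:4] + 1)
    assert best == {12, 13, 14, 15}


def test_moving_average_preserves_constant_profile():
    assert np.allclose(moving_average(np.full(9, 2.5), 5), 2.5)


# -- annular shell ------------------------------------------------------------

def test_shell_threshold_boundary():
    for d, expect_al in ((0.45, True), (0.55, False)):
        system = _two_atom_system(d)
        shell = classify_annular_shell(system, Frame(0.0, system.positions,
                                                     system.box), 0.5)
        assert (1 in shell.al) is expect_al


def test_empty_shell_reports_absent_percentages():
    system = _two_atom_system(3.0)
    shell = classify_annular_shell(system, Frame(0.0, system.positions,
                                                 system.box), 0.5)
    assert shell.percentages is None
    assert shell.al == set()


@pytest.mark.parametrize("seed", range(5))
def test_shell_matches_brute_force(seed):
    rng = np.random.default_rng(400 + seed)
    system = make_random_system(rng, n_lipids=40, with_protein=8)
    fr = Frame(0.0, system.positions, system.box)
    shell = classify_annular_shell(system, fr, 0.5)
    assert shell.al == brute_shell(system, fr, 0.5)
    assert shell.al | shell.nal == {int(m) for m in system.lipid_molecule_ids()}
    assert not shell.al & shell.nal
    if shell.percentages:
        assert sum(shell.percentages.values()) == pytest.approx(100.0)
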