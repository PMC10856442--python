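"""Hydropathy profiles, DSSP regrouping, summaries and contact maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oligoraft import synthetic as syn
from oligoraft.core import Frame, MoleculeType, ProteinRecord, System, Trajectory
from oligoraft.protein import (
    hydropathy_profile,
    interface_map,
    local_maxima,
    regroup_dssp,
    residue_contact_map,
    ss_summary,
)
from oligoraft.sequences import AMYLIN_SEQUENCE, TAU_SEQUENCE

from conftest import brute_contact_map


# -- hydropathy ---------------------------------------------------------------

def test_poly_isoleucine_profile_is_flat_at_scale_value():
    prof = hydropathy_profile("I" * 10)
    assert np.allclose(prof.raw, 4.5)
    assert np.allclose(prof.smoothed, 4.5)


def test_window_one_is_identity():
    prof = hydropathy_profile(AMYLIN_SEQUENCE, window=1)
    assert np.array_equal(prof.smoothed, prof.raw)


def test_unknown_letter_rejected():
    with pytest.raises(ValueError, match="X"):
        hydropathy_profile("AAXAA")


def test_amylin_hydrophobic_landmarks_are_profile_maxima():
    """The smoothed amylin profile peaks at/near the key hydrophobic
    residues C7, L16, I26 and V32."""
    prof = hydropathy_profile(AMYLIN_SEQUENCE, window=5)
    peaks = local_maxima(prof.smoothed)
    for landmark in (7, 16, 26, 32):
        assert any(abs(p - landmark) <= 2 for p in peaks), landmark


def test_tau_construct_landmarks_are_hydrophobic():
    for pos, aa in ((6, "V"), (35, "I"), (66, "I"), (86, "I"),
                    (112, "I"), (121, "V")):
        assert TAU_SEQUENCE[pos - 1] == aa


# -- DSSP regrouping ----------------------------------------------------------

def test_regroup_mapping_counts():
    counts = regroup_dssp(np.array(list("HGIEBTSC"))).counts.iloc[0]
    assert counts["alpha"] == 3
    assert counts["beta"] == 2
    assert counts["turn"] == 1
    assert counts["random"] == 2


def test_all_coil_frame():
    counts = regroup_dssp(np.array([list("C" * 37)])).counts.iloc[0]
    assert counts["random"] == 37
    assert counts[["beta", "alpha", "turn"]].sum() == 0


def test_unknown_code_named_in_error():
    with pytest.raises(ValueError, match="Q"):
        regroup_dssp(np.array(list("HEQ")))


def test_hetero_dimer_counts_partition_167_residues():
    spec = syn.SSTraceSpec((0.3, 0.3, 0.2, 0.2), 167, 25, seed=5)
    counts = regroup_dssp(syn.generate_ss_trace(spec)).counts
    assert (counts.sum(axis=1) == 167).all()


@given(st.lists(st.sampled_from("HGIEBTSC"), min_size=1, max_size=60))
def test_category_counts_always_partition(codes):
    counts = regroup_dssp(np.array(codes)).counts
    assert (counts.sum(axis=1) == len(codes)).all()


# -- summaries ----------------------------------------------------------------

def test_two_replicate_mean_and_sem():
    t1 = np.array([list("E" * 10 + "C" * 27)])   # beta 10
    t2 = np.array([list("E" * 14 + "C" * 23)])   # beta 14
    out = ss_summary([t1, t2]).set_index("category")
    assert out.loc["beta", "mean"] == pytest.approx(12.0)
    assert out.loc["beta", "sem"] == pytest.approx(2.0)


def test_planted_fractions_recovered_within_three_se():
    specs = [syn.SSTraceSpec((0.25, 0.25, 0.25, 0.25), 167, 200, seed=s)
             for s in (1, 2, 3)]
    out = ss_summary([syn.generate_ss_trace(s) for s in specs]).set_index("category")
    se = np.sqrt(167 * 0.25 * 0.75 / (200 * 3))
    for cat in ("beta", "alpha", "turn", "random"):
        assert abs(out.loc[cat, "mean"] - 41.75) < 3 * se


def test_stacked_sum_residue_totals_match_hetero_oligomers():
    from oligoraft.sequences import oligomer_residue_count

    # homo dimer comparison: 1tau + 1am stacks to the hetero-dimer's size
    assert (oligomer_residue_count("1tau") + oligomer_residue_count("1am")
            == oligomer_residue_count("1tam") == 167)
    assert (oligomer_residue_count("2tau") + oligomer_residue_count("2am")
            == oligomer_residue_count("2tam") == 334)
    tau_trace = syn.generate_ss_trace(syn.SSTraceSpec((0.3, 0.2, 0.2, 0.3), 130, 10, 1))
    am_trace = syn.generate_ss_trace(syn.SSTraceSpec((0.3, 0.2, 0.2, 0.3), 37, 10, 2))
    stacked = np.concatenate([tau_trace, am_trace], axis=1)
    out = ss_summary([stacked])
    assert out["mean"].sum() == pytest.approx(167.0)


def test_residue_subset_extracts_constituent_chain():
    trace = syn.generate_ss_trace(syn.SSTraceSpec((0.4, 0.2, 0.2, 0.2), 167, 10, 3))
    amylin_cols = np.arange(130, 167)  # the amylin chain of a hetero-dimer
    out = ss_summary([trace], residue_subset=amylin_cols)
    assert out["mean"].sum() == pytest.approx(37.0)


def test_window_longer_than_trace_rejected():
    trace = syn.generate_ss_trace(syn.SSTraceSpec((1, 0, 0, 0), 5, 4, 0))
    with pytest.raises(ValueError, match="window"):
        ss_summary([trace], last_frames=10)


# -- contact maps -------------------------------------------------------------

def _toy_protein(n_res_a=2, n_res_b=0, jitter=None, seed=0):
    rng = np.random.default_rng(seed)
    names, mol_ids, mol_types, chain_ids, res_idx, resnames, pos = \
        [], [], [], [], [], [], []
    records = []
    chains = [("A", n_res_a)] + ([("B", n_res_b)] if n_res_b else [])
    for ci, (cid, n) in enumerate(chains):
        records.append(ProteinRecord(cid, "A" * n, "amylin"))
        for r in range(1, n + 1):
            names.append("BB")
            mol_ids.append(ci)
            mol_types.append(MoleculeType.PROTEIN)
            chain_ids.append(cid)
            res_idx.append(r)
            resnames.append("ALA")
            pos.append([1 + 0.8 * r, 1 + 2 * ci, 2.0])
    return System(
        atom_names=names, type_keys=["PR0"] * len(names), molecule_ids=mol_ids,
        molecule_types=mol_types, chain_ids=chain_ids, residue_indices=res_idx,
        residue_names=resnames, positions=np.array(pos, dtype=float),
        box=np.array([50.0, 50.0, 50.0]), protein_records=records)


def test_static_two_residue_map():
    system = _toy_protein(2)
    traj = Trajectory(system, [Frame(float(t), system.positions, system.box)
                               for t in range(3)])
    cmap = residue_contact_map(traj)
    assert cmap.mean[0, 1] == pytest.approx(0.8)
    assert np.allclose(cmap.sd, 0.0)
    assert np.allclose(np.diag(cmap.mean), 0.0)
    assert np.allclose(cmap.mean, cmap.mean.T)


def test_random_walk_map_matches_brute_force():
    rng = np.random.default_rng(71)
    system = _toy_protein(10)
    frames = []
    for t in range(20):
        frames.append(Frame(float(t),
                            system.positions + rng.normal(0, 0.3, system.positions.shape),
                            system.box))
    traj = Trajectory(system, frames)
    cmap = residue_contact_map(traj)
    mean, sd = brute_contact_map(system, traj)
    assert np.allclose(cmap.mean, mean, atol=1e-10)
    assert np.allclose(cmap.sd, sd, atol=1e-10)


def test_interface_block_shape_and_symmetry():
    system = _toy_protein(130, 37)
    traj = Trajectory(system, [Frame(0.0, system.positions, system.box)])
    cmap = residue_contact_map(traj)
    block, sd_block = interface_map(cmap, "A", "B")
    assert block.shape == (130, 37)
    swapped, _ = interface_map(cmap, "B", "A")
    assert np.allclose(block, swapped.T)


def test_self_interface_rejected():
    system = _toy_protein(4, 3)
    traj = Trajectory(system, [Frame(0.0, system.positions, system.box)])
    cmap = residue_contact_map(traj)
    with pytest.raises(ValueError, match="disjoint"):
        interface_map(cmap, "A", "A")


def test_planted_cross_chain_contact_is_block_minimum():
    """An amylin C-terminal residue placed against a tau mid-region residue
    shows up as the interface-block minimum."""
    system = _toy_protein(130, 37)
    pos = system.positions.copy()
    # tau residue 65 (chain A) and amylin residue 35 (chain B, row 130+34)
    pos[130 + 34] = pos[64] + np.array([0.0, 0.0, 0.3])
    traj = Trajectory(system.with_positions(pos),
                      [Frame(0.0, pos, system.box)])
    cmap = residue_contact_map(traj)
    block, _ = interface_map(cmap, "A", "B")
    i, j = np.unravel_index(np.argmin(block), block.shape)
    assert (i + 1, j + 1) == (65, 35)
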