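"""Quartet detection, stacking, polarity, loop and V-loop classification."""
import itertools

import numpy as np
import pytest

from g4conform import (
    build_mock_quadruplex, build_quartet, detect_hoogsteen_edges, detect_quartets,
    model_topology, preset, quartet_polarity, stack_quartets,
)
from g4conform.geometry import random_rigid_transform
from g4conform.structure import Atom, Model, Residue
from conftest import detected_summary, truth_summary


def brute_force_edges(model, cutoff=3.5):
    """Direct double loop over guanine pairs (oracle for the graph builder)."""
    out = []
    gs = model.guanines()
    for a in gs:
        for b in gs:
            if a is b:
                continue
            if (np.linalg.norm(a.pos("N1") - b.pos("O6")) <= cutoff
                    and np.linalg.norm(a.pos("N2") - b.pos("N7")) <= cutoff):
                out.append((a.key, b.key))
    return sorted(out)


def brute_force_cycles(edges):
    """Enumerate directed 4-cycles by exhaustive permutation (oracle)."""
    edge_set = set(edges)
    nodes = sorted({k for e in edges for k in e})
    cycles = set()
    for quad in itertools.permutations(nodes, 4):
        if all(
            (quad[i], quad[(i + 1) % 4]) in edge_set for i in range(4)
        ):
            start = quad.index(min(quad))
            cycles.add(tuple(quad[start:] + quad[:start]))
    return cycles


def test_ideal_quartet_gives_four_edges_one_cycle():
    model = Model(build_quartet(+1))
    edges = detect_hoogsteen_edges(model)
    assert len(edges) == 4
    assert [(e.donor.key, e.acceptor.key) for e in edges] == brute_force_edges(model)
    quartets = detect_quartets(edges)
    assert len(quartets) == 1
    assert all(d <= 3.0 for e in edges for *_, d in e.bonds)


def test_distant_guanines_no_edges():
    g1, g2 = build_quartet(+1)[:2]
    for atom in g2.atoms:
        atom.position = atom.position + np.array([20.0, 0.0, 0.0])
    model = Model([g1, g2])
    assert detect_hoogsteen_edges(model) == []


def test_displaced_base_breaks_cycle():
    quartet = build_quartet(+1)
    for atom in quartet[2].atoms:
        atom.position = atom.position + np.array([5.0, 0.0, 0.0])
    model = Model(quartet)
    edges = detect_hoogsteen_edges(model)
    keys = [(e.donor.key, e.acceptor.key) for e in edges]
    assert sorted(keys) == brute_force_edges(model)
    assert len(edges) == 2  # both edges touching the displaced base are lost
    assert detect_quartets(edges) == []


def test_random_guanine_cloud_has_no_quartets():
    rng = np.random.default_rng(1)
    residues = []
    for i in range(8):
        g = build_quartet(+1)[0]
        R, t = random_rigid_transform(rng)
        residues.append(Residue(
            "A", i + 1, "DG",
            [Atom(a.name, a.element, R @ a.position + t) for a in g.atoms],
        ))
    model = Model(residues)
    edges = detect_hoogsteen_edges(model)
    detected = {q.member_keys for q in detect_quartets(edges)}
    oracle = brute_force_cycles([(e.donor.key, e.acceptor.key) for e in edges])
    assert detected <= oracle
    assert detected == set() == oracle


def test_quartet_polarity_antisymmetry_and_mirror(z_axis):
    plus = detect_quartets(detect_hoogsteen_edges(Model(build_quartet(+1))))[0]
    minus = detect_quartets(detect_hoogsteen_edges(Model(build_quartet(-1))))[0]
    assert quartet_polarity(plus, z_axis) == -quartet_polarity(minus, z_axis)

    reversed_members = [plus.members[0]] + plus.members[1:][::-1]
    import dataclasses
    rev = dataclasses.replace(plus, members=reversed_members)
    assert quartet_polarity(rev, z_axis) == -quartet_polarity(plus, z_axis)

    M = np.diag([-1.0, 1.0, 1.0])
    mirrored = [
        Residue("A", r.seq_index, r.name,
                [Atom(a.name, a.element, M @ a.position) for a in r.atoms])
        for r in Model(build_quartet(+1)).residues
    ]
    mq = detect_quartets(detect_hoogsteen_edges(Model(mirrored)))[0]
    assert quartet_polarity(mq, z_axis) == -quartet_polarity(plus, z_axis)


def test_stacking_layers_columns_and_order_invariance(parallel_model, z_axis):
    model, truth = parallel_model
    topo = model_topology(model, axis_hint=z_axis)
    assert topo.n_layers == 3
    assert len(topo.columns) == 4
    assert all(t.orientation == "down" for t in topo.tracts)
    assert sum(len(l) for l in topo.layers) == 4 * topo.n_layers

    rng = np.random.default_rng(0)
    order = rng.permutation(len(model.residues))
    shuffled = Model([model.residues[i] for i in order])
    topo2 = model_topology(shuffled, axis_hint=z_axis)
    assert [sorted(r.key for r in l) for l in topo2.layers] == \
        [sorted(r.key for r in l) for l in topo.layers]


def test_topology_rigid_motion_invariant(parallel_model, z_axis):
    model, _ = parallel_model
    ref = model_topology(model, axis_hint=z_axis).summary()
    rng = np.random.default_rng(2)
    R, t = random_rigid_transform(rng)
    moved = Model([
        Residue(r.chain_id, r.seq_index, r.name,
                [Atom(a.name, a.element, R @ a.position + t) for a in r.atoms])
        for r in model.residues
    ])
    got = model_topology(moved, axis_hint=R @ z_axis).summary()
    assert got == ref


def test_hybrid_fixture_loop_types(z_axis):
    ens, truth = build_mock_quadruplex(preset("hybrid", sigma=0.0, n_models=1))
    topo = model_topology(ens.models[0], axis_hint=z_axis)
    assert [lp.kind for lp in topo.loops] == ["propeller", "lateral", "lateral"]
    assert "heteropolar" in topo.relative_polarities


def test_antiparallel_fixture_six_syn_core_guanines(z_axis):
    from g4conform import classify_chi, glycosidic_chi

    ens, truth = build_mock_quadruplex(preset("antiparallel", sigma=0.0, n_models=1))
    topo = model_topology(ens.models[0], axis_hint=z_axis)
    core = [r for layer in topo.layers for r in layer]
    n_syn = sum(classify_chi(glycosidic_chi(r)) == "syn" for r in core)
    assert n_syn == 6
    assert topo.relative_polarities == ["heteropolar", "heteropolar"]


@pytest.mark.parametrize("name,subtype", [
    ("vloop_conventional", "conventional"),
    ("vloop_alternative", "alternative"),
])
def test_vloop_subtypes_match_construction(name, subtype, z_axis):
    ens, truth = build_mock_quadruplex(preset(name, sigma=0.0, n_models=1))
    topo = model_topology(ens.models[0], axis_hint=z_axis)
    assert len(topo.vloops) == 1
    v = topo.vloops[0]
    assert v.subtype == subtype
    assert v.layers_spanned == 3
    assert len(v.intervening) == 0
    assert v.inversion_site == ("after_loop" if subtype == "conventional" else "within_loop")


@pytest.mark.parametrize("name,polarities,expected_class", [
    ("vloop_conventional", [1, 1, 1], "V_S"),
    ("vloop_conventional", [1, 1, -1], "V_R"),
    ("vloop_alternative", [1, 1, 1], "V_S"),
    ("vloop_alternative", [-1, 1, 1], "V_R"),
])
def test_vr_vs_independent_of_subtype(name, polarities, expected_class, z_axis):
    """Subtype (inversion site) and V_R/V_S (polarity) vary independently."""
    ens, truth = build_mock_quadruplex(
        preset(name, polarities=polarities, sigma=0.0, n_models=1)
    )
    topo = model_topology(ens.models[0], axis_hint=z_axis)
    v = topo.vloops[0]
    assert v.polarity_class == expected_class
    assert v.subtype == truth["vloop"]["subtype"]


def test_sequence_reversal_flips_tracts_not_loop_types(z_axis):
    ens, _ = build_mock_quadruplex(preset("parallel", sigma=0.0, n_models=1))
    model = ens.models[0]
    n = len(model.residues)
    reversed_model = Model([
        Residue(r.chain_id, n + 1 - r.seq_index, r.name, r.atoms)
        for r in reversed(model.residues)
    ])
    fwd = model_topology(model, axis_hint=z_axis)
    rev = model_topology(reversed_model, axis_hint=z_axis)
    assert [lp.kind for lp in fwd.loops] == [lp.kind for lp in rev.loops]
    assert {t.orientation for t in fwd.tracts} == {"down"}
    assert {t.orientation for t in rev.tracts} == {"up"}


def test_recovery_on_v_fixtures_end_to_end(conventional_build, alternative_build, z_axis):
    from g4conform import ensemble_topology

    for build in (conventional_build, alternative_build):
        ens, truth = build
        et = ensemble_topology(ens, axis_hint=z_axis)
        assert detected_summary(et.consensus) == truth_summary(truth)
        assert et.agreement == 1.0
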