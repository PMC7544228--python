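"""H8 reconstruction and base-backbone contact calls."""
import numpy as np
import pytest

from g4conform import (
    build_mock_quadruplex, build_nucleotide, ensemble_topology, measure_contact,
    preset, reconstruct_h8, scan_vloop_contacts,
)
from g4conform.contacts import classify_call, h8_position
from g4conform.geometry import plane_normal
from g4conform.structure import Atom, Ensemble, Model, Residue


def test_reconstructed_h8_matches_file_hydrogen():
    nt = build_nucleotide("G", 240.0, 18.0, 38.0)
    rebuilt = reconstruct_h8(nt)
    assert np.linalg.norm(rebuilt - nt.pos("H8")) < 0.05


def test_reconstructed_h8_is_coplanar_with_ring():
    nt = build_nucleotide("G")
    ring = np.array([nt.pos(n) for n in ("N9", "C8", "N7", "C5", "C4")])
    n = plane_normal(ring)
    h8 = reconstruct_h8(nt)
    assert abs((h8 - ring.mean(axis=0)) @ n) < 1e-6


def test_missing_ring_atom_raises_named_error():
    nt = build_nucleotide("G")
    partial = Residue("A", 1, "DG", [a for a in nt.atoms if a.name != "N7"])
    with pytest.raises(KeyError, match="N7"):
        reconstruct_h8(partial)


def test_contact_at_exactly_2_70_angstrom():
    base = build_nucleotide("G", 240.0, 162.0, 38.0)
    h8, _ = h8_position(base)
    c8 = base.pos("C8")
    direction = (h8 - c8) / np.linalg.norm(h8 - c8)
    acc_pos = h8 + 2.70 * direction
    acceptor = Residue("A", 2, "DG", [Atom("O4'", "O", acc_pos)])
    geom = measure_contact((acceptor, "O4'"), base)
    assert geom.distance == pytest.approx(2.70, abs=1e-9)
    assert geom.call == "present"
    assert geom.angle == pytest.approx(180.0, abs=1e-6)


def test_call_partition_and_monotonicity():
    calls = [classify_call(d) for d in np.arange(0.05, 8.0, 0.01)]
    assert set(calls) == {"present", "ambiguous", "absent"}
    order = {"present": 0, "ambiguous": 1, "absent": 2}
    ranks = [order[c] for c in calls]
    assert ranks == sorted(ranks)  # presence never returns once lost
    assert classify_call(3.5) == "present"
    assert classify_call(3.75) == "ambiguous"
    assert classify_call(4.0) == "absent"


def test_file_vs_reconstructed_h8_distance_shift_small():
    nt = build_nucleotide("G", 240.0, 162.0, 38.0)
    stripped = Residue("A", 1, "DG", [a for a in nt.atoms if a.name != "H8"])
    probe = Residue("A", 2, "DG", [Atom("O4'", "O", nt.pos("H8") + np.array([3.0, 0, 0]))])
    d_file = measure_contact((probe, "O4'"), nt).distance
    d_rec = measure_contact((probe, "O4'"), stripped).distance
    assert measure_contact((probe, "O4'"), stripped).h8_source == "reconstructed"
    assert abs(d_file - d_rec) < 0.1


def test_conventional_vloop_o5_contact_full_occupancy(z_axis):
    ens, truth = build_mock_quadruplex(
        preset("vloop_conventional", sigma=0.0, n_models=5)
    )
    topo = ensemble_topology(ens, axis_hint=z_axis)
    df = scan_vloop_contacts(topo, ens)
    o5 = df[(df["acceptor_atom"] == "O5'") & (df["base_role"] == "next_g")]
    assert len(o5) == 5
    assert o5["distance"].mean() == pytest.approx(2.9, abs=0.05)
    assert (o5["occupancy"] == 1.0).all()


def test_occupancy_counts_present_models(z_axis):
    """Contact present in exactly half the models -> occupancy 0.5."""
    ens, truth = build_mock_quadruplex(
        preset("vloop_conventional", sigma=0.0, n_models=10)
    )
    a3_key = tuple(truth["vloop"]["anchor3"])
    for model in ens.models[:5]:
        res = model.residue(*a3_key)
        res.atom("O5'").position = res.pos("O5'") + np.array([0.0, 0.0, 30.0])
    topo = ensemble_topology(ens, axis_hint=z_axis)
    df = scan_vloop_contacts(topo, ens)
    o5 = df[(df["acceptor_atom"] == "O5'") & (df["base_role"] == "next_g")]
    # independent counting oracle
    assert int(o5["call"].eq("present").sum()) == 5
    assert o5["occupancy"].iloc[0] == pytest.approx(0.5)


def test_alternative_vloop_lacks_o5_contact(z_axis):
    ens, _ = build_mock_quadruplex(preset("vloop_alternative", sigma=0.0, n_models=3))
    topo = ensemble_topology(ens, axis_hint=z_axis)
    df = scan_vloop_contacts(topo, ens)
    o5 = df[(df["acceptor_atom"] == "O5'") & (df["base_role"] == "next_g")]
    assert (o5["distance"] > 4.0).all()
    assert (o5["call"] == "absent").all()
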