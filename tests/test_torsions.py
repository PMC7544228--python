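"""Glycosidic/pucker torsion math and domain classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4conform import (
    build_nucleotide, build_ring, classify_chi, classify_pucker,
    glycosidic_chi, pseudorotation, PuckerError,
)
from g4conform.geometry import random_rigid_transform, wrap180
from g4conform.structure import Atom, Residue
from g4conform.torsions import sugar_torsions, ensemble_torsion_table
from g4conform.synthetic import _nu_targets


def ring_residue(P, tau_m):
    ring = build_ring(P, tau_m)
    return Residue("A", 1, "DG", [Atom(n, n[0], p) for n, p in ring.items()])


def test_cosine_relation_is_fixed_point():
    nu = 38.0 * np.cos(np.radians(144.0 * (np.arange(5) - 2)))
    P, tau = pseudorotation(nu)
    assert P == pytest.approx(0.0, abs=1e-9)
    assert tau == pytest.approx(38.0, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(P=st.floats(0, 359.999), tau=st.floats(15, 65))
def test_pseudorotation_inverts_cosine_generation(P, tau):
    nu = _nu_targets(P, tau)
    Pr, tr = pseudorotation(nu)
    assert abs(wrap180(Pr - P)) < 1e-6
    assert tr == pytest.approx(tau, abs=1e-6)


def test_nu2_equals_amplitude_times_cos_phase():
    res = ring_residue(205.0, 33.0)
    nu = sugar_torsions(res)
    P, tau = pseudorotation(nu)
    assert nu[2] == pytest.approx(tau * np.cos(np.radians(P)), abs=1e-9)


def test_ring_coordinates_roundtrip():
    res = ring_residue(162.0, 35.0)
    P, tau = pseudorotation(sugar_torsions(res))
    assert P == pytest.approx(162.0, abs=1.0)
    assert tau == pytest.approx(35.0, abs=1.0)


def test_planar_ring_raises_undefined_pucker():
    res = ring_residue(0.0, 0.0)
    with pytest.raises(PuckerError):
        pseudorotation(sugar_torsions(res))


@pytest.mark.parametrize("chi,domain", [
    (320.0, "low_syn"), (300.0, "low_syn"), (60.0, "syn"), (0.0, "syn"),
    (240.0, "anti"), (180.0, "anti"), (150.0, "intermediate"), (120.0, "intermediate"),
])
def test_chi_domain_examples(chi, domain):
    assert classify_chi(chi) == domain


@pytest.mark.parametrize("P,domain,label", [
    (18.0, "north", "C3'-endo"), (162.0, "south", "C2'-endo"),
    (54.0, "north", "C4'-exo"), (90.0, "south", "O4'-endo"),
    (270.0, "north", "O4'-exo"), (89.9, "north", "O4'-endo"),
])
def test_pucker_domain_examples(P, domain, label):
    d, l = classify_pucker(P)
    assert (d, l) == (domain, label)


def test_domains_partition_without_gaps_or_overlaps():
    grid = np.arange(0.0, 360.0, 0.1)
    chi_labels = {c: classify_chi(c) for c in grid}
    assert set(chi_labels.values()) == {"syn", "intermediate", "anti", "low_syn"}
    # each grid point has exactly one label (total function) and boundaries
    # fall exactly where documented
    for boundary, before, after in [(120.0, "syn", "intermediate"),
                                    (180.0, "intermediate", "anti"),
                                    (300.0, "anti", "low_syn")]:
        assert classify_chi(boundary - 0.05) == before
        assert classify_chi(boundary) == after
    assert classify_chi(359.95) == "low_syn" and classify_chi(0.0) == "syn"

    for P in grid:
        domain, label = classify_pucker(P)
        assert domain in ("north", "south")
        assert label
    assert classify_pucker(89.95)[0] == "north" and classify_pucker(90.0)[0] == "south"
    assert classify_pucker(270.0)[0] == "north" and classify_pucker(269.95)[0] == "south"


def test_glycosidic_chi_matches_build_target_and_rigid_invariance():
    rng = np.random.default_rng(9)
    for chi in (60.0, 240.0):
        nt = build_nucleotide("G", chi, 18.0, 38.0)
        assert glycosidic_chi(nt) == pytest.approx(chi, abs=0.5)
        R, t = random_rigid_transform(rng)
        moved = Residue("A", 1, "DG",
                        [Atom(a.name, a.element, R @ a.position + t) for a in nt.atoms])
        assert glycosidic_chi(moved) == pytest.approx(glycosidic_chi(nt), abs=1e-6)
        P0, t0 = pseudorotation(sugar_torsions(nt))
        P1, t1 = pseudorotation(sugar_torsions(moved))
        assert P1 == pytest.approx(P0, abs=1e-6)
        assert t1 == pytest.approx(t0, abs=1e-6)


def test_ensemble_table_uses_circular_means(conventional_build):
    ens, _ = conventional_build
    table = ensemble_torsion_table(ens, entry="mock")
    summary = table[table["model"] == 0]
    assert not summary.empty
    # circular mean stays in the residue's own chi domain despite noise
    per_model = table[table["model"] > 0]
    for (_, seq), grp in per_model.groupby(["chain", "seq_index"]):
        srow = summary[summary["seq_index"] == seq].iloc[0]
        assert srow["chi_domain"] in set(grp["chi_domain"])
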