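"""Superposition and pairwise-RMSD statistics."""
import numpy as np
import pytest

from g4conform import (
    DegenerateSelectionError, build_mock_quadruplex, ensemble_topology,
    core_guanine_heavy, heavy_atoms, pairwise_rmsd, preset, superpose,
)
from g4conform.geometry import random_rigid_transform
from g4conform.structure import Atom, Ensemble, Model, Residue


def quaternion_superpose_rmsd(ref, mov):
    """Horn's closed-form quaternion method (independent oracle)."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    S = mov_c.T @ ref_c
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(ref_c ** 2) + np.sum(mov_c ** 2) - 2.0 * lam) / ref.shape[0]
    return np.sqrt(max(msd, 0.0))


def test_identical_sets_rmsd_zero():
    pts = np.random.default_rng(0).normal(size=(30, 3))
    R, t, rmsd = superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_rigid_motion_is_fully_removed():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(50, 3))
    from g4conform.geometry import rotation_about_axis
    R0 = rotation_about_axis(rng.normal(size=3), 37.0)
    moved = pts @ R0.T + np.array([5.0, -3.0, 2.0])
    _, _, rmsd = superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_noisy_fit_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    ref = rng.normal(size=(500, 3)) * 10.0
    R0, t0 = random_rigid_transform(rng)
    mov = (ref + rng.normal(0.0, 0.2, ref.shape)) @ R0.T + t0
    _, _, rmsd = superpose(ref, mov)
    assert rmsd == pytest.approx(quaternion_superpose_rmsd(ref, mov), abs=1e-9)


def test_degenerate_selections_raise():
    with pytest.raises(DegenerateSelectionError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateSelectionError):
        superpose(line, line)


def _ensemble_from_coords(models_coords):
    models = []
    for mi, coords in enumerate(models_coords, start=1):
        residues = [
            Residue("A", 1, "DG",
                    [Atom(f"C{i+1}'", "C", c) for i, c in enumerate(coords)])
        ]
        models.append(Model(residues, number=mi))
    return Ensemble(models, entry_id="SYN")


def test_two_model_rigid_pair_mean_zero():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 3)) * 4.0
    R, t = random_rigid_transform(rng)
    ens = _ensemble_from_coords([pts, pts @ R.T + t])
    mean, matrix = pairwise_rmsd(ens, heavy_atoms())
    assert mean == pytest.approx(0.0, abs=1e-9)
    assert matrix.shape == (2, 2)


def test_three_model_matrix_matches_constructed_deviations():
    """Displacement fields orthogonal to the rigid modes leave the optimal
    superposition at identity, so the RMSD equals the analytic value."""
    rng = np.random.default_rng(4)
    base = rng.normal(size=(40, 3)) * 6.0
    base -= base.mean(axis=0)

    def orthogonal_displacement(scale):
        d = rng.normal(size=base.shape)
        d -= d.mean(axis=0)                       # no net translation
        # remove net infinitesimal rotation: sum_i r_i x d_i = 0
        L = np.sum(np.cross(base, d), axis=0)
        # subtract the rigid-rotation field w x r that reproduces L
        I = np.einsum("ni,nj->ij", base, base)
        Imat = np.trace(I) * np.eye(3) - I
        w = np.linalg.solve(Imat, L)
        d -= np.cross(w, base)
        d -= d.mean(axis=0)
        return scale * d / np.sqrt(np.mean(np.sum(d ** 2, axis=1)))

    d1 = orthogonal_displacement(1e-3)
    d2 = orthogonal_displacement(2e-3)
    ens = _ensemble_from_coords([base, base + d1, base + d2])
    mean, matrix = pairwise_rmsd(ens, heavy_atoms())
    assert matrix[0, 1] == pytest.approx(np.sqrt(np.mean(np.sum(d1 ** 2, axis=1))), rel=1e-4)
    assert matrix[0, 2] == pytest.approx(np.sqrt(np.mean(np.sum(d2 ** 2, axis=1))), rel=1e-4)
    assert matrix[1, 2] == pytest.approx(
        np.sqrt(np.mean(np.sum((d2 - d1) ** 2, axis=1))), rel=1e-4)


def test_matrix_symmetry_order_invariance_and_pretransform(z_axis):
    ens, _ = build_mock_quadruplex(preset("parallel", sigma=0.2, n_models=4))
    topo = ensemble_topology(ens, axis_hint=z_axis)
    sel = core_guanine_heavy(topo.consensus._core_keys)
    mean, matrix = pairwise_rmsd(ens, sel)
    assert np.allclose(matrix, matrix.T)
    assert np.allclose(np.diag(matrix), 0.0)
    assert mean > 0

    rng = np.random.default_rng(5)
    R, t = random_rigid_transform(rng)
    moved_models = []
    for i, m in enumerate(ens.models):
        if i == 2:
            residues = [
                Residue(r.chain_id, r.seq_index, r.name,
                        [Atom(a.name, a.element, R @ a.position + t) for a in r.atoms],
                        auth_seq=r.auth_seq)
                for r in m.residues
            ]
            moved_models.append(Model(residues, number=m.number))
        else:
            moved_models.append(m)
    mean2, matrix2 = pairwise_rmsd(Ensemble(moved_models), sel)
    assert np.allclose(matrix, matrix2, atol=1e-9)

    order = [2, 0, 3, 1]
    mean3, _ = pairwise_rmsd(
        Ensemble([ens.models[i] for i in order]), sel
    )
    assert mean3 == pytest.approx(mean, abs=1e-12)
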