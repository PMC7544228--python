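"""Superposition and coordinate-precision statistics for NMR-style ensembles."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .structure import Atom, Ensemble, Model, Residue

__all__ = [
    "DegenerateSelectionError",
    "SelectionSpec",
    "heavy_atoms",
    "core_guanine_heavy",
    "superpose",
    "pairwise_rmsd",
]


class DegenerateSelectionError(ValueError):
    """Selection resolves to too few or rank-deficient coordinates."""


@dataclass
class SelectionSpec:
    """Predicate over (residue, atom) pairs; must match the same atoms in every model."""
    predicate: Callable[[Residue, Atom], bool]
    name: str = "selection"

    def coordinates(self, model: Model) -> np.ndarray:
        coords = [
            atom.position
            for res in model.residues
            for atom in res.atoms
            if self.predicate(res, atom)
        ]
        return np.array(coords) if coords else np.empty((0, 3))


def heavy_atoms() -> SelectionSpec:
    return SelectionSpec(lambda r, a: not a.element.upper().startswith("H"), "heavy")


def core_guanine_heavy(core_keys) -> SelectionSpec:
    """Heavy atoms of the quartet-core guanines (keys from topology detection)."""
    keys = frozenset(core_keys)
    return SelectionSpec(
        lambda r, a: r.key in keys and not a.element.upper().startswith("H"),
        "core-guanine-heavy",
    )


def superpose(ref_coords, mov_coords) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``mov @ rotation.T + translation`` best fits ref.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("superpose needs two equal-shape (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateSelectionError(f"superposition needs >= 3 atoms, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    H = mov_c.T @ ref_c
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-10:
        raise DegenerateSelectionError("rank-deficient selection (collinear atoms)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mov.mean(axis=0)
    fitted = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def pairwise_rmsd(
    ensemble: Ensemble,
    selection: SelectionSpec,
    fit_selection: Optional[SelectionSpec] = None,
) -> Tuple[float, np.ndarray]:
    """Mean pairwise RMSD over all unordered model pairs, plus the matrix.

    Each pair is superposed on ``fit_selection`` (defaults to the measured
    selection, i.e. fit-on = measure-on) before the RMSD is evaluated on
    ``selection``.
    """
    if len(ensemble) < 2:
        raise ValueError("pairwise RMSD needs at least two models")
    fit_sel = fit_selection or selection
    meas = [selection.coordinates(m) for m in ensemble]
    fit = [fit_sel.coordinates(m) for m in ensemble]
    if meas[0].shape[0] == 0:
        raise DegenerateSelectionError(f"selection {selection.name!r} matches no atoms")
    counts = {c.shape[0] for c in meas} | {c.shape[0] for c in fit}
    if len({c.shape[0] for c in meas}) != 1 or len({c.shape[0] for c in fit}) != 1:
        raise DegenerateSelectionError("selection resolves to differing atom counts across models")

    n = len(ensemble)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, t, _ = superpose(fit[i], fit[j])
            fitted = meas[j] @ R.T + t
            rmsd = float(np.sqrt(np.mean(np.sum((fitted - meas[i]) ** 2, axis=1))))
            matrix[i, j] = matrix[j, i] = rmsd
    mean = float(matrix[np.triu_indices(n, k=1)].mean())
    return mean, matrix
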