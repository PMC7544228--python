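"""Synthetic coordinate fixtures with prescribed conformational parameters.

Every analysis stage in this package can be exercised without downloading
deposited structures: this module builds furanose rings at a chosen
pseudorotation phase/amplitude, nucleotides at a chosen glycosidic
torsion and sugar chemistry (deoxy/ribo/locked/2'F), planar Hoogsteen
G-quartets of either polarity, and small stacked mock quadruplexes whose
topology (tract orientations, loop plan, V-loop subtype, tetrad
polarities) is prescribed and returned as ground truth.

The mock backbone is idealized, not energy-minimized: only the geometric
predicates the analysis relies on are guaranteed (Hoogsteen distances,
stacking rise, consecutive-residue P-O3' linkage, axis-projected step
directions).  Base and quartet geometry come from a planar guanine
template and a quartet pose solved once from standard bond lengths and
hydrogen-bond constraints and frozen below.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .geometry import rotation_about_axis, signed_dihedral, wrap180, wrap360
from .structure import (
    Atom, Ensemble, Model, Residue, write_pdb,
    DEOXYRIBOSE, RIBOSE, LOCKED, F_RIBO, F_ARABINO,
)

__all__ = [
    "RingBuildError",
    "MockSpecError",
    "Segment",
    "MockTopologySpec",
    "build_ring",
    "build_nucleotide",
    "build_quartet",
    "build_mock_quadruplex",
    "preset",
    "PRESETS",
    "random_mock_spec",
    "write_fixture",
]


class RingBuildError(RuntimeError):
    """Ring closure failed to reach the requested pucker."""


class MockSpecError(ValueError):
    """The mock topology plan is geometrically inconsistent."""


# ---------------------------------------------------------------------------
# frozen templates (planar guanine from standard bond lengths/angles, and the
# quartet pose satisfying N1...O6 / N2...N7 = 2.9 A with near-linear N-H...X)
# ---------------------------------------------------------------------------

GUANINE_TEMPLATE: Dict[str, Tuple[float, float]] = {
    "N9": (+0.0000, -0.0000), "C8": (-0.3883, +1.3163), "N7": (+0.6180, +2.1481),
    "C5": (+1.7414, +1.3295), "C4": (+1.3743, +0.0000), "C6": (+3.1237, +1.6587),
    "O6": (+3.6504, +2.7780), "N1": (+3.9203, +0.5184), "C2": (+3.4521, -0.7727),
    "N2": (+4.3814, -1.7395), "N3": (+2.1664, -1.0931), "H8": (-1.4212, +1.6320),
    "H1": (+4.9216, +0.6503), "H21": (+5.3620, -1.4974), "H22": (+4.1008, -2.7097),
}
QUARTET_POSE = (-3.868453, -5.535599, 0.380386)  # (tx, ty, theta) of the template

GUANINE_HEAVY = ("N9", "C8", "N7", "C5", "C4", "C6", "O6", "N1", "C2", "N2", "N3")
GUANINE_H = ("H8", "H1", "H21", "H22")

# minimal planar thymine for loop residues (regular hexagon, exocyclics)
_hex = {
    name: (1.38 * np.cos(np.radians(90 + 60 * i)), 1.38 * np.sin(np.radians(90 + 60 * i)))
    for i, name in enumerate(("N1", "C2", "N3", "C4", "C5", "C6"))
}
THYMINE_TEMPLATE: Dict[str, Tuple[float, float]] = {
    **_hex,
    "O2": tuple(np.array(_hex["C2"]) * (1 + 1.22 / 1.38)),
    "O4": tuple(np.array(_hex["C4"]) * (1 + 1.22 / 1.38)),
    "C7": tuple(np.array(_hex["C5"]) * (1 + 1.50 / 1.38)),
}

RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
_RING_BONDS = (1.41, 1.52, 1.52, 1.52, 1.41)  # O4'-C1', C1'-C2', ..., C4'-O4'
_NU_IDX = ((4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1))


def _nu_targets(P: float, tau_m: float) -> np.ndarray:
    j = np.arange(5)
    return tau_m * np.cos(np.radians(P + 144.0 * (j - 2)))


@lru_cache(maxsize=512)
def _solve_ring(P: float, tau_m: float) -> tuple:
    targets = _nu_targets(P, tau_m)

    def unpack(x):
        pts = np.zeros((5, 3))
        pts[1] = (x[0], 0.0, 0.0)
        pts[2] = (x[1], x[2], 0.0)
        pts[3] = x[3:6]
        pts[4] = x[6:9]
        return pts

    def residuals(x):
        pts = unpack(x)
        res = []
        for i in range(5):
            d = np.linalg.norm(pts[(i + 1) % 5] - pts[i])
            res.append(20.0 * (d - _RING_BONDS[i]))
        for t, idx in zip(targets, _NU_IDX):
            try:
                tor = signed_dihedral(*(pts[k] for k in idx))
            except Exception:
                tor = 0.0
            res.append(1.0 * wrap180(tor - t))
        return res

    radius = 1.48 / (2.0 * np.sin(np.pi / 5.0))
    amp = 0.40 * max(tau_m, 1.0) / 38.0
    best = None
    # a converged solution has cost of order 1 (the cosine targets are not
    # exactly ring-closable); bad local minima sit orders of magnitude higher
    starts = [(0, 1.0), (0, -1.0)] + [
        (d, s) for d in (72, 144, 216, 288) for s in (1.0, -1.0)
    ]
    for delta, sgn in starts:
        ang = np.radians(90.0 + 72.0 * np.arange(5))
        z = sgn * amp * np.cos(np.radians(P + 144.0 * np.arange(5) + delta))
        guess_pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])
        guess_pts -= guess_pts[0]
        x0 = np.concatenate([
            [guess_pts[1][0]], guess_pts[2][:2], guess_pts[3], guess_pts[4]
        ])
        sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 2.0:
            break
    pts = unpack(best.x)
    achieved = np.array([signed_dihedral(*(pts[k] for k in idx)) for idx in _NU_IDX])
    if tau_m >= 1.0 and np.max(np.abs(wrap180(achieved - targets))) > 1.0:
        raise RingBuildError(
            f"ring closure did not converge for P={P:.1f}, tau_m={tau_m:.1f} "
            f"(torsion error {np.max(np.abs(wrap180(achieved - targets))):.2f} deg)"
        )
    return tuple(map(tuple, pts))


def build_ring(P: float, tau_m: float) -> Dict[str, np.ndarray]:
    """Five furanose ring atoms realizing pucker (P, tau_m) within 1 degree.

    Standard bond lengths (C-C 1.52 A, C-O 1.41 A); the ring is solved by
    numerical closure against the cosine torsion targets.  ``tau_m = 0``
    yields a planar ring (useful to exercise the undefined-pucker path).
    """
    if not (0.0 <= tau_m <= 65.0):
        raise ValueError("tau_m must lie in [0, 65] degrees")
    pts = np.array(_solve_ring(round(float(wrap360(P)), 4), round(float(tau_m), 4)))
    return {name: pts[i].copy() for i, name in enumerate(RING_ATOMS)}


# ---------------------------------------------------------------------------
# internal-coordinate helpers
# ---------------------------------------------------------------------------

def _place_nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given predecessors a-b-c (standard internal-coordinate step)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_on_face(center, nb1, nb2, bond, ang1, ang2, normal, side: float) -> np.ndarray:
    """Atom bonded to ``center`` with two angle constraints, on a chosen face."""
    e1 = nb1 - center
    e1 /= np.linalg.norm(e1)
    e2 = nb2 - center
    e2 /= np.linalg.norm(e2)
    g = e1 @ e2
    c1, c2 = np.cos(np.radians(ang1)), np.cos(np.radians(ang2))
    det = 1.0 - g * g
    alpha = (c1 - g * c2) / det
    beta = (c2 - g * c1) / det
    u_par = alpha * e1 + beta * e2
    perp2 = 1.0 - u_par @ u_par
    perp = np.sqrt(max(perp2, 0.0))
    n = np.cross(e1, e2)
    n /= np.linalg.norm(n)
    if n @ normal < 0:
        n = -n
    return center + bond * (u_par + side * perp * n)


def _ring_normal(ring: Dict[str, np.ndarray]) -> np.ndarray:
    pts = np.array([ring[a] for a in RING_ATOMS])
    ctr = pts.mean(axis=0)
    n = np.zeros(3)
    for i in range(5):
        n += np.cross(pts[i] - ctr, pts[(i + 1) % 5] - ctr)
    return n / np.linalg.norm(n)


# The ring-atom order O4'->C1'->C2'->C3'->C4' induces a normal; the beta face
# (C5' and base side of a D-sugar) is the -normal side: at P = 162 (C2'-endo)
# the C2' atom is then displaced toward the base, as the name requires.
_BETA_SIDE = -1.0


def _embed_template(template: Dict[str, Tuple[float, float]], origin, x_axis, y_axis):
    return {
        name: origin + uv[0] * x_axis + uv[1] * y_axis
        for name, uv in template.items()
    }


def build_nucleotide(
    base: str = "G",
    chi: float = 240.0,
    P: float = 162.0,
    tau_m: float = 38.0,
    chemistry: str = DEOXYRIBOSE,
    include_hydrogens: bool = True,
    chain_id: str = "A",
    seq_index: int = 1,
    name: Optional[str] = None,
) -> Residue:
    """One free-standing nucleotide with prescribed chi, pucker and chemistry.

    ``base`` is G (full guanine, Hoogsteen-competent) or T (minimal
    pyrimidine used for loop residues).  The sugar ring comes from
    :func:`build_ring`; C5'/O5'/P and O3' are attached at idealized
    geometry, and the chemistry decorations (O2', F2' on the ribo or
    arabino face, the O2'-C-C4' bridge of a locked sugar) are placed so
    the geometric classification rules recover them.
    """
    ring = build_ring(P, tau_m)
    normal = _ring_normal(ring) * _BETA_SIDE
    coords: Dict[str, np.ndarray] = dict(ring)

    c1, c2, c3, c4, o4 = (ring[a] for a in ("C1'", "C2'", "C3'", "C4'", "O4'"))
    coords["C5'"] = _place_on_face(c4, c3, o4, 1.51, 115.0, 109.0, normal, +1.0)
    coords["O3'"] = _place_on_face(c3, c2, c4, 1.42, 110.0, 110.0, normal, -1.0)
    coords["O5'"] = _place_nerf(c3, c4, coords["C5'"], 1.44, 110.0, 180.0)
    coords["P"] = _place_nerf(c4, coords["C5'"], coords["O5'"], 1.60, 120.0, 180.0)

    if chemistry in (RIBOSE, LOCKED):
        coords["O2'"] = _place_on_face(c2, c1, c3, 1.41, 110.0, 112.0, normal, -1.0)
    elif chemistry == F_RIBO:
        coords["F2'"] = _place_on_face(c2, c1, c3, 1.39, 110.0, 112.0, normal, -1.0)
    elif chemistry == F_ARABINO:
        coords["F2'"] = _place_on_face(c2, c1, c3, 1.39, 110.0, 112.0, normal, +1.0)
    elif chemistry != DEOXYRIBOSE:
        raise ValueError(f"unknown chemistry {chemistry!r}")

    if chemistry == LOCKED:
        # methylene bridging O2' and C4': intersection of the two bond spheres
        o2 = coords["O2'"]
        d = np.linalg.norm(c4 - o2)
        if d > 1.42 + 1.55:
            raise RingBuildError("locked bridge infeasible at this pucker")
        u = (c4 - o2) / d
        x = (1.42 ** 2 - 1.55 ** 2 + d * d) / (2 * d)
        h = np.sqrt(max(1.42 ** 2 - x * x, 0.0))
        perp = np.cross(u, normal)
        perp /= np.linalg.norm(perp)
        coords["C6'"] = o2 + x * u - h * perp

    # glycosidic nitrogen direction, on the base (beta) face
    n_glyc = "N9" if base == "G" else "N1"
    n_pos = _place_on_face(c1, o4, c2, 1.47, 108.0, 113.0, normal, +1.0)

    template = GUANINE_TEMPLATE if base == "G" else THYMINE_TEMPLATE
    t2 = {k: np.asarray(v) for k, v in template.items()}
    t_origin = t2[n_glyc]
    if base == "G":
        bis = (t2["C4"] - t_origin) / np.linalg.norm(t2["C4"] - t_origin) \
            + (t2["C8"] - t_origin) / np.linalg.norm(t2["C8"] - t_origin)
    else:
        bis = (t2["C2"] - t_origin) / np.linalg.norm(t2["C2"] - t_origin) \
            + (t2["C6"] - t_origin) / np.linalg.norm(t2["C6"] - t_origin)
    out_dir = -bis / np.linalg.norm(bis)  # template direction toward C1'

    d_glyc = (c1 - n_pos) / np.linalg.norm(c1 - n_pos)
    # 2D rotation aligning out_dir with +x, then embed with X = d_glyc
    cs, sn = out_dir
    rot2 = np.array([[cs, sn], [-sn, cs]])
    ref = normal - (normal @ d_glyc) * d_glyc
    ref /= np.linalg.norm(ref)
    base_coords = {}
    for atom_name, uv in t2.items():
        uvr = rot2 @ (uv - t_origin)
        base_coords[atom_name] = n_pos + uvr[0] * d_glyc + uvr[1] * ref
    # rotate about the glycosidic bond to the target chi
    probe = "C4" if base == "G" else "C2"
    current = wrap360(signed_dihedral(o4, c1, n_pos, base_coords[probe]))
    # the IUPAC torsion grows with right-handed rotation about C1'->N9,
    # which is -d_glyc
    R = rotation_about_axis(d_glyc, -(chi - current))
    for atom_name, pos in base_coords.items():
        base_coords[atom_name] = n_pos + R @ (pos - n_pos)
    base_coords[n_glyc] = n_pos
    coords.update(base_coords)

    if not include_hydrogens:
        for h in list(coords):
            if h.startswith("H"):
                del coords[h]

    if name is None:
        name = {
            DEOXYRIBOSE: "DG", RIBOSE: "G", LOCKED: "LCG",
            F_RIBO: "GF2", F_ARABINO: "GFA",
        }.get(chemistry, "DG") if base == "G" else "DT"

    atoms = [Atom(a, _element_of(a), p) for a, p in coords.items()]
    return Residue(chain_id, seq_index, name, atoms, auth_seq=seq_index)


def _element_of(atom_name: str) -> str:
    if atom_name == "P":
        return "P"
    return atom_name[0]


# ---------------------------------------------------------------------------
# quartets and stacked scaffolds
# ---------------------------------------------------------------------------

def _pose_template_2d() -> Dict[str, np.ndarray]:
    tx, ty, th = QUARTET_POSE
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s], [s, c]])
    return {
        a: R @ np.asarray(uv) + np.array([tx, ty])
        for a, uv in GUANINE_TEMPLATE.items()
    }


def _scaffold_base(layer: int, col: int, polarity: int, rise: float, twist: float):
    """3D coordinates of the guanine base occupying one (layer, column) slot."""
    t2 = _pose_template_2d()
    if polarity < 0:
        az = np.arctan2(t2["N9"][1], t2["N9"][0])
        c2, s2 = np.cos(2 * az), np.sin(2 * az)
        fix = np.array([[c2, s2], [s2, -c2]])  # reflect across the N9 azimuth
        t2 = {a: fix @ p for a, p in t2.items()}
    ang = np.radians(90.0 * col + twist * layer)
    c, s = np.cos(ang), np.sin(ang)
    R = np.array([[c, -s], [s, c]])
    z = -rise * layer
    return {a: np.array([*(R @ p), z]) for a, p in t2.items()}


def build_quartet(
    polarity_sign: int = 1,
    include_hydrogens: bool = True,
    chain_id: str = "A",
    start_seq: int = 1,
    layer: int = 0,
    rise: float = 3.5,
    twist: float = 0.0,
) -> List[Residue]:
    """Four planar Hoogsteen-bonded guanine bases forming one G-quartet.

    Donor->acceptor hydrogen-bond cycle direction is set by
    ``polarity_sign`` (+1: counterclockwise seen from +z).  Heavy-atom
    N1...O6 and N2...N7 distances are 2.9 +- 0.1 A by construction.
    """
    residues = []
    for k in range(4):
        coords = _scaffold_base(layer, k, polarity_sign, rise, twist)
        names = GUANINE_HEAVY + (GUANINE_H if include_hydrogens else ())
        atoms = [Atom(a, _element_of(a), coords[a]) for a in names]
        residues.append(Residue(chain_id, start_seq + k, "DG", atoms, auth_seq=start_seq + k))
    return residues


# ---------------------------------------------------------------------------
# mock quadruplex assembly
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A run of core guanines occupying one column, walked layer_from -> layer_to."""
    column: int
    layer_from: int
    layer_to: int

    @property
    def layers(self) -> List[int]:
        step = 1 if self.layer_to >= self.layer_from else -1
        return list(range(self.layer_from, self.layer_to + step, step))


@dataclass
class MockTopologySpec:
    name: str
    n_layers: int
    segments: List[Segment]
    loop_nts: List[int]                  # intervening residues between segments
    loop_kinds: List[str]                # ground-truth labels per connection
    polarities: List[int]
    chi: List[float]                     # per core guanine, segment order
    P: List[float]
    tau_m: List[float]
    chemistry: List[str]
    rise: float = 3.5
    twist: float = 18.0
    sigma: float = 0.1                   # Gaussian coordinate noise, A
    n_models: int = 10
    seed: int = 0
    include_hydrogens: bool = True
    o5_contact_distance: Optional[float] = None  # place anchor3 O5' at this
    vloop_subtype: Optional[str] = None  # conventional | alternative | None
    vloop_connection: Optional[int] = None  # index into loop_kinds of the V

    def validate(self) -> None:
        slots = [(l, s.column) for s in self.segments for l in s.layers]
        expected = {(l, c) for l in range(self.n_layers) for c in range(4)}
        if len(slots) != len(set(slots)) or set(slots) != expected:
            raise MockSpecError(
                f"segments must cover each of the {4 * self.n_layers} "
                "(layer, column) slots exactly once"
            )
        n_core = len(slots)
        for nm, vals in (("chi", self.chi), ("P", self.P),
                         ("tau_m", self.tau_m), ("chemistry", self.chemistry)):
            if len(vals) != n_core:
                raise MockSpecError(f"{nm} plan needs {n_core} entries, got {len(vals)}")
        if len(self.loop_nts) != len(self.segments) - 1:
            raise MockSpecError("need one loop entry per segment junction")
        if len(self.polarities) != self.n_layers:
            raise MockSpecError("need one polarity per layer")


def build_mock_quadruplex(spec: MockTopologySpec) -> Tuple[Ensemble, dict]:
    """Assemble the mock ensemble and its ground-truth labels.

    Residues are numbered 1..N along the strand (chain A).  Core guanines
    are placed on the quartet scaffold (their bases superposed onto the
    solved quartet pose at the spec's rise/twist/polarities), carrying
    individually prescribed chi, pucker and chemistry; loop residues are
    idealized thymines swung radially outward; the backbone is linked by
    placing each P 1.6 A from the preceding O3'.  Each of ``n_models``
    models receives iid Gaussian coordinate noise ``sigma`` from ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    core_params = list(zip(spec.chi, spec.P, spec.tau_m, spec.chemistry))
    residues: List[Residue] = []
    core_info: List[dict] = []           # layer, column, seq
    seq = 0
    param_i = 0
    anchor_pairs: List[Tuple[int, int]] = []   # (a5 index, a3 index) per connection

    for si, seg in enumerate(spec.segments):
        for layer in seg.layers:
            seq += 1
            chi, P, tau, chem = core_params[param_i]
            param_i += 1
            nt = build_nucleotide(
                "G", chi, P, tau, chem, spec.include_hydrogens, "A", seq
            )
            target = _scaffold_base(
                layer, seg.column, spec.polarities[layer], spec.rise, spec.twist
            )
            _superpose_base(nt, target)
            residues.append(nt)
            core_info.append({"seq": seq, "layer": layer, "column": seg.column})
        if si < len(spec.segments) - 1:
            n_loop = spec.loop_nts[si]
            a5_seq = seq
            nxt = spec.segments[si + 1]
            for li in range(n_loop):
                seq += 1
                residues.append(_loop_residue(
                    seq, li, n_loop, seg, nxt, spec, core_info
                ))
            anchor_pairs.append((a5_seq, seq + 1))

    _link_backbone(residues)

    if spec.o5_contact_distance is not None and spec.vloop_connection is not None:
        a5_seq, a3_seq = anchor_pairs[spec.vloop_connection]
        _place_o5_contact(residues, a3_seq, spec.o5_contact_distance, core_info)

    base_model = Model(residues, number=1)
    models = []
    for m in range(spec.n_models):
        noise_model = Model(
            [
                Residue(
                    r.chain_id, r.seq_index, r.name,
                    [
                        Atom(a.name, a.element, a.position + rng.normal(0.0, spec.sigma, 3))
                        for a in r.atoms
                    ],
                    auth_seq=r.auth_seq,
                )
                for r in base_model.residues
            ],
            number=m + 1,
        )
        models.append(noise_model)
    ensemble = Ensemble(models, format="mock", entry_id=spec.name)

    truth = _ground_truth(spec, core_info, anchor_pairs, residues)
    return ensemble, truth


def _superpose_base(nt: Residue, target: Dict[str, np.ndarray]) -> None:
    from .ensemble import superpose

    names = [n for n in GUANINE_HEAVY if nt.has(n)]
    ref = np.array([target[n] for n in names])
    mov = np.array([nt.pos(n) for n in names])
    R, t, _ = superpose(ref, mov)
    for atom in nt.atoms:
        atom.position = R @ atom.position + t


def _loop_residue(seq, li, n_loop, seg_from, seg_to, spec, core_info) -> Residue:
    """Loop thymine on an outward arc between the flanking core positions."""
    za = -spec.rise * seg_from.layer_to
    zb = -spec.rise * seg_to.layer_from
    aza = np.radians(90.0 * seg_from.column + spec.twist * seg_from.layer_to)
    azb = np.radians(90.0 * seg_to.column + spec.twist * seg_to.layer_from)
    f = (li + 1) / (n_loop + 1)
    z = za + f * (zb - za)
    az = aza + f * (wrap_angle(azb - aza))
    radius = 11.0
    pos = np.array([radius * np.cos(az), radius * np.sin(az), z])

    nt = build_nucleotide("T", 240.0, 162.0, 38.0, DEOXYRIBOSE,
                          spec.include_hydrogens, "A", seq)
    out = np.array([np.cos(az), np.sin(az), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    side = np.cross(up, out)
    n1 = nt.pos("N1")
    c1 = nt.pos("C1'")
    d = (n1 - c1) / np.linalg.norm(n1 - c1)
    ref = np.array([1.0, 0.0, 0.0])
    axis = np.cross(d, out)
    if np.linalg.norm(axis) > 1e-9:
        ang = np.degrees(np.arccos(np.clip(d @ out, -1, 1)))
        R = rotation_about_axis(axis, ang)
    else:
        R = np.eye(3)
    for atom in nt.atoms:
        atom.position = R @ (atom.position - c1) + pos
    return nt


def wrap_angle(a: float) -> float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _link_backbone(residues: List[Residue]) -> None:
    for prev, cur in zip(residues, residues[1:]):
        if not (prev.has("O3'") and cur.has("C5'")):
            continue
        o3 = prev.pos("O3'")
        c5 = cur.pos("C5'")
        u = (c5 - o3) / np.linalg.norm(c5 - o3)
        p = o3 + 1.60 * u
        cur.atom("P").position = p
        v = (c5 - p) / np.linalg.norm(c5 - p)
        cur.atom("O5'").position = p + 1.44 * v
    first = residues[0]
    if first.has("P"):
        first.atoms = [a for a in first.atoms if a.name != "P"]
        first._index.pop("P")


def _place_o5_contact(residues, a3_seq: int, distance: float, core_info) -> None:
    from .contacts import h8_position

    a3 = residues[a3_seq - 1]
    core_seqs = sorted(ci["seq"] for ci in core_info)
    later = [s for s in core_seqs if s > a3_seq]
    if not later:
        return
    target = residues[later[0] - 1]
    h8, _ = h8_position(target)
    c5 = a3.pos("C5'")
    u = (c5 - h8) / np.linalg.norm(c5 - h8)
    a3.atom("O5'").position = h8 + distance * u


def _ground_truth(spec, core_info, anchor_pairs, residues) -> dict:
    key = lambda s: ("A", s)
    by_layer: Dict[int, List[tuple]] = {}
    by_col: Dict[int, List[tuple]] = {}
    for ci in core_info:
        by_layer.setdefault(ci["layer"], []).append((ci["layer"], key(ci["seq"])))
        by_col.setdefault(ci["column"], []).append((ci["layer"], key(ci["seq"])))
    layers = [
        sorted(k for _, k in by_layer[l]) for l in range(spec.n_layers)
    ]
    columns = [
        [k for _, k in sorted(by_col[c], key=lambda t: t[0])] for c in range(4)
    ]

    # tracts: maximal seq-consecutive core runs within one column
    tracts = []
    seq_sorted = sorted(core_info, key=lambda ci: ci["seq"])
    run: List[dict] = []
    for ci in seq_sorted + [None]:
        if run and (
            ci is None
            or ci["seq"] != run[-1]["seq"] + 1
            or ci["column"] != run[-1]["column"]
        ):
            keys = tuple(key(r["seq"]) for r in run)
            if len(run) > 1:
                orientation = "down" if run[-1]["layer"] > run[0]["layer"] else "up"
            else:
                orientation = None
            tracts.append((keys, orientation))
            run = []
        if ci is not None:
            run.append(ci)

    loops = []
    for (a5, a3), kind, n_nt in zip(anchor_pairs, spec.loop_kinds, spec.loop_nts):
        loops.append({
            "kind": kind, "anchor5": key(a5), "anchor3": key(a3),
            "n_intervening": n_nt,
        })

    vloop = None
    if spec.vloop_connection is not None:
        a5, a3 = anchor_pairs[spec.vloop_connection]
        l5 = next(ci["layer"] for ci in core_info if ci["seq"] == a5)
        l3 = next(ci["layer"] for ci in core_info if ci["seq"] == a3)
        vloop = {
            "anchor5": key(a5), "anchor3": key(a3),
            "n_intervening": spec.loop_nts[spec.vloop_connection],
            "layers_spanned": abs(l5 - l3) + 1,
            "subtype": spec.vloop_subtype,
            "polarity_class": "V_S" if spec.polarities[l5] == spec.polarities[l3] else "V_R",
        }

    return {
        "name": spec.name,
        "seed": spec.seed,
        "sigma": spec.sigma,
        "n_layers": spec.n_layers,
        "layers": layers,
        "columns": columns,
        "tracts": tracts,
        "loops": loops,
        "vloop": vloop,
        "polarities": list(spec.polarities),
        "relative_polarities": [
            "homopolar" if a == b else "heteropolar"
            for a, b in zip(spec.polarities, spec.polarities[1:])
        ],
        "chi_domains": _chi_domains(spec),
        "n_core": 4 * spec.n_layers,
    }


def _chi_domains(spec) -> List[str]:
    from .torsions import classify_chi

    return [classify_chi(c) for c in spec.chi]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _flat(per_tract: List[List[float]]) -> List[float]:
    return [x for tract in per_tract for x in tract]


def preset(name: str, **overrides) -> MockTopologySpec:
    """Named study fixtures; overrides replace any spec field."""
    n = 3
    anti, syn, low_syn = 240.0, 60.0, 330.0
    south, north = 162.0, 18.0

    if name == "parallel":
        n_layers = overrides.pop("n_layers", 3)
        spec = MockTopologySpec(
            name=name, n_layers=n_layers,
            segments=[Segment(c, 0, n_layers - 1) for c in range(4)],
            loop_nts=[2, 2, 2], loop_kinds=["propeller"] * 3,
            polarities=[1] * n_layers,
            chi=[anti] * (4 * n_layers), P=[south] * (4 * n_layers),
            tau_m=[38.0] * (4 * n_layers), chemistry=[DEOXYRIBOSE] * (4 * n_layers),
        )
    elif name == "hybrid":
        spec = MockTopologySpec(
            name=name, n_layers=n,
            segments=[Segment(0, 0, 2), Segment(1, 0, 2),
                      Segment(2, 2, 0), Segment(3, 0, 2)],
            loop_nts=[2, 2, 1], loop_kinds=["propeller", "lateral", "lateral"],
            polarities=[-1, 1, 1],
            chi=_flat([[syn, anti, anti], [syn, anti, anti],
                       [syn, syn, anti], [syn, anti, anti]]),
            P=[south] * 12, tau_m=[38.0] * 12, chemistry=[DEOXYRIBOSE] * 12,
        )
    elif name == "antiparallel":
        spec = MockTopologySpec(
            name=name, n_layers=n,
            segments=[Segment(0, 0, 2), Segment(1, 2, 0),
                      Segment(2, 0, 2), Segment(3, 2, 0)],
            loop_nts=[2, 2, 2], loop_kinds=["lateral"] * 3,
            polarities=[1, -1, 1],
            chi=_flat([[syn, syn, anti], [syn, anti, anti],
                       [syn, syn, anti], [syn, anti, anti]]),
            P=[south] * 12, tau_m=[38.0] * 12, chemistry=[DEOXYRIBOSE] * 12,
        )
    elif name == "vloop_conventional":
        # isolated anchor5 on the top layer reached laterally; V drops three
        # layers; the following tract climbs back; filler completes column 2
        spec = MockTopologySpec(
            name=name, n_layers=n,
            segments=[Segment(0, 0, 2), Segment(1, 2, 0), Segment(2, 0, 0),
                      Segment(3, 2, 0), Segment(2, 1, 2)],
            loop_nts=[2, 1, 0, 1],
            loop_kinds=["lateral", "lateral", "V", "other"],
            polarities=[1, 1, -1],
            chi=_flat([[anti] * 3, [anti] * 3, [syn],
                       [anti] * 3, [anti] * 2]),
            P=_flat([[south] * 3, [south] * 3, [north],
                     [north, south, south], [south] * 2]),
            tau_m=_flat([[38.0] * 3, [38.0] * 3, [38.0],
                         [58.0, 38.0, 38.0], [38.0] * 2]),
            chemistry=_flat([[DEOXYRIBOSE] * 3, [DEOXYRIBOSE] * 3, [F_RIBO],
                             [LOCKED, DEOXYRIBOSE, DEOXYRIBOSE], [DEOXYRIBOSE] * 2]),
            o5_contact_distance=2.9,
            vloop_subtype="conventional", vloop_connection=2,
        )
    elif name == "vloop_alternative":
        # vertical (propeller-style) descent into a bottom-layer anchor5;
        # V climbs back to the top; reversed top tetrad
        spec = MockTopologySpec(
            name=name, n_layers=n,
            segments=[Segment(0, 0, 2), Segment(1, 2, 0), Segment(2, 2, 2),
                      Segment(3, 0, 2), Segment(2, 1, 0)],
            loop_nts=[2, 1, 0, 1],
            loop_kinds=["lateral", "propeller", "V", "other"],
            polarities=[-1, 1, 1],
            chi=_flat([[anti] * 3, [anti] * 3, [low_syn],
                       [anti] * 3, [anti] * 2]),
            P=_flat([[south] * 3, [south] * 3, [south],
                     [south] * 3, [south] * 2]),
            tau_m=[38.0] * 12,
            chemistry=_flat([[DEOXYRIBOSE] * 3, [DEOXYRIBOSE] * 3, [F_ARABINO],
                             [DEOXYRIBOSE] * 3, [DEOXYRIBOSE] * 2]),
            vloop_subtype="alternative", vloop_connection=2,
        )
    else:
        raise MockSpecError(f"unknown preset {name!r}")

    for k, v in overrides.items():
        if not hasattr(spec, k):
            raise MockSpecError(f"unknown spec field {k!r}")
        setattr(spec, k, v)
    spec.validate()
    return spec


PRESETS = ("parallel", "hybrid", "antiparallel", "vloop_conventional", "vloop_alternative")


def random_mock_spec(rng: np.random.Generator, sigma_max: float = 0.3) -> MockTopologySpec:
    """A randomized but geometrically valid study spec (for recovery sweeps)."""
    name = PRESETS[rng.integers(len(PRESETS))]
    overrides = dict(
        rise=float(rng.uniform(3.5, 3.7)),
        twist=float(rng.uniform(12.0, 20.0)),
        sigma=float(rng.uniform(0.02, sigma_max)),
        seed=int(rng.integers(2 ** 31 - 1)),
        n_models=10,
        include_hydrogens=bool(rng.integers(2)),
    )
    if name == "parallel":
        overrides["n_layers"] = int(rng.integers(2, 5))
    spec = preset(name, **overrides)
    if name in ("parallel", "hybrid", "antiparallel"):
        spec.polarities = [int(s) for s in rng.choice([-1, 1], size=spec.n_layers)]
    else:
        # keep the planned V-loop anchors but randomize which polarity class
        spec.polarities = [int(s) for s in rng.choice([-1, 1], size=spec.n_layers)]
    n_core = 4 * spec.n_layers
    spec.chi = [float(wrap360(c + rng.uniform(-15, 15))) for c in spec.chi]
    spec.P = [float(wrap360(p + rng.uniform(-8, 8))) for p in spec.P]
    spec.tau_m = [float(np.clip(t + rng.uniform(-4, 4), 20, 62)) for t in spec.tau_m]
    spec.validate()
    return spec


def write_fixture(spec: MockTopologySpec, out_dir) -> Tuple[Path, Path]:
    """Write the fixture PDB and its ground-truth JSON side file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ensemble, truth = build_mock_quadruplex(spec)
    pdb_path = out_dir / f"{spec.name}.pdb"
    json_path = out_dir / f"{spec.name}.truth.json"
    write_pdb(ensemble, pdb_path)
    json_path.write_text(json.dumps(_jsonable(truth), indent=2, sort_keys=True))
    return pdb_path, json_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
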