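"""G-quartet detection and fold topology classification.

A G-quartet is a directed 4-cycle in the Hoogsteen hydrogen-bond graph:
guanine A donates to guanine B when both N1(A)...O6(B) and N2(A)...N7(B)
heavy-atom distances fall below a cutoff (default 3.5 A, chosen so the
criterion works without hydrogens).  Detected quartets are stacked into
layers along the principal axis of their centroids, guanines are threaded
into four columns, sequence-consecutive core runs become tracts, and the
linkers between consecutive core anchors are classified as lateral,
diagonal, propeller or V-shaped loops.  V-shaped loops are further split
into conventional/alternative (backbone inversion after vs. within the
loop) and V_R/V_S (linked outer quartets of reverse vs. same polarity).

Ensemble handling follows NMR practice: hydrogen-bond distances are
averaged over the superposed models for the consensus call, while each
model is also classified on its own; models that disagree with the
consensus raise flags instead of silently flipping labels.
"""
from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .structure import Ensemble, Model, Residue

__all__ = [
    "TopologyError",
    "HoogsteenEdge",
    "Quartet",
    "Tract",
    "Loop",
    "VLoopRecord",
    "QuartetTopology",
    "EnsembleTopology",
    "detect_hoogsteen_edges",
    "detect_quartets",
    "stack_quartets",
    "quartet_polarity",
    "classify_loops",
    "classify_vloop",
    "model_topology",
    "ensemble_topology",
]

DEFAULT_HBOND_CUTOFF = 3.5  # A, heavy-atom donor...acceptor

_BASE_RING = ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3")


class TopologyError(ValueError):
    """Raised when quartets cannot be assembled into a consistent fold."""


class InconsistentVLoopError(TopologyError):
    """The backbone direction scan around a V-loop admits no inversion site."""


def base_centroid(residue: Residue) -> np.ndarray:
    pts = [residue.pos(n) for n in _BASE_RING if residue.has(n)]
    if len(pts) < 5:
        raise TopologyError(f"residue {residue.label}: too few base ring atoms")
    return np.mean(pts, axis=0)


@dataclass
class HoogsteenEdge:
    donor: Residue
    acceptor: Residue
    bonds: List[Tuple[str, str, float]]  # (donor atom, acceptor atom, distance)

    @property
    def mean_distance(self) -> float:
        return float(np.mean([b[2] for b in self.bonds]))


@dataclass
class Quartet:
    members: List[Residue]          # donor -> acceptor cyclic order
    mean_hbond_distance: float
    polarity_sign: int = 0          # +-1 once an axis is chosen

    def __post_init__(self):
        self.member_keys = tuple(r.key for r in self.members)
        self.centroid = np.mean([base_centroid(r) for r in self.members], axis=0)

    @property
    def plane_normal(self) -> np.ndarray:
        pts = np.array([base_centroid(r) for r in self.members])
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[-1]


@dataclass
class Tract:
    residues: List[Residue]
    column: int
    orientation: Optional[str]      # "up" (toward layer 0) | "down" | None

    @property
    def keys(self):
        return tuple(r.key for r in self.residues)


@dataclass
class Loop:
    kind: str                       # lateral | diagonal | propeller | V | other
    anchor5: Residue
    anchor3: Residue
    residues: List[Residue]         # intervening, sequence order


@dataclass
class VLoopRecord:
    anchor5: Residue
    anchor3: Residue
    intervening: List[Residue]
    layers_spanned: int
    inversion_site: str             # within_loop | after_loop
    subtype: str                    # alternative | conventional
    polarity_class: str             # V_R | V_S


@dataclass
class QuartetTopology:
    quartets: List[Quartet]         # ordered top (layer 0) to bottom
    axis: np.ndarray
    layers: List[List[Residue]]
    columns: List[List[Residue]]    # 4 columns, each ordered top to bottom
    tracts: List[Tract]
    loops: List[Loop]
    vloops: List[VLoopRecord]
    polarities: List[int]
    relative_polarities: List[str]  # homopolar | heteropolar per adjacent pair
    warnings: List[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_of(self, key) -> int:
        return self._layer_index[key]

    def column_of(self, key) -> int:
        return self._column_index[key]

    def summary(self) -> dict:
        """Hashable-ish label summary used for ensemble consensus voting."""
        return {
            "layers": [[r.key for r in layer] for layer in self.layers],
            "columns": [[r.key for r in col] for col in self.columns],
            "tracts": [(t.keys, t.orientation) for t in self.tracts],
            "loops": [(lp.kind, lp.anchor5.key, lp.anchor3.key) for lp in self.loops],
            "vloops": [
                (v.anchor5.key, v.anchor3.key, v.subtype, v.polarity_class)
                for v in self.vloops
            ],
            "polarities": list(self.polarities),
            "relative_polarities": list(self.relative_polarities),
        }


# ---------------------------------------------------------------------------
# Hoogsteen edges and quartets
# ---------------------------------------------------------------------------

def detect_hoogsteen_edges(
    model: Model,
    dist_cutoff: float = DEFAULT_HBOND_CUTOFF,
    distance_fn=None,
) -> List[HoogsteenEdge]:
    """Directed Hoogsteen edges A->B: N1(A)..O6(B) and N2(A)..N7(B) <= cutoff.

    ``distance_fn(resA, atomA, resB, atomB)`` may replace the plain
    euclidean distance (used for ensemble-averaged detection).
    """
    guanines = [g for g in model.guanines() if g.has("N1", "N2", "O6", "N7")]
    if distance_fn is None:
        def distance_fn(ra, na, rb, nb):
            return float(np.linalg.norm(ra.pos(na) - rb.pos(nb)))

    edges = []
    for a in guanines:
        for b in guanines:
            if a is b:
                continue
            d1 = distance_fn(a, "N1", b, "O6")
            if d1 > dist_cutoff:
                continue
            d2 = distance_fn(a, "N2", b, "N7")
            if d2 > dist_cutoff:
                continue
            edges.append(HoogsteenEdge(a, b, [("N1", "O6", d1), ("N2", "N7", d2)]))
    return edges


def detect_quartets(edges: Sequence[HoogsteenEdge]) -> List[Quartet]:
    """All directed 4-cycles of the Hoogsteen graph, deduplicated and merged.

    Each cycle is reported once, rotated to start at its lowest
    (chain, seq_index) member; near-duplicate cycles sharing three or more
    members keep only the candidate with the smaller mean hydrogen-bond
    distance.
    """
    if not edges:
        return []
    graph = nx.DiGraph()
    res_by_key: Dict[tuple, Residue] = {}
    edge_dist: Dict[tuple, float] = {}
    for e in edges:
        ka, kb = e.donor.key, e.acceptor.key
        res_by_key[ka] = e.donor
        res_by_key[kb] = e.acceptor
        graph.add_edge(ka, kb)
        edge_dist[(ka, kb)] = e.mean_distance

    candidates = []
    seen = set()
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        start = cycle.index(min(cycle))
        cyc = tuple(cycle[start:] + cycle[:start])
        if cyc in seen:
            continue
        seen.add(cyc)
        dists = [edge_dist[(cyc[i], cyc[(i + 1) % 4])] for i in range(4)]
        candidates.append(Quartet([res_by_key[k] for k in cyc], float(np.mean(dists))))

    candidates.sort(key=lambda q: (q.mean_hbond_distance, q.member_keys))
    accepted: List[Quartet] = []
    for cand in candidates:
        if any(len(set(cand.member_keys) & set(q.member_keys)) >= 3 for q in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda q: q.member_keys)
    return accepted


# ---------------------------------------------------------------------------
# Stacking, polarity
# ---------------------------------------------------------------------------

def stack_quartets(
    quartets: Sequence[Quartet],
    axis_hint: Optional[np.ndarray] = None,
):
    """Order quartets into layers along the stack axis and thread columns.

    The axis is the first principal direction of the quartet centroids,
    oriented so the layer holding the 5'-most core guanine comes first
    ("top"); with an ``axis_hint`` the orientation follows the hint
    instead (useful for frame-fixed comparisons).  Columns are threaded by
    matching each guanine to the nearest base centroid of the next layer
    (<= 5 A).  Returns (layers of quartets, axis, columns, warnings).
    """
    if len(quartets) < 2:
        raise TopologyError("stacking needs at least two quartets")
    warnings: List[str] = []
    centroids = np.array([q.centroid for q in quartets])
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    if axis_hint is not None:
        if axis @ np.asarray(axis_hint, dtype=float) < 0:
            axis = -axis
    else:
        first_key = min(k for q in quartets for k in q.member_keys)
        proj = centroids @ axis
        q_first = next(q for q in quartets if first_key in q.member_keys)
        if centroids[quartets.index(q_first)] @ axis < proj.mean():
            axis = -axis

    order = np.argsort([-(q.centroid @ axis) for q in quartets])
    layered = [quartets[i] for i in order]
    proj = [q.centroid @ axis for q in layered]
    for i in range(len(layered) - 1):
        gap = proj[i] - proj[i + 1]
        if not (2.5 <= gap <= 5.5):
            warnings.append(
                f"layer spacing {gap:.2f} A between layers {i} and {i + 1} "
                "outside the 2.5-5.5 A stacking range"
            )

    # thread columns top-down by nearest base centroid in the next layer
    columns: List[List[Residue]] = [[g] for g in layered[0].members]
    for layer in layered[1:]:
        cents = [base_centroid(g) for g in layer.members]
        taken = set()
        for col in columns:
            prev = base_centroid(col[-1])
            dists = [
                np.linalg.norm(prev - c) if i not in taken else np.inf
                for i, c in enumerate(cents)
            ]
            best = int(np.argmin(dists))
            if dists[best] > 5.0:
                raise TopologyError(
                    f"column starting at {col[0].label} finds no stacked guanine "
                    f"within 5 A in the next layer"
                )
            taken.add(best)
            col.append(layer.members[best])
    return layered, axis, columns, warnings


def quartet_polarity(quartet: Quartet, axis: np.ndarray) -> int:
    """Sign of the donor->acceptor circulation of the quartet about ``axis``."""
    pts = [base_centroid(r) - quartet.centroid for r in quartet.members]
    total = 0.0
    for i in range(4):
        total += np.asarray(axis, dtype=float) @ np.cross(pts[i], pts[(i + 1) % 4])
    if abs(total) < 1e-9:
        raise TopologyError("degenerate quartet: circulation vanishes")
    return 1 if total > 0 else -1


# ---------------------------------------------------------------------------
# Tracts and loops
# ---------------------------------------------------------------------------

def _build_tracts(topo: "QuartetTopology", rise: float) -> List[Tract]:
    core = sorted(topo._core_keys)
    runs: List[List[tuple]] = []
    for key in core:
        if (runs and key[0] == runs[-1][-1][0] and key[1] == runs[-1][-1][1] + 1
                and topo.column_of(key) == topo.column_of(runs[-1][-1])):
            runs[-1].append(key)
        else:
            runs.append([key])
    tracts = []
    for run in runs:
        residues = [topo._res_by_key[k] for k in run]
        orientation = None
        if len(run) > 1:
            dz = (base_centroid(residues[-1]) - base_centroid(residues[0])) @ topo.axis
            if abs(dz) > 0.5 * rise:
                orientation = "up" if dz > 0 else "down"
        tracts.append(Tract(residues, topo.column_of(run[0]), orientation))
    return tracts


def _column_orientation(topo: "QuartetTopology", column: int) -> Optional[str]:
    best = None
    for tract in topo.tracts:
        if tract.column == column and tract.orientation is not None:
            if best is None or len(tract.residues) > len(best.residues):
                best = tract
    return best.orientation if best else None


def _effective_orientation(topo, residue: Residue) -> Optional[str]:
    for tract in topo.tracts:
        if residue.key in tract.keys and tract.orientation is not None:
            return tract.orientation
    return _column_orientation(topo, topo.column_of(residue.key))


def classify_loops(topo: "QuartetTopology", model: Model) -> List[Loop]:
    """Classify the linkers between sequence-consecutive core anchors.

    Same-end connections are lateral (adjacent columns) or diagonal;
    opposite-end connections are V-shaped when they join antiparallel
    neighboring columns across >= 3 layers with <= 2 intervening
    residues, propeller when the flanking strands run parallel; anything
    else (e.g. a connection ending on a middle layer) is reported as
    ``other``.  Anchors in the same column are tract continuations, not
    loops.
    """
    core = topo._core_keys
    loops: List[Loop] = []
    by_chain: Dict[str, List[Residue]] = collections.defaultdict(list)
    for res in model.residues:
        by_chain[res.chain_id].append(res)
    for chain_id, residues in by_chain.items():
        residues = sorted(residues, key=lambda r: r.seq_index)
        anchors = [r for r in residues if r.key in core]
        for a, b in zip(anchors, anchors[1:]):
            between = [
                r for r in residues
                if a.seq_index < r.seq_index < b.seq_index and r.key not in core
            ]
            ca, cb = topo.column_of(a.key), topo.column_of(b.key)
            if ca == cb:
                continue  # tract continuation
            la, lb = topo.layer_of(a.key), topo.layer_of(b.key)
            adjacent = (cb - ca) % 4 in (1, 3)
            outer = {0, topo.n_layers - 1}
            oa, ob = _effective_orientation(topo, a), _effective_orientation(topo, b)
            if la == lb:
                kind = "lateral" if adjacent else "diagonal"
            elif {la, lb} == outer:
                span = abs(la - lb) + 1
                antiparallel = oa is not None and ob is not None and oa != ob
                parallel = oa is not None and oa == ob
                if adjacent and antiparallel and len(between) <= 2 and span >= 3:
                    kind = "V"
                elif parallel:
                    kind = "propeller"
                else:
                    kind = "other"
            else:
                kind = "other"
            loops.append(Loop(kind, a, b, between))
    return loops


def classify_vloop(loop: Loop, topo: "QuartetTopology", rise: float) -> VLoopRecord:
    """Subtype a V-shaped loop by locating the backbone inversion site.

    The scan projects C1' positions on the stack axis and takes the signed
    step direction into the 5' anchor (from the preceding core guanine),
    across the loop, and out of the 3' anchor.  A near-horizontal arrival
    (same-end lateral/diagonal step) leaves the V-jump as the first
    vertical direction, so the first reversal falls after the loop:
    conventional.  A vertical arrival opposing the V-jump puts the first
    reversal between the anchors: alternative.  V_R/V_S records whether
    the two linked outer quartets have reverse or the same polarity.
    """
    a5, a3 = loop.anchor5, loop.anchor3
    core_sorted = sorted(topo._core_keys)
    axis = topo.axis

    def zc(res: Residue) -> float:
        return float(res.pos("C1'") @ axis) if res.has("C1'") else float(base_centroid(res) @ axis)

    def step_sign(r1: Residue, r2: Residue) -> int:
        dz = zc(r2) - zc(r1)
        if abs(dz) < 0.5 * rise:
            return 0
        return 1 if dz > 0 else -1

    # previous core G: same-column tract predecessor if any, else sequence predecessor
    prev = None
    for tract in topo.tracts:
        if a5.key in tract.keys:
            idx = tract.keys.index(a5.key)
            if idx > 0:
                prev = tract.residues[idx - 1]
    if prev is None:
        earlier = [k for k in core_sorted if k[0] == a5.key[0] and k[1] < a5.key[1]]
        if earlier:
            prev = topo._res_by_key[earlier[-1]]

    s_in = step_sign(prev, a5) if prev is not None else 0
    s_loop = step_sign(a5, a3)
    later = [k for k in core_sorted if k[0] == a3.key[0] and k[1] > a3.key[1]]
    nxt = topo._res_by_key[later[0]] if later else None
    s_out = step_sign(a3, nxt) if nxt is not None else 0

    if s_loop == 0 or s_out == 0 or s_loop == s_out:
        raise InconsistentVLoopError(
            f"V-loop {a5.label}->{a3.label}: no backbone inversion found "
            f"(steps {s_in:+d}, {s_loop:+d}, {s_out:+d})"
        )
    if s_in != 0 and s_in != s_loop:
        inversion, subtype = "within_loop", "alternative"
    else:
        inversion, subtype = "after_loop", "conventional"

    q5 = topo.quartets[topo.layer_of(a5.key)]
    q3 = topo.quartets[topo.layer_of(a3.key)]
    polarity_class = "V_S" if q5.polarity_sign == q3.polarity_sign else "V_R"
    return VLoopRecord(
        anchor5=a5, anchor3=a3, intervening=loop.residues,
        layers_spanned=abs(topo.layer_of(a5.key) - topo.layer_of(a3.key)) + 1,
        inversion_site=inversion, subtype=subtype, polarity_class=polarity_class,
    )


# ---------------------------------------------------------------------------
# Whole-model / whole-ensemble drivers
# ---------------------------------------------------------------------------

def model_topology(
    model: Model,
    dist_cutoff: float = DEFAULT_HBOND_CUTOFF,
    axis_hint: Optional[np.ndarray] = None,
    distance_fn=None,
) -> QuartetTopology:
    """Full topology classification of a single model."""
    edges = detect_hoogsteen_edges(model, dist_cutoff, distance_fn=distance_fn)
    quartets = detect_quartets(edges)
    if len(quartets) < 2:
        raise TopologyError(f"found {len(quartets)} quartet(s); need >= 2 to stack")
    layered, axis, columns, warnings = stack_quartets(quartets, axis_hint=axis_hint)

    topo = QuartetTopology(
        quartets=layered, axis=axis,
        layers=[list(q.members) for q in layered],
        columns=columns, tracts=[], loops=[], vloops=[],
        polarities=[], relative_polarities=[], warnings=warnings,
    )
    topo._core_keys = {r.key for q in layered for r in q.members}
    topo._res_by_key = {r.key: r for q in layered for r in q.members}
    topo._layer_index = {r.key: i for i, q in enumerate(layered) for r in q.members}
    topo._column_index = {g.key: c for c, col in enumerate(columns) for g in col}

    for q in layered:
        q.polarity_sign = quartet_polarity(q, axis)
    topo.polarities = [q.polarity_sign for q in layered]
    topo.relative_polarities = [
        "homopolar" if a == b else "heteropolar"
        for a, b in zip(topo.polarities, topo.polarities[1:])
    ]

    proj = [q.centroid @ axis for q in layered]
    rise = float(np.median(np.abs(np.diff(proj)))) if len(proj) > 1 else 3.4
    topo.tracts = _build_tracts(topo, rise)
    topo.loops = classify_loops(topo, model)
    for loop in topo.loops:
        if loop.kind != "V":
            continue
        try:
            topo.vloops.append(classify_vloop(loop, topo, rise))
        except InconsistentVLoopError as exc:
            topo.warnings.append(str(exc))
    return topo


@dataclass
class EnsembleTopology:
    consensus: QuartetTopology
    per_model: List[Optional[QuartetTopology]]
    agreement: float                # fraction of models matching the consensus
    flags: List[str]


def ensemble_topology(
    ensemble: Ensemble,
    dist_cutoff: float = DEFAULT_HBOND_CUTOFF,
    axis_hint: Optional[np.ndarray] = None,
) -> EnsembleTopology:
    """Consensus topology of a superposed ensemble, with per-model checks.

    Hydrogen-bond distances for the consensus are averaged across models
    (the analogue of ensemble-averaged restraint analysis), which keeps
    edge detection stable against per-model coordinate noise; geometry
    (stacking, polarity, backbone directions) is evaluated on the
    model-averaged coordinates.  Each model is additionally classified on
    its own; disagreement or per-model failures are reported as flags.
    """
    mean_model = _mean_coordinate_model(ensemble)
    consensus = model_topology(mean_model, dist_cutoff, axis_hint=axis_hint)

    per_model: List[Optional[QuartetTopology]] = []
    flags: List[str] = []
    matches = 0
    ref = consensus.summary()
    for model in ensemble:
        try:
            topo = model_topology(model, dist_cutoff, axis_hint=consensus.axis)
        except TopologyError as exc:
            per_model.append(None)
            flags.append(f"model {model.number}: {exc}")
            continue
        per_model.append(topo)
        if topo.summary() == ref:
            matches += 1
        else:
            flags.append(f"model {model.number} disagrees with consensus topology")
    agreement = matches / len(ensemble)
    if agreement < 0.5:
        flags.append(
            f"consensus supported by only {matches}/{len(ensemble)} models; "
            "treat labels as low-confidence"
        )
    if consensus.warnings:
        flags.extend(f"consensus: {w}" for w in consensus.warnings)
    return EnsembleTopology(consensus, per_model, agreement, flags)


def _mean_coordinate_model(ensemble: Ensemble) -> Model:
    """Model with coordinates averaged across the (superposed) ensemble."""
    from copy import deepcopy

    mean = deepcopy(ensemble.models[0])
    mean.number = 0
    for ri, res in enumerate(mean.residues):
        for atom in res.atoms:
            stack = np.array([
                m.residues[ri].atom(atom.name).position for m in ensemble.models
            ])
            atom.position = stack.mean(axis=0)
    return mean
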