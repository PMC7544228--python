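"""Base-backbone contact geometry: O4'/O5'/F2'/O2' ... H8-C8 interactions.

These weak CH...O/F contacts have donor-H-acceptor angles near 90-105 deg,
far from linear hydrogen bonds, so the presence call is made on the
acceptor-H8 distance alone: present below 3.5 A, absent above 4.0 A,
ambiguous in between (the gray zone between "below or slightly above 3 A"
and "above 4 A" contact classes).  Angles are reported but never gate the
call.  When a deposit lacks hydrogens, H8 is rebuilt on the external
bisector of N7-C8-N9 at 1.08 A.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import angle
from .structure import Ensemble, Residue
from .topology import EnsembleTopology, VLoopRecord

__all__ = [
    "ContactGeometry",
    "reconstruct_h8",
    "h8_position",
    "measure_contact",
    "scan_vloop_contacts",
    "PRESENT_CUTOFF",
    "ABSENT_CUTOFF",
]

PRESENT_CUTOFF = 3.5   # A: distance <= this  -> present
ABSENT_CUTOFF = 4.0    # A: distance >= this  -> absent
ACCEPTOR_ATOMS = ("O4'", "O5'", "F2'", "O2'")


@dataclass
class ContactGeometry:
    acceptor_residue: Residue
    acceptor_atom: str
    base_residue: Residue
    distance: float            # acceptor ... H8, A
    angle: float               # acceptor-H8-C8, deg
    h8_source: str             # file | reconstructed
    call: str                  # present | ambiguous | absent


def classify_call(
    distance: float,
    present_cutoff: float = PRESENT_CUTOFF,
    absent_cutoff: float = ABSENT_CUTOFF,
) -> str:
    if distance <= present_cutoff:
        return "present"
    if distance >= absent_cutoff:
        return "absent"
    return "ambiguous"


def reconstruct_h8(residue: Residue) -> np.ndarray:
    """H8 on the external bisector of N7-C8-N9, 1.08 A from C8."""
    for name in ("N7", "C8", "N9"):
        if not residue.has(name):
            raise KeyError(f"residue {residue.label}: missing atom {name} for H8 rebuild")
    c8 = residue.pos("C8")
    u = residue.pos("N7") - c8
    v = residue.pos("N9") - c8
    bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
    return c8 - 1.08 * bis / np.linalg.norm(bis)


def h8_position(residue: Residue) -> Tuple[np.ndarray, str]:
    if residue.has("H8"):
        return residue.pos("H8"), "file"
    return reconstruct_h8(residue), "reconstructed"


def measure_contact(
    acceptor: Tuple[Residue, str],
    base: Residue,
    present_cutoff: float = PRESENT_CUTOFF,
    absent_cutoff: float = ABSENT_CUTOFF,
) -> ContactGeometry:
    """Distance/angle geometry of one acceptor ... H8-C8 contact."""
    acc_res, acc_name = acceptor
    acc = acc_res.atom(acc_name).position  # KeyError with residue context if absent
    h8, source = h8_position(base)
    d = float(np.linalg.norm(acc - h8))
    ang = angle(acc, h8, base.pos("C8"))
    return ContactGeometry(
        acceptor_residue=acc_res, acceptor_atom=acc_name, base_residue=base,
        distance=d, angle=ang, h8_source=source,
        call=classify_call(d, present_cutoff, absent_cutoff),
    )


def scan_vloop_contacts(
    topology: EnsembleTopology,
    ensemble: Ensemble,
    present_cutoff: float = PRESENT_CUTOFF,
    absent_cutoff: float = ABSENT_CUTOFF,
) -> pd.DataFrame:
    """Per-model V-loop contact geometries with per-contact occupancies.

    For every detected V-loop and every model, measures the contacts from
    the 3' anchor's O4'/O5' (and F2'/O2' when present) to H8 of the core
    guanine that follows the anchor, and the same acceptors against H8 of
    the 5' anchor.  Occupancy is the fraction of models in which the
    contact is called present.
    """
    rows = []
    consensus = topology.consensus
    core_sorted = sorted(consensus._core_keys)
    for vloop in consensus.vloops:
        a3_key, a5_key = vloop.anchor3.key, vloop.anchor5.key
        later = [k for k in core_sorted if k[0] == a3_key[0] and k[1] > a3_key[1]]
        target_keys = [("next_g", later[0])] if later else []
        target_keys.append(("anchor5", a5_key))
        for model in ensemble:
            a3 = model.residue(*a3_key)
            for role, tkey in target_keys:
                base = model.residue(*tkey)
                for acc_name in ACCEPTOR_ATOMS:
                    if not a3.has(acc_name):
                        continue
                    geom = measure_contact(
                        (a3, acc_name), base, present_cutoff, absent_cutoff
                    )
                    rows.append({
                        "model": model.number,
                        "vloop": f"{vloop.anchor5.label}->{vloop.anchor3.label}",
                        "acceptor_residue": a3.label,
                        "acceptor_atom": acc_name,
                        "base_residue": base.label,
                        "base_role": role,
                        "distance": geom.distance,
                        "angle": geom.angle,
                        "h8_source": geom.h8_source,
                        "call": geom.call,
                    })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    occ = (
        df.assign(present=df["call"].eq("present"))
        .groupby(["vloop", "acceptor_atom", "base_role"])["present"]
        .mean()
        .rename("occupancy")
    )
    return df.merge(occ, on=["vloop", "acceptor_atom", "base_role"], how="left")


def summarize_contacts(df: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max distance and occupancy per contact across models."""
    if df.empty:
        return df
    return (
        df.groupby(["vloop", "acceptor_residue", "acceptor_atom", "base_residue", "base_role"])
        .agg(
            mean_distance=("distance", "mean"),
            min_distance=("distance", "min"),
            max_distance=("distance", "max"),
            mean_angle=("angle", "mean"),
            occupancy=("occupancy", "first"),
        )
        .reset_index()
    )
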