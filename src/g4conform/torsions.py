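"""Glycosidic torsion, sugar ring torsions and pseudorotation analysis.

The furanose pucker is summarized by the pseudorotation phase angle P and
amplitude tau_m of the five endocyclic torsions nu0..nu4 (Altona-
Sundaralingam convention, nu2 = C1'-C2'-C3'-C4' so that nu2 = tau_m cos P).
The glycosidic torsion chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2
for pyrimidines.

Domain boundaries: the low-syn range [300, 360) follows the published
V-loop classification; syn [0, 120), intermediate [120, 180) and anti
[180, 300) follow common usage. North puckers are P in [270, 360) u [0, 90),
south the complementary half-wheel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import signed_dihedral, dihedral, wrap180, wrap360, circular_mean
from .structure import Ensemble, Residue

__all__ = [
    "PuckerError",
    "TorsionProfile",
    "glycosidic_chi",
    "sugar_torsions",
    "pseudorotation",
    "classify_chi",
    "classify_pucker",
    "torsion_profile",
    "ensemble_torsion_table",
]

#: endocyclic torsion atom paths, nu0..nu4
NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

_SIN36_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))

#: pseudorotation wheel, 18-degree sectors; envelopes at 18 + 36 k
CONFORMER_WHEEL = (
    "C2'-exo/C3'-endo", "C3'-endo", "C3'-endo/C4'-exo", "C4'-exo",
    "C4'-exo/O4'-endo", "O4'-endo", "O4'-endo/C1'-exo", "C1'-exo",
    "C1'-exo/C2'-endo", "C2'-endo", "C2'-endo/C3'-exo", "C3'-exo",
    "C3'-exo/C4'-endo", "C4'-endo", "C4'-endo/O4'-exo", "O4'-exo",
    "O4'-exo/C1'-endo", "C1'-endo", "C1'-endo/C2'-exo", "C2'-exo",
)


class PuckerError(ValueError):
    """The ring is planar (or nearly so); the pseudorotation phase is undefined."""


@dataclass
class TorsionProfile:
    chi: float                  # degrees, [0, 360)
    nu: np.ndarray              # nu0..nu4, signed degrees
    P: float                    # pseudorotation phase, [0, 360)
    tau_m: float                # pucker amplitude, >= 0
    chi_domain: str
    pucker_domain: str
    conformer_label: str


def glycosidic_chi(residue: Residue) -> float:
    """Glycosidic torsion chi in degrees on [0, 360)."""
    bt = residue.base_type
    if bt == "purine":
        names = ("O4'", "C1'", "N9", "C4")
    elif bt == "pyrimidine":
        names = ("O4'", "C1'", "N1", "C2")
    else:
        raise KeyError(f"residue {residue.label} ({residue.name}) has no recognizable base")
    return dihedral(*(residue.pos(n) for n in names))


def sugar_torsions(residue: Residue) -> np.ndarray:
    """Endocyclic torsions nu0..nu4 as signed degrees in (-180, 180]."""
    return np.array([
        wrap180(signed_dihedral(*(residue.pos(n) for n in path))) for path in NU_ATOMS
    ])


def pseudorotation(nu: Sequence[float]) -> tuple:
    """Phase angle P ([0, 360)) and amplitude tau_m (>= 0) from nu0..nu4.

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72));
    the quadrant is fixed by the signs of numerator and nu2, which makes
    tau_m = nu2 / cos P non-negative.
    """
    nu = wrap180(np.asarray(nu, dtype=float))
    if nu.shape != (5,):
        raise ValueError("pseudorotation needs exactly five torsions")
    if np.all(np.abs(nu) < 1.0):
        raise PuckerError("ring is planar; pseudorotation phase undefined")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * _SIN36_SIN72
    P = wrap360(np.degrees(np.arctan2(num, den)))
    tau_m = np.hypot(num / (2.0 * _SIN36_SIN72), nu[2])
    return float(P), float(tau_m)


def classify_chi(chi: float, boundaries=(120.0, 180.0, 300.0)) -> str:
    """syn / anti / low_syn / intermediate domain of a glycosidic torsion.

    ``boundaries`` are the syn/intermediate, intermediate/anti and
    anti/low-syn cut points (degrees); the low-syn band always ends at 360.
    """
    syn_end, inter_end, anti_end = boundaries
    c = wrap360(chi)
    if c < syn_end:
        return "syn"
    if c < inter_end:
        return "intermediate"
    if c < anti_end:
        return "anti"
    return "low_syn"


def classify_pucker(P: float, north=(270.0, 90.0)) -> tuple:
    """(north|south, canonical envelope/twist name) for a phase angle.

    ``north`` gives the wrap-around north band [north[0], 360) u [0, north[1]).
    """
    p = wrap360(P)
    domain = "north" if (p >= north[0] or p < north[1]) else "south"
    sector = int(np.floor(wrap360(p + 9.0) / 18.0)) % 20
    return domain, CONFORMER_WHEEL[sector]


def torsion_profile(residue: Residue) -> TorsionProfile:
    """Full chi / pucker profile of one nucleotide."""
    chi = glycosidic_chi(residue)
    nu = sugar_torsions(residue)
    P, tau_m = pseudorotation(nu)
    domain, label = classify_pucker(P)
    return TorsionProfile(
        chi=chi, nu=nu, P=P, tau_m=tau_m,
        chi_domain=classify_chi(chi), pucker_domain=domain, conformer_label=label,
    )


def ensemble_torsion_table(ensemble: Ensemble, entry: Optional[str] = None) -> pd.DataFrame:
    """Per-residue, per-model torsion table plus circular-mean summary rows.

    Summary rows carry model = 0; angular columns are averaged with
    circular means so values near the 0/360 wrap do not cancel.
    """
    rows = []
    for model in ensemble:
        for res in model.nucleotides():
            try:
                prof = torsion_profile(res)
            except (KeyError, PuckerError):
                continue
            rows.append({
                "entry": entry or ensemble.entry_id or "",
                "model": model.number,
                "chain": res.chain_id,
                "seq_index": res.seq_index,
                "name": res.name,
                "sugar_chemistry": res.sugar_chemistry,
                "chi": prof.chi,
                "chi_domain": prof.chi_domain,
                **{f"nu{i}": prof.nu[i] for i in range(5)},
                "P": prof.P,
                "tau_m": prof.tau_m,
                "pucker_domain": prof.pucker_domain,
                "conformer_label": prof.conformer_label,
            })
    df = pd.DataFrame(rows)
    if df.empty or len(ensemble) < 2:
        return df

    summaries = []
    for (chain, seq), grp in df.groupby(["chain", "seq_index"], sort=False):
        chi_mean = circular_mean(grp["chi"])
        P_mean = circular_mean(grp["P"])
        domain, label = classify_pucker(P_mean)
        summaries.append({
            "entry": grp["entry"].iloc[0], "model": 0,
            "chain": chain, "seq_index": seq, "name": grp["name"].iloc[0],
            "sugar_chemistry": grp["sugar_chemistry"].iloc[0],
            "chi": chi_mean, "chi_domain": classify_chi(chi_mean),
            **{f"nu{i}": wrap180(circular_mean(grp[f"nu{i}"])) for i in range(5)},
            "P": P_mean, "tau_m": float(grp["tau_m"].mean()),
            "pucker_domain": domain, "conformer_label": label,
        })
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
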