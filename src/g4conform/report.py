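"""Analysis driver: configuration, report tables and plot-ready output.

``analyze`` runs the whole pipeline on one or more coordinate files and
writes, per run: a per-residue torsion CSV, a topology JSON, V-loop
contact CSVs, pairwise-RMSD CSVs, and a scatter-ready TSV of
pseudorotation phase vs. glycosidic torsion for V-loop flanking residues
(one row per anchor, the axes of the V-loop classification plots).
Numbers are formatted at fixed precision (angles 0.1 deg, distances and
RMSD 0.01 A) so repeated runs produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from .ensemble import core_guanine_heavy, heavy_atoms, pairwise_rmsd
from .structure import Ensemble, read_structure
from .topology import TopologyError, ensemble_topology
from .torsions import ensemble_torsion_table

logger = logging.getLogger("g4conform")

__all__ = ["AnalysisConfig", "AnalysisError", "analyze", "analyze_ensemble"]


class AnalysisError(RuntimeError):
    """A module error wrapped with entry/residue context for the CLI."""


@dataclass
class AnalysisConfig:
    inputs: List[str]
    out_dir: str = "g4conform_out"
    models: str = "all"                    # all | first
    format: str = "auto"                   # auto | pdb | mmcif
    hbond_cutoff: float = 3.5
    contact_present: float = 3.5
    contact_absent: float = 4.0
    # domain boundary overrides (degrees)
    chi_boundaries: List[float] = field(default_factory=lambda: [120.0, 180.0, 300.0])
    pucker_north: List[float] = field(default_factory=lambda: [270.0, 90.0])
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))


def _fmt(df: pd.DataFrame, angle_cols=(), dist_cols=()) -> pd.DataFrame:
    out = df.copy()
    for c in angle_cols:
        if c in out:
            out[c] = out[c].map(lambda v: f"{v:.1f}")
    for c in dist_cols:
        if c in out:
            out[c] = out[c].map(lambda v: f"{v:.2f}")
    return out


_ANGLE_COLS = ("chi", "nu0", "nu1", "nu2", "nu3", "nu4", "P", "tau_m", "angle", "mean_angle")
_DIST_COLS = ("distance", "mean_distance", "min_distance", "max_distance", "occupancy")


def analyze_ensemble(ensemble: Ensemble, config: AnalysisConfig, entry: str) -> dict:
    """Run every analysis stage on one ensemble; returns the report bundle."""
    if config.models == "first":
        ensemble = Ensemble(ensemble.models[:1], path=ensemble.path,
                            format=ensemble.format, entry_id=ensemble.entry_id)

    bundle: dict = {"entry": entry}
    table = ensemble_torsion_table(ensemble, entry=entry)
    if not table.empty:
        from .torsions import classify_chi, classify_pucker

        table["chi_domain"] = table["chi"].map(
            lambda c: classify_chi(c, tuple(config.chi_boundaries))
        )
        table["pucker_domain"] = table["P"].map(
            lambda p: classify_pucker(p, tuple(config.pucker_north))[0]
        )
    bundle["torsions"] = table

    try:
        topo = ensemble_topology(ensemble, dist_cutoff=config.hbond_cutoff)
    except TopologyError as exc:
        raise AnalysisError(f"{entry}: topology detection failed: {exc}") from exc
    bundle["topology"] = topo

    consensus = topo.consensus
    bundle["topology_json"] = {
        "entry": entry,
        "n_models": len(ensemble),
        "n_layers": consensus.n_layers,
        "core_guanines": sorted(
            f"{r.label}" for layer in consensus.layers for r in layer
        ),
        "layers": [
            {
                "members": [r.label for r in layer],
                "polarity_sign": consensus.polarities[i],
            }
            for i, layer in enumerate(consensus.layers)
        ],
        "relative_polarities": consensus.relative_polarities,
        "columns": [[r.label for r in col] for col in consensus.columns],
        "tracts": [
            {"residues": [r.label for r in t.residues], "orientation": t.orientation}
            for t in consensus.tracts
        ],
        "loops": [
            {
                "type": lp.kind,
                "anchor5": lp.anchor5.label,
                "anchor3": lp.anchor3.label,
                "residues": [r.label for r in lp.residues],
            }
            for lp in consensus.loops
        ],
        "vloops": [
            {
                "anchor5": v.anchor5.label,
                "anchor3": v.anchor3.label,
                "intervening": [r.label for r in v.intervening],
                "layers_spanned": v.layers_spanned,
                "inversion_site": v.inversion_site,
                "subtype": v.subtype,
                "polarity_class": v.polarity_class,
            }
            for v in consensus.vloops
        ],
        "model_agreement": round(topo.agreement, 3),
        "flags": topo.flags,
    }

    bundle["contacts"] = contacts_mod.scan_vloop_contacts(
        topo, ensemble, config.contact_present, config.contact_absent
    )
    bundle["contacts_summary"] = contacts_mod.summarize_contacts(bundle["contacts"])

    if len(ensemble) >= 2:
        core_keys = consensus._core_keys
        sel = core_guanine_heavy(core_keys)
        mean_core, matrix = pairwise_rmsd(ensemble, sel)
        mean_all, _ = pairwise_rmsd(ensemble, heavy_atoms())
        mean_core_fit_all, _ = pairwise_rmsd(ensemble, sel, fit_selection=heavy_atoms())
        bundle["rmsd_matrix"] = matrix
        bundle["rmsd_summary"] = {
            "core_heavy_mean_pairwise": round(mean_core, 4),
            "core_heavy_fit_all_mean_pairwise": round(mean_core_fit_all, 4),
            "all_heavy_mean_pairwise": round(mean_all, 4),
        }

    # scatter table: pucker phase vs glycosidic torsion of V-loop anchors
    rows = []
    tt = bundle["torsions"]
    for v in consensus.vloops:
        for role, res in (("anchor5", v.anchor5), ("anchor3", v.anchor3)):
            sub = tt[(tt["chain"] == res.chain_id) & (tt["seq_index"] == res.seq_index)]
            sub = sub[sub["model"] == 0] if (sub["model"] == 0).any() else sub
            if sub.empty:
                continue
            r = sub.iloc[0]
            rows.append({
                "entry": entry, "residue": res.label, "role": role,
                "chi": r["chi"], "P": r["P"],
                "chi_domain": r["chi_domain"], "pucker_domain": r["pucker_domain"],
                "subtype": v.subtype,
            })
    bundle["fig_vloop"] = pd.DataFrame(rows)
    return bundle


def analyze(config: AnalysisConfig) -> dict:
    """Run the pipeline on every input and write the report files."""
    logging.basicConfig(level=config.log_level)
    if not config.inputs:
        raise AnalysisError("no input files given")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_torsions, all_vloop_rows = [], []
    reports = {}
    for path in config.inputs:
        entry = Path(path).stem
        logger.info("analyzing %s", path)
        ensemble = read_structure(path, format=config.format)
        bundle = analyze_ensemble(ensemble, config, entry)
        reports[entry] = bundle
        all_torsions.append(bundle["torsions"])
        all_vloop_rows.append(bundle["fig_vloop"])

        (out / f"{entry}.topology.json").write_text(
            json.dumps(bundle["topology_json"], indent=2, sort_keys=True)
        )
        if not bundle["contacts"].empty:
            _fmt(bundle["contacts"], _ANGLE_COLS, _DIST_COLS).to_csv(
                out / f"{entry}.contacts.csv", index=False
            )
            _fmt(bundle["contacts_summary"], _ANGLE_COLS, _DIST_COLS).to_csv(
                out / f"{entry}.contacts_summary.csv", index=False
            )
        if "rmsd_matrix" in bundle:
            pd.DataFrame(bundle["rmsd_matrix"]).round(2).to_csv(
                out / f"{entry}.rmsd.csv", index=False
            )
            (out / f"{entry}.rmsd.json").write_text(
                json.dumps(bundle["rmsd_summary"], indent=2, sort_keys=True)
            )

    torsions = pd.concat(all_torsions, ignore_index=True)
    _fmt(torsions, _ANGLE_COLS, _DIST_COLS).to_csv(out / "torsions.csv", index=False)
    fig = pd.concat(all_vloop_rows, ignore_index=True) if all_vloop_rows else pd.DataFrame()
    _fmt(fig, _ANGLE_COLS, _DIST_COLS).to_csv(out / "fig_vloop.tsv", sep="\t", index=False)
    (out / "config.json").write_text(config.to_json())
    return reports
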