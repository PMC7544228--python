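# g4conform

Conformational analysis of G-quadruplex (G4) coordinate ensembles, for
structural biologists working on quadruplex folds and sugar-modified
nucleotides (LNA, 2'-F-ribo/arabino guanosine).

From a multi-model PDB or mmCIF deposit the package computes, per model and
as an ensemble consensus:

- **Glycosidic torsions** chi (O4'-C1'-N9-C4 for purines) with the domain
  classification *syn* [0, 120), *intermediate* [120, 180), *anti*
  [180, 300) and *low-syn* [300, 360);
- **Sugar pucker** via the endocyclic torsions nu0..nu4 and the
  pseudorotation phase angle / amplitude,

      tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
      tau_m = nu2 / cos P,

  with *north*/*south* domains and canonical envelope/twist conformer
  names (C3'-endo, C2'-endo, C4'-exo, ...);
- **Sugar chemistry** derived from the atom inventory and geometry alone
  (deoxyribose, ribose, locked 2'-O-4'-C bridge, 2'F-ribo, 2'F-arabino) —
  residue codes are never trusted;
- **G-quartet topology**: directed Hoogsteen hydrogen-bond edges
  (N1...O6 and N2...N7 heavy-atom distances <= 3.5 A), quartets as
  directed 4-cycles, stacked layers, columns, G-tracts with orientation,
  tetrad polarity (homopolar/heteropolar stacking), and loop taxonomy
  (lateral / diagonal / propeller / V-shaped);
- **V-loop subtypes**: conventional vs. alternative (backbone polarity
  inversion after vs. within the loop) and V_R vs. V_S (linked outer
  quartets of reverse vs. same polarity);
- **Base-backbone contacts**: O4'/O5'/F2'/O2' ... H8-C8 distances and
  angles with present (< 3.5 A) / ambiguous / absent (> 4 A) calls and
  per-ensemble occupancies, reconstructing H8 when deposits lack
  hydrogens;
- **Ensemble precision**: least-squares superposition and mean pairwise
  heavy-atom RMSD over any atom selection (e.g. the quartet-core
  guanines).

A synthetic-structure generator builds furanose rings at prescribed
(P, tau_m), nucleotides at prescribed chi and chemistry, Hoogsteen
quartets of either polarity, and whole mock quadruplexes with known
topology — so every stage of the pipeline is testable without downloading
deposited structures.

## Worked example

Generate a conventional-V-loop mock ensemble (10 models, 0.1 A coordinate
noise, an LNA-like locked sugar at the V-loop 3'-end) and analyze it:

```sh
g4conform fixture vloop_conventional --out demo
g4conform analyze demo/vloop_conventional.pdb --out demo/report
```

`demo/report/vloop_conventional.topology.json` (excerpt):

```json
{
 "n_layers": 3,
 "relative_polarities": ["homopolar", "heteropolar"],
 "vloops": [
  {
   "anchor5": "A10", "anchor3": "A11",
   "intervening": [], "layers_spanned": 3,
   "inversion_site": "after_loop",
   "subtype": "conventional", "polarity_class": "V_R"
  }
 ],
 "model_agreement": 1.0
}
```

The quadruplex stacks three quartet layers; the 0-nt V-shaped loop between
residues 10 and 11 spans all three layers, and the backbone direction
first reverses *after* the loop (between residue 11 and the next core G),
so the loop is classified conventional; the two quartets it links have
opposite polarity (V_R).

`demo/report/fig_vloop.tsv` is the scatter-ready pseudorotation-vs-chi
table for the V-loop flanking residues:

```text
entry               residue  role     chi    P     chi_domain  pucker_domain  subtype
vloop_conventional  A10      anchor5  59.4   18.2  syn         north          conventional
vloop_conventional  A11      anchor3  240.1  18.4  anti        north          conventional
```

Both anchors are north-puckered (C3'-endo region) with a syn 5'-anchor —
the conformational signature of a conventional V-loop.  The contact
summary shows the single present base-backbone contact, O5' of the
3'-anchor against H8 of the following core guanine, at 2.84 A mean
distance with occupancy 1.0 across the ensemble, while every other
acceptor is absent (> 4 A).  `vloop_conventional.rmsd.json` reports the
ensemble precision (mean pairwise heavy-atom RMSD on the core guanines,
0.24 A for this fixture at its 0.1 A noise level).

The same objects are available as a library:

```python
from g4conform import preset, build_mock_quadruplex, ensemble_topology

ensemble, truth = build_mock_quadruplex(preset("vloop_conventional"))
topo = ensemble_topology(ensemble)
print(topo.consensus.vloops[0].subtype)   # -> "conventional"
```

and `read_structure(path)` loads any multi-model PDB/mmCIF deposit into
the same `Ensemble` type.

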