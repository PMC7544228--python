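# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `g4conform`. All angles are degrees, all distances
Angstrom.

## Coordinate model and normalization

Deposits are read with gemmi (PDB v3.3 and mmCIF, multi-model). Atom
names are normalized on read: `*` and the unicode prime are mapped to
`'`, and old phosphate names (O1P/O2P/O3P) to OP1/OP2/OP3. Alternate
locations other than blank/A are dropped, which makes reading
deterministic; NMR ensembles rarely carry altlocs. Waters and ions are
retained but excluded from nucleotide-level analyses (a residue counts as
a nucleotide when it has C1' and O4'). All models of an ensemble must
share one residue sequence and atom inventory; a mismatch raises an error
naming the first offending residue rather than silently intersecting
atoms.

Sugar chemistry is derived from the atom inventory and geometry, never
from the residue code, because chemical-component codes for modified
nucleotides vary across deposits:

- **locked (LNA)** — a carbon bonded (< 1.8 A) to both O2' and C4'
  (the 2'-O-4'-C methylene bridge); the atom name of the bridge carbon is
  irrelevant.
- **2'F-ribo / 2'F-arabino** — a fluorine bonded to C2'; the epimer is
  decided by face: the fluorine on the same side of the furanose
  least-squares plane as the glycosidic nitrogen is arabino, the opposite
  side ribo.
- **ribose** — O2' without a bridge; otherwise **deoxyribose**.
- Missing ring atoms give **unknown** instead of an exception, so partial
  residues do not abort an ensemble scan.

## Torsions and pseudorotation

Dihedrals use the standard atan2 construction with the IUPAC sign
convention (verified against gemmi's torsion routine and an independent
projection formula) and are reported on [0, 360). The endocyclic
torsions are indexed nu0 = C4'-O4'-C1'-C2' through nu4 = C3'-C4'-O4'-C1',
which places nu2 = C1'-C2'-C3'-C4' so that nu2 = tau_m cos P holds as
written. Phase and amplitude follow the classical five-membered-ring
pseudorotation treatment:

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))

with the quadrant fixed by the signs of numerator and nu2, making
tau_m >= 0. A ring with all |nu_j| < 1 is treated as planar and raises
an undefined-pucker error: the phase of a flat ring is meaningless and
should never be averaged into statistics.

Domain boundaries: low-syn is [300, 360); syn [0, 120), intermediate
[120, 180), anti [180, 300). Only the low-syn band is structurally
load-bearing for V-loop work (it separates the south-puckered V-loop
family from ordinary anti conformers); the remaining cuts follow common
crystallographic usage and are configurable in the analysis config.
North is P in [270, 360) u [0, 90), south the complement; conformer
labels come from the 20-sector pseudorotation wheel (18-degree sectors,
envelopes centered at 18 + 36k, so C3'-endo is centered at 18 and
C2'-endo at 162). Ensemble averages of angles use circular means to
survive the 0/360 wrap.

## Quartets, stacking and topology

A directed Hoogsteen edge A -> B exists when both d(N1_A, O6_B) and
d(N2_A, N7_B) are <= 3.5 A. The criterion is heavy-atom only so it works
on deposits without hydrogens; 3.5 A is a conventional upper bound for
N-H...O/N hydrogen-bond heavy-atom separations and is configurable. A
G-quartet is a directed 4-cycle in this graph; cycles are enumerated with
networkx, reported once in canonical rotation (starting at the lowest
(chain, seq) member), and near-duplicates sharing three or more guanines
are merged keeping the candidate with the smaller mean hydrogen-bond
distance.

Quartets are stacked along the first principal direction of their
centroids. The axis is oriented so the layer containing the 5'-most core
guanine is layer 0 ("top"); all polarity signs and tract orientations are
reported relative to this axis (an explicit axis hint can override the
orientation for frame-fixed comparisons, which the tests use). Adjacent
layer spacings outside 2.5-5.5 A raise warnings, not errors. Columns are
threaded by matching each guanine to the nearest base centroid in the
next layer (<= 5 A; an unmatched column is a topology error). Tetrad
polarity is the sign of the circulation sum over the donor->acceptor
cycle, axis . (r_i x r_{i+1}) with r the centroid-relative base
positions; adjacent layers with equal signs stack homopolar, otherwise
heteropolar.

Tracts are maximal runs of sequence-consecutive core guanines within one
column; their orientation (up = toward layer 0) is the sign of the
axis-projected displacement when it exceeds half the median layer rise,
else undefined (single-guanine tracts). Loops are the linkers between
sequence-consecutive core anchors in different columns (same-column pairs
are tract continuations):

- same layer: **lateral** (adjacent columns) or **diagonal**;
- opposite outer layers: **V-shaped** when the columns are adjacent, the
  flanking strands antiparallel, the loop has <= 2 intervening residues
  and spans >= 3 layers; **propeller** when the flanking strands are
  parallel;
- anything else (e.g. a connection ending on a middle layer, as occurs
  where a column is completed by a short filler segment): **other**.

For anchors whose own tract has no defined orientation, the dominant
orientation of their column stands in.

## V-loop subtyping

The conventional/alternative distinction is "where does the backbone
direction invert": after the loop (between the 3'-anchor and the next
core G) or within it (between the anchors). Operationally the package
projects C1' positions on the stack axis and takes three signed steps:
into the 5'-anchor (from its preceding core guanine), across the loop,
and out of the 3'-anchor. Because both anchors sit on opposite outer
layers, the V-step and the exit step always have opposite signs; the
discriminating information is the arrival at the 5'-anchor. A
near-horizontal arrival (|dz| below half the layer rise — a lateral or
diagonal, same-end step) leaves the V-jump as the first vertical
direction, so the first reversal falls after the loop: **conventional**.
A vertical arrival opposing the V-jump puts the first reversal between
the anchors: **alternative**. This operationalization reproduces the
defining phenotypes — conventional V-loops with north/north anchor sugars
and an O5'-H8 contact to the following guanine, alternative V-loops with
south/low-syn anchors, a reversed outer tetrad and no such contact — and
is exercised in both directions by the generator. If the V-step and exit
step do not oppose each other the loop is flagged inconsistent instead of
guessed. Independently, **V_R**/**V_S** records whether the two linked
outer quartets have reverse or the same polarity sign; subtype and
polarity class are independent labels and the generator produces all four
combinations.

## Base-backbone contacts

Contacts are measured from the 3'-anchor's O4', O5' (and F2'/O2' when the
chemistry provides them) to H8 of the core guanine following the anchor,
and to H8 of the 5'-anchor. The call is made on the acceptor-H8 distance
alone: present <= 3.5, absent >= 4.0, ambiguous between — the gray band
encodes the gap between reported "short" (about 3 A or below) and
"long" (above 4 A) contact classes. The acceptor-H8-C8 angle is
reported but never gates the call: these CH...O/F interactions sit near
90-105 degrees, far from linear hydrogen bonds, yet are structurally
meaningful. When a model lacks H8 it is rebuilt on the external bisector
of N7-C8-N9 at 1.08 A from C8; on fixtures with hydrogens the rebuilt
position changes contact distances by well under 0.1 A. Occupancy is the
fraction of models in which a contact is present; per-model values, mean,
min and max are reported alongside.

## Ensemble statistics and consensus

Superposition is the closed-form least-squares (Kabsch/SVD) fit with the
determinant correction enforcing a proper rotation; the tests check it to
1e-9 against an independent quaternion-eigenvalue solution. Pairwise
RMSD superposes every unordered model pair on the measured selection
(fit-on = measure-on, configurable to fit on a different selection; the
report emits both the fit-on-core and fit-on-all variants). The
core-guanine selection is derived from quartet detection, not from
hard-coded residue numbers.

Whole-ensemble topology follows NMR practice in two layers. The
consensus is computed on model-averaged coordinates (the analogue of
ensemble-averaged restraint analysis): averaging over n superposed models
shrinks iid coordinate noise by sqrt(n), which keeps hydrogen-bond edge
detection far from both failure modes (a 2.9 A built bond vs. the 3.5 A
cutoff on one side, the nearest non-partner pair at >= 4.1 A on the
other). Independently, every model is classified on its own and compared
against the consensus; disagreeing or failing models produce flags, and a
consensus supported by fewer than half the models is explicitly marked
low-confidence. At extreme noise the pipeline therefore degrades into
errors or flagged output, never silently wrong labels.

## Synthetic structures

The generator exists to give every classifier a ground-truth oracle.

- **Rings**: five atoms with C-C 1.52 / C-O 1.41 bonds are solved
  numerically (least squares over atom coordinates; bond residuals
  weighted 20, torsion residuals 1) against the cosine torsion targets
  for a requested (P, tau_m). The targets are not exactly closable, so
  the solution is a compromise: worst-case torsion error ~0.6 degrees
  and bond strain ~0.03 A over tau_m in [15, 65]; re-analysis recovers
  (P, tau_m) within 1 degree. Ten deterministic starts (five phase
  offsets, two pucker-side signs) guard against mirror-image local
  minima; tau_m = 0 produces a planar ring for exercising the
  undefined-pucker path.
- **Nucleotides**: an idealized planar guanine (or minimal thymine for
  loop residues) solved once from standard bond lengths/angles is
  attached at the requested chi; C5'/O5'/P, O3' and the chemistry
  decorations (O2'/F2' on the correct face, the locked bridge carbon) are
  placed by internal-coordinate geometry on the correct furanose face.
- **Quartets**: a 2D pose of the guanine template was solved once so that
  each base donates N1->O6 and N2->N7 at 2.9 A to its 90-degree-rotated
  neighbor with near-linear N-H...acceptor geometry; the pose is frozen
  as a constant. Reversing polarity reflects the template in-plane
  (equivalent to flipping the bases over), which reverses the
  donor->acceptor cycle while preserving distances exactly.
- **Mock quadruplexes**: core guanines are placed on a stacked scaffold
  (default rise 3.5, twist 18 per layer — chosen so that non-partner
  donor/acceptor pairs stay >= 4.1 A apart even across polarity-reversed
  layers) by superposing each built nucleotide's base onto its scaffold
  slot; loop residues are swung radially outward; the backbone is linked
  by placing each residue's P 1.6 A from the preceding O3'. Presets
  cover parallel, hybrid (propeller + 2 lateral), antiparallel (6 syn
  core guanines, reversed central tetrad), and both V-loop subtypes; the
  V-loop presets include a short filler segment completing the
  interrupted column, which necessarily enters through one non-canonical
  ("other") connection. Each of n_models (default 10, the usual size of
  a deposited NMR ensemble) receives iid Gaussian coordinate noise
  (default sigma 0.1 A) from a fixed seed; identical specs and seeds are
  bit-identical.

What the generator does **not** emulate: energy-minimized backbones (loop
and linker geometry is idealized, only the predicates the analysis reads
are guaranteed), realistic loop conformer ensembles, correlated
inter-model variation (real NMR ensembles fluctuate collectively, not as
iid atomic jitter — which makes the synthetic noise a *harder* test for
distance criteria at a given sigma), cation coordination, or
sequence-dependent structure. Passing the recovery tests therefore
demonstrates the classifiers' correctness and noise margins, not the
biological realism of the fixtures.

## Numerical choices and degenerate inputs

- Dihedral/angle routines raise on coincident or collinear points rather
  than returning arbitrary values.
- The quartet cycle search is bounded at length 4; candidate order and
  canonical rotations make detection independent of input atom/residue
  order.
- Near-horizontal backbone steps use half the median layer rise as the
  dead-band; polarity circulation sums below 1e-9 are degenerate errors.
- Superposition refuses selections with fewer than 3 atoms or collinear
  geometry (rank-deficient covariance).
- Report numbers are written at fixed precision (angles 0.1, distances
  0.01) so repeated runs are byte-identical.

## Problem sizes

The randomized recovery sweep uses 20 specs of 12-20 core guanines and
10 models each with noise sigma drawn up to 0.3 A; oracle comparisons use
100 random dihedral quadruples and 10 superpositions of 200 points.
These sizes exercise every code path while keeping the full suite and the
acceptance script in the tens of seconds.

## Known limitations

- Only G-quartets are detected; mixed or GCGC tetrads, bulges, snapback
  and duplex-quadruplex hybrids are out of scope beyond the loop rules
  above.
- The absolute polarity sign convention is package-internal (relative
  polarities are the robust observable); comparisons across programs
  should use homopolar/heteropolar labels.
- Bimolecular folds are supported in that columns may mix chains while
  tracts and loops stay chain-internal, but interlocked dimers have not
  been validated against deposited examples inside this repository.
- H8 reconstruction assumes a planar, complete five-membered base ring;
  severely distorted bases propagate into contact distances.
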