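# Methods

## Scope and model

`qsar3d` implements the ligand-based 3D-QSAR workflow for a congeneric
series: SOM dataset splitting, MCS template alignment, CoMFA/CoMSIA
interaction fields, PLS regression with leave-one-out validation,
StDev*Coeff contour maps, and DISCO-style pharmacophore elucidation with
distance-geometry validation.  The underlying assumptions are the usual
ones for field-based QSAR: all compounds bind in a common mode, so a
single rigid alignment is meaningful; activity differences are driven by
differences in the steric/electrostatic/hydrophobic/H-bond environment
sampled on a lattice around the aligned series; and a linear latent-
variable model suffices to relate those field differences to pIC50.

## Charges and logP

Partial charges are Gasteiger PEOE (iterative partial equalization of
orbital electronegativity), as implemented in RDKit.  The classic
"Gasteiger-Hückel" combination adds a Hückel π-charge correction on
conjugated systems; that correction is proprietary to Sybyl and is
omitted here.  The practical delta is a modest redistribution of charge
within aromatic systems; the electrostatic field patterns and everything
downstream are insensitive to it at the level this package tests.
Calculated logP ("ClogP" in QSAR tables) is the Crippen atom-contribution
method — deterministic, open, and playing the same role as a
whole-molecule hydrophobicity descriptor.

## Dataset splitting

A compact descriptor set (~40 columns: constitutional counts,
topological indices, logP, MR, TPSA, element counts) stands in for large
commercial descriptor suites; splitting only needs a diverse space, and
the split rules are descriptor-set-agnostic.  The SOM is a rectangular
grid (default 6×6) trained online with a Gaussian neighborhood,
learning rate decaying linearly 0.5 → 0.01 and radius max(rows, cols)/2
→ 0.5 over a fixed epoch count (default 500), weights initialized
uniformly in the per-dimension data range from a seeded generator.  No
published training schedule exists for this application; these are
ordinary Kohonen defaults, and all randomness is seed-controlled.

Test molecules are drawn per occupied neuron — ⌊occupancy/(ratio+1)⌋
seeded draws each — and any deficit against the global target
round(n/(ratio+1)) is topped up from the most populous neurons, which
always retain at least one training member.  This keeps (1) a minimum
test-set size of five, (2) every test molecule near training molecules
in descriptor space (they share or neighbor a neuron), and (3) training
coverage of the whole occupied map.  At ratio 4:1 the test fraction is
held within ±5 percentage points of 20%.

## Alignment

The maximum common substructure (element- and bond-order-preserving,
heavy atoms only — hydrogens are excluded from the fit) defines matched
atom pairs; the rigid fit is the Kabsch SVD superposition restricted to
proper rotations (determinant +1), so mirror images are never absorbed.
When molecular symmetry yields several MCS mappings, every mapping is
fitted and the lowest post-fit RMSD wins, with lexicographic
template-index order as the final deterministic tie-break.  Collinear
anchor sets are rejected (the rotation would be underdetermined).  No
torsional relaxation is performed: the package assumes conformers come
from the input or from the seeded ETKDG embedder.

## Fields

The lattice (default spacing 2.0 Å) is the smallest box holding every
aligned molecule with a ≥ 4 Å margin on all faces; all molecules share
it, and it translates rigidly with the series (no global snapping).
Lattice points iterate z-fastest, matching the OpenDX export convention;
column metadata records the (field, lattice index) of every descriptor
column.

CoMFA steric energies use a Lennard-Jones 6-12 form with a generic
element-keyed parameter table (Bondi-style radii, UFF-like well depths,
listed in `fields.VDW_PARAMS`) and an sp³-carbon probe; electrostatics
use 332·q·q_probe/r² (distance-dependent dielectric ε(r)=r).  Both are
clipped at ±30 kcal/mol.  At lattice points where a molecule's steric
energy sits at the +30 cutoff (probe inside the molecule), its
electrostatic value is replaced by the column mean over the remaining
molecules — the standard convention that keeps meaningless in-body
Coulomb values from dominating a column.

CoMSIA similarity indices are −Σ ω_probe·ω_i·exp(−α r²) with α = 0.3 Å⁻²
and probe weights +1 throughout.  Atom weights: steric r_vdW³,
electrostatic PEOE charge, hydrophobic Crippen per-atom contribution
(these sum to the molecule's logP), donor/acceptor 0/1 typing (N/O with
attached H donate; O and H-free, non-cationic N accept, excluding
substituted pyrrole-type nitrogens).  A value-clipping cut at ±0.3 is
applied at block assembly by default; the raw per-molecule fields are
never truncated, so the r = 0 value for a unit-weight atom is exactly
−1.  The clipping can be disabled (`truncate=None`) — the conventional
"0.3 contribution cut" admits more than one reading, and both are
available.

Columns with standard deviation below a per-field threshold are dropped
(conventional defaults: 2.0 kcal/mol for CoMFA, 0.01 for CoMSIA); each
surviving block is rescaled to unit total variance so every field gets
equal a-priori weight (CoMFA-standard block scaling).  ClogP, when
included, forms its own unit-variance block.

## PLS and validation

The PLS flavor is NIPALS for a single response with X-deflation;
coefficients are reported in original column units with an explicit
intercept.  The model centers X and y internally (autoscaling optional
and off by default, since block scaling already handled column weight);
inside every leave-one-out fold this centering/scaling is recomputed
from the n−1 training rows, so no information leaks from the held-out
sample.  Q² = 1 − PRESS/SD accumulates SD about each training fold's
mean.  Denominator conventions: SEP = √(PRESS/(n−c−1)) and SEE =
√(RSS/(n−c−1)) count the intercept; F uses (c, n−c−1) degrees of
freedom, consistent with SEE.  These conventions are documented rather
than tuned — printed statistics from proprietary software cannot pin
them down without the original data matrix.  OPN is the component count
maximizing Q², ties resolved toward the smaller model.  External
prediction uses R²pre = (SD − PRESS)/SD about the training mean.  Field
contributions are Σ|b|·σ per block, normalized to sum to one.  With c =
rank(X) the NIPALS solution coincides with the minimum-norm least-squares
fit, which the tests exploit for parameter recovery.

## Contours

The contour quantity is σ_col·b_col mapped back to the lattice
(filtered-out columns are zero).  The favored iso-level is chosen so the
enclosed points carry 80% of the total positive contribution mass, the
disfavored level 20% of the negative mass — contribution-mass
percentiles of the signed distribution, which is the conventional
display semantics when only the percentages are stated.  Fields export
as OpenDX text grids plus a top-k point table.

## Pharmacophores

Feature perception is rule-based and deterministic: donor atoms (N/O
with H) yield a donor-atom feature plus a donor site projected 3.00 Å
along the mean X–H axis; acceptors yield an acceptor atom plus a site
3.00 Å along the idealized lone-pair axis (opposite the mean bond
vector); aromatic rings yield an aromatic centroid, doubled with a
hydrophobic centroid when the ring is carbon-dominated (> half carbon).
The 3.00 Å site offset matches the printed site-to-atom distances of the
bundled reference pharmacophore.

Clique detection builds, per molecule and conformer, the association
graph between reference features and molecule features (same kind; every
pairwise distance difference within the tolerance) and enumerates its
maximal cliques (networkx).  Because a model common to several molecules
is an intersection of their cliques, the candidate set is closed under
pairwise intersection (and cliques above the maximum size contribute
their admissible-size subsets) before support counting; only maximal
qualifying feature subsets are emitted.  Conformers come from seeded
ETKDG embedding (up to 50), thinned to 7 by maximin RMSD diversity; a
Morgan-fingerprint Tanimoto pre-filter (default 0.85) can restrict the
molecule set to close analogues of the reference.  The model score,
SIZE·(1 − mean pairwise deviation/tolerance) averaged over matched
molecules (reference included at zero deviation), and DMEAN, the mean
pairwise matched-feature distance, are documented stand-ins — the
original scoring function is proprietary, so scores are comparable
within a run but not across programs.

Distance-geometry validation embeds a feature distance matrix in 3D:
classical metric scaling (double-centered Gram matrix, top three
eigenvectors) on a shortest-path-completed matrix provides the start,
followed by least-squares refinement over all retained pairs
(`scipy.optimize.least_squares`, tolerances 1e-15).  Leaving one pair
out and reporting its realized distance turns the embedder into an
internal-consistency check on printed pharmacophore geometries.  A
maximum residual above 1.0 Å (far beyond any tolerance used here)
raises as non-embeddable.

The bundled reference matrix is the published six-point pharmacophore of
pyridinylimidazole TNF-α release inhibitors (merged donor/acceptor
nitrogen atoms of the imidazole and pyridine rings, their projected
donor sites, two fused hydrophobic/aromatic centers; 0.25 Å tolerance).
Its source text carries two internal inconsistencies (a 16.41 Å reading
of the 6.41 Å atom–atom distance, and 5.05 Å attributed to the
ring–ring pair listed as 4.05 Å in the table); the tabulated matrix is
taken as authoritative — it is the embeddable reading — and the
embedder's leave-one-out predictions confirm it to within 0.01 Å.

## Synthetic data

The generator emulates a congeneric series: a 2-thioimidazole core
(4-pyridinyl + phenyl) with an S-substituent and a para-phenyl
substituent drawn without replacement from pools spanning alkyl, polar,
halogenated and aromatic groups, so every field block carries variance.
One seeded ETKDG conformer per molecule; alignment, grid and field
assembly run exactly as on real data.  Activities are planted as y =
6.0 + X·w + ε with w a fixed combination (weights 1, 0.5, 0.25) of the
three leading right-singular vectors of the centered descriptor matrix,
scaled so the noiseless signal has a standard deviation of 0.7 pIC50
units — the potency spread of a realistic tight congeneric series — and
ε seeded Gaussian noise.  Placing w in the row space of X makes it
exactly identifiable: at σ = 0 a full-rank PLS fit recovers it to
machine precision (cosine similarity 1), which is the module's central
guarantee, and at assay-scale noise (σ = 0.3) the cross-validated Q²
settles in the 0.8 band, between chance and perfection.  What the
generator does not emulate: conformational flexibility (one conformer),
binding-mode switches, activity cliffs from specific protein contacts,
and assay heteroscedasticity; passing recovery tests therefore validates
the numerics of the pipeline, not the biology of any particular series.

Pharmacophore toys are seeded point sets (well-separated random
geometry, or the bundled reference geometry) with rigid-motion copies
and optional Gaussian jitter; the planted common clique is known by
construction.

## Problem sizes and determinism

Tests run the pipeline at desk scale: 12- and 30-molecule series for
fit/recovery checks, a 151-molecule graph-only series for the split
contract (the SOM there uses 150 epochs — the assignment stabilizes long
before the default 500), 3-seed samples of the noisy Q² envelope, and
≤5-feature toys for exhaustive-enumeration comparisons.  Every source
of randomness (ETKDG, SOM init/shuffling, split draws, noise) is
seed-controlled; identical seeds give byte-identical outputs.

## Known limitations

* No force-field minimization or conformational search; alignment is
  rigid and conformers are ETKDG samples.
* Generic vdW parameters and PEOE-only charges: absolute field energies
  are not force-field quality; the analysis is comparative.
* Tautomer/protonation enumeration is out of scope; fixtures use neutral
  forms (the protonation state of pyridinyl/imidazole nitrogens in the
  historical series is unrecorded).
* DISCO scoring is a stand-in; ranking is internally consistent only.
* Printed model statistics of historical studies are not reproduction
  targets: they depend on unavailable structures and proprietary
  conventions.  The package's quantitative claims are the property-based
  checks in the test suite and the distance-geometry reproductions in
  `scripts/acceptance.py`.
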