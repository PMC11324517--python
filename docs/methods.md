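# Methods

This note documents the models and conventions implemented in
`bindsight`, the choices made where a measurement is conventionally
under-specified, and what the synthetic-data generators do and do not
emulate.

## Coordinate model and I/O

Structures are flat, ordered atom lists (PDB conventions, Å).  Residue
numbers are kept exactly as deposited — transporter constructs with
truncated termini conventionally retain full-length numbering, so W84
is always residue 84 and no renumbering happens on read.  Where an atom
carries alternate locations, only the blank or `A` conformer is kept:
every analysis here is single-conformer.  Hydrogens are retained on
read and excluded only where an operation is defined on heavy atoms
(contacts, ring centres of mass).

Trajectories pair one topology with per-frame coordinate arrays and are
read from multi-model PDB or a plain per-frame XYZ dialect (count line;
comment line, optionally carrying `box a b c`; one `element x y z` row
per atom).  Engine-native binary formats are out of scope; converting a
production trajectory to multi-model PDB/XYZ is left to the usual MD
tooling.  Elements missing from a file are inferred from the atom name,
with monatomic ions recognised by the PDB convention that residue name
equals atom name (so `CA` in residue `CA` is calcium, otherwise Cα).

## Superposition and helix metrics

Superposition is the closed-form least-squares (Kabsch) fit, computed
with `scipy`'s `Rotation.align_vectors`; a test cross-checks the
optimal RMSD against an exhaustive 5° rotation-grid search.  Cα pairs
across orthologues come from explicit residue-mapping tables — there is
deliberately no automatic sequence alignment in the measurement path,
so a comparison is always reproducible from its mapping file.  The
packaged `residue_mapping.csv` expresses the transporter orthologue
correspondences as per-helix constant offsets anchored on conserved
motif residues; it is a package-maintained convention that users can
replace, and `helix_ranges.csv` likewise ships conventional
transmembrane helix boundaries (helix ends are not sharply defined).

A helix axis is the first principal component of sliding 4-residue Cα
centroids.  The 4-residue window spans roughly one helical turn
(3.6 residues), so the winding largely cancels and the centroids track
the local axis; raw Cα PCA is biased by up to a few degrees at
non-integer turn counts, which matters when the reported reorientations
are themselves only 3–9°.  The axis sign points from the first to the
last residue of the range.

Two structures are compared by fitting the rigid transform on a shared
core (e.g. TM3/TM8 Cα) only, applying it to the whole mobile structure,
and then measuring, for the helix of interest:

- **displacement** — distance between helix Cα centroids.  The source
  measurements do not define "displacement"; the centroid is used here
  because it is stable to end-fraying, and rotation is captured
  separately.  Displacement is not symmetric in ref/target (the
  transform is fit one way); reorientation is.
- **reorientation** — acute angle between axis directions, folded to
  [0°, 90°] because an axis has no intrinsic sign.

Residue-pair distances support four atom rules: Cα–Cα, named atoms,
side-chain ring centroids (Phe/Tyr six-ring, Trp indole, His
imidazole), and minimum over heavy-atom pairs.  The aromatic
extracellular-gate separation is measured with the ring-centroid rule;
this is this package's convention, since the printed ~13 Å figure does
not name its atoms.

Per-atom RMSF superposes every frame onto frame 0 using a fit
selection, then takes √⟨|x−⟨x⟩|²⟩ per measured atom.  For isotropic
per-coordinate noise σ this converges to σ√3, which the tests use as a
closed-form oracle.

## Interaction criteria

- **Contacts**: a residue is in contact in a frame when *any* of its
  heavy atoms is within 4.0 Å of any ligand heavy atom; the per-residue
  probability is the fraction of frames in contact, and the *stable*
  flag applies the strict rule probability > 0.40 ("more than 40 % of
  the time"), so exactly 40 % is not stable.  Contacts never use
  hydrogens, and assume an unwrapped solute (no minimum image).
- **π-stacking**: ring centres of mass are mass-weighted over the
  listed heavy atoms (masses from the element symbol via gemmi); ring
  normals are the smallest principal component of the ring plane.  A
  frame is stacked when COM distance ≤ 5 Å *and* the acute inter-normal
  angle ≤ 45°.  Angles are folded to [0°, 90°] because plane normals
  are sign-ambiguous — any other convention would make occupancy depend
  on atom input order.  The packaged ring definitions are the
  tryptophan indole (CG, CD1, NE1, CE2, CZ2, CH2, CZ3, CE3, CD2) and
  the ligand adenine ring (N3, C4, N1, C3, C5, N4, C6, N5, C2).
- **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å and D–H–A angle
  ≥ 120°, both configurable.  These cutoffs are a common geometric
  convention, not values taken from a particular study — published
  H-bond occupancies rarely print their thresholds.  On heavy-atom-only
  topologies the hydrogen can be omitted, which disables the angle
  criterion (documented distance-only mode).
- **RDF**: minimum-image distances in an orthorhombic box, histogram
  normalised by shell volume 4πr²dr, bulk probe density N/V, reference
  count and frame count.  A uniform box then gives g(r) = 1, and
  ∫ρg(r)4πr²dr recovers the neighbour count — both are test oracles.

Occupancies are invariant under frame permutation and duplication by
construction (they are frame averages), and stacking statistics are
invariant to rigid motion of whole frames; both properties are tested.

Where a study pools several MD replicas, the 40 % stability rule can be
applied per replica or to pooled frames; this package computes per
trajectory, and pooling is a matter of concatenating frame lists (the
probability then scales as tested under frame duplication).

## Ion coordination

The shell of a bound ion is every N/O/S atom inside a per-element
distance window: Zn 1.9–2.6 Å and Na 2.2–2.9 Å by default, standard
coordination-chemistry brackets that users can reconfigure.  No
tautomer assignment is attempted for histidine — whichever imidazole
nitrogen falls inside the window is listed (in practice the distal
nitrogen is well outside it).  Shell geometry is scored against ideal
templates (trigonal planar, tetrahedral, square planar, trigonal
bipyramidal, octahedral) as the RMS deviation of ligand–ion–ligand
angles, minimised exhaustively over all ligand-to-vertex assignments
(≤ 6! = 720), which makes the score invariant to ligand input order and
rigid motion.  A square-planar shell scored against the tetrahedral
template has the closed-form deviation
√((4(109.47−90)² + 2(180−109.47)²)/6) ≈ 43.7°, used as a test oracle.

## Dose-response fitting

Models: v = Vmax·S/(Km+S); B = Bmax·L/(Kd+L);
y = 100/(1+(x/IC50)^h); y = bottom+(top−bottom)/(1+(x/IC50)^h)
(note x^h/IC50^h ≡ (x/IC50)^h).  Preprocessing subtracts the mean
background replicate and scales so the control dose (lowest
concentration by default) reads 100 %.

Concentration parameters (Km, Kd, IC50) are fitted on the log scale —
positivity is structural, not a constraint — by trust-region nonlinear
least squares with a small multi-start over the concentration
quartiles.  Fits run on replicate means by default (replicate-level
pooling available), unweighted.  Standard errors come from the Jacobian
at the optimum, delta-method-transformed back to the linear scale, and
nominal confidence intervals use the Student-t quantile at the fit's
residual degrees of freedom (with ~6 dof a normal quantile visibly
under-covers).  Monte-Carlo tests at the published assay parameters
show median relative bias below 2 % and 95 %-interval coverage within
[88 %, 98 %] over 200 seeded replicates per model.

Free-Zn²⁺ bookkeeping follows the assay's stated accounting: an
EDTA-washed zero-dose control is taken as 0 µM free Zn²⁺, and every
other condition is the added concentration plus ~100 nM ambient Zn²⁺
from the uptake buffer.  IC₅₀ fold changes between two fits propagate
uncertainty by the delta method on the ratio.

## Synthetic data

The generators define the test conditions, and their constructions are
threshold-exact rather than statistical: planted-contact trajectories
place the residue atom 1 Å inside the cutoff in exactly
round(f·n_frames) seeded-random frames and 2 Å outside it otherwise, so
a planted fraction of 0.40 vs 0.41 brackets the stability threshold
exactly; stacked-ring frames satisfy both stacking criteria with
equality-free margins, and unstacked frames violate the distance
criterion.  Dose-response noise is multiplicative Gaussian with
constant 5 % CV by default — assays of this kind report mean ± s.d.
only, so constant CV is the simulator's model — on 3 replicates over
3-fold dilution series matching the assay ranges (30→0.0137 µM uptake,
0–150 nM binding).  The fold-pair generator plants an exact
post-superposition Cα RMSD by iteratively rescaling a random
displacement field, then hides the correspondence behind a random
global rigid motion.

What the generators do **not** emulate: real force-field dynamics
(frames are independent, with no kinetics or correlations), sequence
realism, crystallographic/cryo-EM noise, or solvent structure.  Passing
tests therefore demonstrate that the measurement criteria are
implemented exactly and recover planted truth — not that any particular
biological system behaves this way.

## Problem sizes and numerics

Test and acceptance workloads are sized for interactive runs: ≤ 200
atoms for brute-force oracle comparisons, hundreds to a thousand frames
for occupancy statistics, 5 000 probe atoms × 50–80 frames for RDF
checks, and 200 seeded repeats for fit-recovery studies.  Tolerances:
rotations are validated to 1e-8 orthonormality; superposition RMSDs to
~1e-7 against floating-point noise; axis fits to 2°; statistical checks
at 2–5 % as stated per test.  Degenerate inputs (collinear point sets,
zero-variance clouds, empty selections, all-zero signals) raise
`ValueError` rather than returning silently wrong numbers.

## Known limitations

- PDB fixed-column only (no mmCIF); no bond perception or force-field
  topology.
- Contact analysis has no periodic-boundary handling; it expects an
  unwrapped solute.
- Helix ranges and cross-species mappings are shipped conventions, not
  derived from structure or sequence at run time.
- The H-bond criterion is geometric only; no energetic or
  wavefunction-based scoring.
- Coordination scoring compares to ideal polyhedra only; bond-valence
  sums and density-based validation are out of scope.
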