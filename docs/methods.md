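# Methods

## The problem and the model

A receptor that binds its ligand may pre-populate binding-competent
conformations (conformational selection) or be remodelled by the ligand
(induced fit).  The observable chain implemented here: extract the
metastable conformers of free and bound ensembles, measure how similar they
are (structure, fluctuations, surface physicochemistry), and rank the bound
conformers by interaction energetics.  High free↔bound similarity with
population shifts argues selection; divergence localised at interface
residues argues an induced component.

## Metastable-conformer extraction

Frames are featurised per level:

- **cPCA** — all selected atoms, every frame least-squares superposed
  (Kabsch, proper rotation) onto the ensemble mean structure, iterated to
  convergence of the mean (tolerance 1e-6 Å); features are the flattened
  coordinates.
- **dPCA** — selected torsions θ encoded as (sin θ, cos θ), which removes
  the ±180° discontinuity.  Torsion sets are filtered by class
  (φ/ψ/χ/ω) and owner (receptor backbone, recognition domain, ligand).

PCA is computed on the covariance matrix of mean-centred, never-scaled
features (sin/cos are already commensurate; Å are Å).  The first two
components span the essential subspace; their 2-D histogram becomes the
free-energy landscape ΔG = −kT·ln(P/P_max), so the global minimum is
exactly 0 and unoccupied bins carry a NaN sentinel, never 0.  kT defaults
to 2.494 kJ/mol (300 K) but is a free parameter — the conformer assignment
is invariant to it, only the ΔG axis changes.

k-means (k-means++ seeding, best of 10 restarts, fixed seed) separates the
subspace geometrically.  With `k='auto'` the k in {2..8} maximising the
mean silhouette is used, with a k = 1 fallback when the retained-PC
variance is below a floor (default 0.05): a flat single-basin landscape
must not be force-split.  Hierarchical refinement re-clusters every leaf of
the previous level in the next level's feature space; leaves smaller than
`min_population` (default 10) merge into the nearest sibling centroid.
Refinement-within-parents was chosen over re-clustering the union because
it guarantees nested provenance — every leaf names the path of levels that
produced it.

## Descriptors

RMSD and radius of gyration are per-frame series with mean ± sd; RMSF is
computed after superposition onto the iterated ensemble mean (the same
convention as cPCA, so fluctuations and the essential subspace refer to the
same frame); per-residue RMSF averages the residue's atoms.  SASA is
Shrake–Rupley with deterministic golden-spiral test points (no RNG; 960
points ≈ 1% accuracy on an isolated sphere), probe 1.4 Å.  The hand-rolled
implementation is cross-checked in the test suite against biotite's
independent one (2% agreement on the toy receptor).

Similarity between conformers is the standard Pearson product-moment
correlation of matched profiles.  Zero-variance profiles yield an undefined
(NaN) correlation, reported as missing rather than 0.  Profiles can be
restricted to a named residue-position map (the conserved recognition
positions) for the key-residue analysis.

## Interaction fields

All rules are geometric, inclusive, and configurable, because occurrence
heatmaps depend directly on them:

| kind        | rule (defaults) |
|-------------|-----------------|
| hydrogen bond | polar (N/O) pair ≤ 3.5 Å; if the donor has hydrogens, best D–H···A angle ≥ 120°, else distance-only fallback flagged `angle=None` |
| hydrophobic | apolar-carbon pair ≤ 4.0 Å (apolar = C with no bonded N/O/S) |
| van der Waals | distance ≤ 1.1·(r_i + r_j), excluding pairs already reported as H-bonds |
| water bridge | water O within the H-bond distance of ≥1 receptor polar atom and ≥1 ligand polar atom in the same frame |

Occurrence is the percentage of a conformer's frames with ≥ 1 record of a
kind at a residue position (records at unmapped residues land in an
"other" row with a warning).  Interaction midpoints pooled per conformer
give the MIF point clouds; centroid and rms spread quantify
cluster-to-cluster displacement.

## Binding energetics

Single-trajectory convention: receptor and ligand geometries are taken
from the complex, so intramolecular terms cancel and the MM terms reduce
to the receptor–ligand pairwise sums.  Lennard-Jones 12-6 with
Lorentz–Berthelot combination; Coulomb with k_e = 138.935458
kJ·mol⁻¹·nm·e⁻²; no cutoff (toy systems are small; a cutoff config key
exists).  Pairs closer than 0.1 Å raise a clash error naming the pair.

Polar solvation is pluggable.  The faithful route imports three OpenDX
potential grids (complex, receptor, ligand) and evaluates
E = ½·Σ qᵢφ(rᵢ) by trilinear interpolation.  The built-in stand-in is a
screened Coulomb sum with distance-dependent dielectric
ε(r) = ε_int + (ε_solv − ε_int)(1 − e^(−r/λ)), ε_int = 2.0,
ε_solv = 78.54, λ = 3 Å, minus the vacuum reference — it reproduces the
sign and saturation behaviour of a continuum model without solving the
Poisson–Boltzmann equation, and its output is always labelled approximate.
The nonpolar term is γ·SASA + b with γ = 0.0226778 kJ·mol⁻¹·Å⁻²,
b = 3.84928 kJ·mol⁻¹ (the conventional SASA-model constants;
config-overridable).  For non-contacting molecules ΔE_nonpolar = −b
exactly (areas add; one complex offset minus two component offsets).

Ensemble averaging draws min(500, n_frames) frames uniformly without
replacement under a fixed seed and reports mean ± standard error of the
mean per term.  SE (not SD, not block averages) was chosen because the
frames are drawn independently by construction here; the estimator is
labelled in the output.

## Surface topography

The accessible dot surface reuses the Shrake–Rupley retention rule with
golden-spiral points; occlusion is tested against all atoms so the buried
face of a residue subset is removed.  A true re-entrant (Connolly) surface
is not computed — the accessible surface is the documented stand-in.

MHP follows MLP(r) = Σᵢ fᵢ·e^(−|r−rᵢ|²) with d in Å exactly as printed in
the source method, with no length-scale constant.  At solvent-accessible
distances (≈3 Å from the parent atom) the kernel is ≈e^(−9), so absolute
map values are small (≈1e-4 for the toys) and differ from pyMLP's; only
relative patterns between maps produced by the same kernel are compared,
which is what the Pearson map statistic does.  An alternative kernel is a
config hook.  MEP comes either from an imported grid or from the
approximate Coulomb sum with effective dielectric 78.54.

Spherical projection: latitude = arcsin(z/|r|); longitude uses the
two-argument arctangent (a single-argument arctan cannot cover
(−180°, 180°]).  The sphere centre is the geometric centre of the surface
points, not the centre of mass.  Interpolation onto the 181 × 361 1°-step
grid is nearest-neighbour/inverse-distance weighting (power 2, 6
neighbours) in the great-circle metric, so the ±180° seam is continuous by
construction; nodes farther than 10° from any sample are masked.  The
scheme recovers a smooth analytic field sampled at 2° with max error
≤ 0.02.  The Mollweide forward transform solves
2θ + sin 2θ = π·sin φ by Newton iteration (tolerance 1e-12, poles closed
form); the projection is exactly equal-area, verified numerically to 0.5%
at 1° resolution, and round-trips through the inverse within 1e-6° off the
poles.

## The synthetic world

Generators are pure functions of their arguments (seed included).

- **Receptor** — a chain of pseudo-residues (N, CA, C, O + one sidechain
  atom), built by NeRF internal-coordinate placement with ideal bond
  lengths/angles; backbone φ/ψ are the mobile torsions.  Residue types
  cycle through aromatic / apolar / polar so interaction detection has
  positives.  Charges come from a built-in synthetic table whose
  per-residue sums are zero — the net charge is an integer by
  construction.  The table is a plausible-magnitude stand-in, **not** a
  force field.
- **Ligand** — planar hexagonal pseudo-sugar rings with two hydroxyl-like
  oxygens and an exocyclic apolar carbon each, attached in a binary-tree
  (branched) topology through φ/ψ glycosidic-like linkage torsions; n rings
  carry n−1 torsion pairs.
- **Complex** — the ligand is rigidly docked at the most surface-exposed
  polar sidechain; a deterministic orientation scan maximises polar (and,
  secondarily, apolar) contacts subject to a ≥ 2.6 Å clearance.  The
  merged internal-coordinate template roots the ligand on the anchor
  residue, so complex trajectories remain rebuildable from torsions.
  Depending on the seed, the selected pocket can be purely polar — a zero
  hydrophobic-occurrence row is then an honest output, not a failure.
- **Trajectories** — each frame's state is drawn categorically by weight;
  mobile torsions are drawn from independent von Mises distributions
  (the circular analogue of harmonic fluctuation about a metastable mean;
  `concentration=inf` means the exact mean), coordinates are rebuilt from
  the template and jittered isotropically (default 0.05 Å).  The pipeline
  plants states on a torsion window chosen by a dual screen (a short probe
  trajectory under the full fluctuation model plus ±3σ corner excursions)
  so transient frames stay clash-free; its default concentration is 800
  (σ ≈ 2°), the stiffness of a folded, docked complex — the
  planted-recoverability tests use the looser κ = 100 on the free
  receptor, where no interface exists.
- **Water bridges** — water oxygens at the midpoint of receptor/ligand
  polar pairs with gap ∈ [4.8, 7.0] Å, hydrogens pointing at each partner,
  so each planted water satisfies the bridge rule by construction.

What the toys do **not** emulate: force-field energetics, solvation
shells, excluded-volume dynamics, correlated torsion motion, realistic
glycan ring puckering.  A green pipeline therefore establishes that the
*analysis chain* is correct against planted truth and closed forms — it
says nothing about any real lectin.

## Numerical choices

- Dihedral convention: signed IUPAC, range [−180°, 180°), syn = 0,
  anti mapped to −180.  Degenerate (colinear) quadruples are flagged
  per-frame, not fatal.
- Kabsch reflections corrected by flipping the smallest singular
  direction; superposition targets are iterated means (tolerance 1e-6 Å).
- k-means determinism: fixed seed + fixed restarts ⇒ identical labels;
  all pipeline stages derive their seeds from one global seed by hashing
  the stage name, so changing one stage's seed leaves the others alone.
- CSV artifacts are written with fixed float formatting (`%.10g`), which
  is what makes identical-seed runs byte-identical.

## Known limitations

- The screened-dielectric polar term is a labelled approximation; only the
  OpenDX import path is faithful to a continuum-electrostatics workflow.
- The hierarchy's refinement order and small-leaf merge rule are this
  package's choices; other reasonable definitions of "hierarchical
  sampling" exist and would partition borderline frames differently.
- Hydrogen-free structures use the distance-only H-bond fallback; angle
  filtering activates only when hydrogens are present (waters, here).
- Binding energies of the toys are not comparable to any published value;
  only their internal decomposition, additivity and sampling behaviour are
  meaningful.
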