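# confrec

Conformational-recognition analysis for receptor–ligand ensembles: does a
receptor select a binding-competent conformation from a pre-existing
ensemble, does the ligand induce one, or both?  `confrec` implements the
full analysis chain used to ask that question of lectin–glycan systems —
here exercised on deterministic synthetic toys with planted ground truth, so
every stage is verifiable without molecular-dynamics runs or downloads.

The pipeline:

1. **Metastable-conformer extraction** — trajectory frames are featurised
   either as superposed Cartesian coordinates (cPCA) or as sin/cos-encoded
   torsions (dPCA over backbone / recognition-domain / ligand selections),
   reduced by covariance PCA, binned into a 2-D free-energy landscape
   ΔG = −kT·ln(P/P_max) over (PC1, PC2), and separated geometrically by
   k-means (k fixed or chosen by silhouette).  Levels refine hierarchically;
   the leaves are the metastable conformers with their populations.
2. **Ensemble descriptors** — per-frame RMSD (Kabsch superposition) and
   radius of gyration; per-residue RMSF about the iterated ensemble-mean
   structure and Shrake–Rupley SASA; conformer-to-conformer similarity as
   Pearson correlation matrices of these profiles.
3. **Interaction fields** — geometric detection of hydrogen bonds
   (≤ 3.5 Å, donor–H···acceptor ≥ 120° when hydrogens exist), hydrophobic
   contacts (apolar C···C ≤ 4.0 Å), van der Waals contacts
   (≤ 1.1·(r_i + r_j)) and water bridges (a water oxygen within H-bond
   distance of both sides at once); per-conformer percentage-occurrence
   matrices over named residue positions and 3-D interaction point clouds.
4. **Binding energetics** — single-trajectory mmPBSA-style decomposition,
   ΔE_bind = ΔE_vdW + ΔE_elec + ΔE_polar + ΔE_nonpolar (entropy excluded),
   averaged over up to 500 frames drawn randomly per conformer.  The polar
   term either consumes imported OpenDX potential grids (½·Σ qᵢφ(rᵢ)) or
   uses a built-in screened-Coulomb distance-dependent-dielectric stand-in,
   always labelled approximate.  Nonpolar: γ·SASA + b.
5. **Protein surface topography** — MEP and MHP
   (MLP(r) = Σᵢ fᵢ·e^(−|r−rᵢ|²)) evaluated on the accessible dot surface,
   projected onto a sphere (latitude = arcsin(z/|r|), longitude =
   atan2(y, x)), interpolated on the 1° equal-area grid and rendered in
   Mollweide projection; maps compared by Pearson correlation over
   co-occupied nodes.

The synthetic-data module builds pseudo-peptide receptors, branched
pseudo-sugar ligands and docked complexes from ideal internal geometry, and
samples trajectories from mixtures of von Mises states on the mobile
torsions — so clustering, populations and water-bridge detection can be
checked against the planted truth exactly.

## Worked example

The numbered scripts under `analysis/` run the whole study on the shared
synthetic world (12-residue receptor, 3-ring ligand, 3 planted states with
weights 0.5/0.33/0.17, 600 frames, seed 2025) and write tables under
`results/`.  Running them in order prints, among other things:

```
free:  3 conformers, populations [293, 91, 216], ARI vs truth = 1.000
bound: 3 conformers, populations [283, 105, 212], ARI vs truth = 1.000

RMSF similarity: off-diagonal r in [0.78, 1.00]
SASA similarity: off-diagonal r in [0.85, 0.99]

conformer 1 (n=105): vdW 21.83±0.99  elec 43.66±0.40  polar -42.57±0.39
                     SASA -7.00±0.01  ΔG_bind 15.93±0.99
most favourable conformer: 1 (15.93 kJ/mol)

MEP: free-vs-bound map correlations r in [0.73, 0.88]
```

Reading: the hierarchy recovers exactly the three planted metastable states
(adjusted Rand index 1.0) and their populations; conformers of the free and
bound forms stay highly similar in SASA (r 0.85–0.99) while residue
fluctuations diverge more — the signature that distinguishes conformational
selection from induced fit; the binding-energy table ranks conformers by
affinity; and the topography maps quantify how much the bound surface
landscape still resembles the free one.

A CLI mirrors the stages (`confrec run --config run.cfg`, plus
`simulate | cluster | describe | energy`); `confrec run` executes the whole
pipeline from a sectioned key=value config and writes a manifest with the
config hash, so identical seeds give byte-identical CSV artifacts.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch —
synthesis, hierarchical conformer extraction, descriptors, interaction
fields, ensemble binding energies and topography maps — under the given
seed and writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Pipeline artifacts land next to the JSON under `pipeline_run/`.

## Layout

```
src/confrec/        library: structure_io, synthetic_data, conformer_sampling,
                    ensemble_descriptors, interaction_fields,
                    binding_energetics, surface_topography, pipeline, cli
analysis/           numbered narrative drivers over the library
results/            tables written by the analysis scripts
tests/              pytest suite (incl. property-based acceptance tests)
docs/methods.md     models, assumptions, parameters, limitations
```
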