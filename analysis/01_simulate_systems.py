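"""Build the toy receptor, glycan-like ligand and their docked complex, and
sample metastable trajectories with planted ground truth.

Writes: results/systems_summary.csv, results/truth_{free,bound}.txt and
reference structures under results/; full multi-model trajectories go to
scratch/ (they are bulky, regeneratable artifacts)."""

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, SCRATCH, build_trajectories, ensure_dirs
from confrec.structure_io import write_pdb, write_pqr
from confrec.synthetic_data import write_truth_labels

ensure_dirs()
receptor, ligand, complx, trajs, truths = build_trajectories()

rows = []
for tag, system in (("receptor", receptor), ("ligand", ligand),
                    ("complex", complx)):
    rows.append({
        "system": tag,
        "n_atoms": system.n_atoms,
        "n_residues": len(system.residue_keys()),
        "net_charge_e": round(system.net_charge, 6),
        "n_mobile_torsions": len(system.mobile_torsions),
    })
    write_pdb(RESULTS / f"structure_{tag}.pdb", system)
    write_pqr(RESULTS / f"structure_{tag}.pqr", system)
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "systems_summary.csv", index=False)

for tag in ("free", "bound"):
    write_truth_labels(RESULTS / f"truth_{tag}.txt", truths[tag])
    write_pdb(SCRATCH / f"traj_{tag}.pdb", trajs[tag].system, trajs[tag])

rec = complx.atom_indices("receptor")
lig = complx.atom_indices("ligand")
d = np.linalg.norm(complx.coords[rec][:, None] - complx.coords[lig][None], axis=2)
print(summary.to_string(index=False))
print(f"\ndocked pose: closest receptor-ligand approach {d.min():.2f} Å")
for tag in ("free", "bound"):
    frac = np.bincount(truths[tag].frame_labels) / CONFIG.n_frames
    print(f"{tag}: {CONFIG.n_frames} frames, planted state fractions "
          f"{np.round(frac, 3).tolist()}")
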