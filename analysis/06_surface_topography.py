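"""Protein surface topography: MEP and MHP evaluated on the accessible dot
surface of each conformer's representative structure, interpolated onto the
1° equal-area spherical grid and rendered in Mollweide projection.

Writes: results/topography_summary.csv, results/topography_similarity.csv;
Mollweide images under scratch/figures/."""

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, SCRATCH, build_trajectories, ensure_dirs
from confrec import conformer_sampling as cs
from confrec import surface_topography as topo
from confrec.pipeline import _parse_levels, select_representatives, stage_seed

ensure_dirs()
receptor, _, _, trajs, _ = build_trajectories()
crd_keys = receptor.residue_keys()

maps = {}
for tag in ("free", "bound"):
    traj = trajs[tag]
    levels = _parse_levels(CONFIG.levels, has_ligand=(tag == "bound"))
    ens = cs.hierarchical_sample(traj, levels,
                                 seed=stage_seed(CONFIG.seed, f"cluster:{tag}"),
                                 min_population=CONFIG.min_population)
    feats = cs.encode_circular(cs.compute_dihedrals(traj))
    proj = cs.run_pca(feats, 2)
    for cid, frames in sorted(ens.members.items()):
        reps = select_representatives(
            frames, proj.projections[np.asarray(frames, int)],
            n_random=CONFIG.n_representatives,
            seed=stage_seed(CONFIG.seed, f"reps:{tag}:{cid}"))
        coords = traj.coords[int(reps[0])]
        surface = topo.dot_surface(traj.system, residue_subset=crd_keys,
                                   probe_radius=CONFIG.probe_radius,
                                   points_per_atom=CONFIG.points_per_atom,
                                   coords=coords)
        lat, lon, centre = topo.spherical_project(surface.points)
        for prop, vals in (
            ("MEP", topo.mep_at_points(surface.points, traj.system, coords=coords)),
            ("MHP", topo.mhp_at_points(surface.points, traj.system, coords=coords)),
        ):
            tmap = topo.interpolate_equal_area_grid(
                lat, lon, vals, property_name=prop, centre=centre,
                mask_radius_deg=CONFIG.mask_radius_deg)
            maps[(tag, cid, prop)] = tmap
            topo.render_mollweide(
                tmap, path=SCRATCH / "figures" / f"pst_{prop}_{tag}_c{cid}.png")

summary = pd.DataFrame([
    {"system": tag, "conformer": cid, "property": prop,
     "occupied_nodes": int((~m.mask).sum()),
     "mean": float(np.nanmean(m.values)),
     "min": float(np.nanmin(m.values)), "max": float(np.nanmax(m.values))}
    for (tag, cid, prop), m in maps.items()
])
summary.to_csv(RESULTS / "topography_summary.csv", index=False)
print(summary.round(3).to_string(index=False))

rows = []
keys = sorted(maps, key=str)
for i, ka in enumerate(keys):
    for kb in keys[i + 1:]:
        if ka[2] != kb[2]:
            continue
        rows.append({"property": ka[2], "map_a": f"{ka[0]}_c{ka[1]}",
                     "map_b": f"{kb[0]}_c{kb[1]}",
                     "pearson_r": topo.map_similarity(maps[ka], maps[kb])})
sim = pd.DataFrame(rows)
sim.to_csv(RESULTS / "topography_similarity.csv", index=False)
for prop in ("MEP", "MHP"):
    sub = sim[sim["property"] == prop]
    fb = sub[sub["map_a"].str.startswith("bound") != sub["map_b"].str.startswith("bound")]
    print(f"\n{prop}: free-vs-bound map correlations r in "
          f"[{fb['pearson_r'].min():.2f}, {fb['pearson_r'].max():.2f}]")
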