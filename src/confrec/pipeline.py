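"""End-to-end orchestration: synthetic (or user) trajectories in, conformer
populations, descriptor similarity, interaction occurrence, binding-energy
tables and topography maps out, under one global seed.

Every stage writes plain CSV (fixed float formatting, so identical seeds
give byte-identical artifacts); the manifest records every artifact with the
config hash and the per-stage seeds.  One global seed is expanded
deterministically into per-stage seeds, so changing one stage's seed does
not shift the others.
"""

from __future__ import annotations

import configparser
import itertools
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_energetics as energy
from . import conformer_sampling as sampling
from . import ensemble_descriptors as desc
from . import interaction_fields as mif
from . import surface_topography as topo
from . import synthetic_data as synth
from .structure_io import ResiduePositionMap, write_pdb

__all__ = ["RunConfig", "run_pipeline", "select_representatives", "stage_seed"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    # synthetic world
    n_residues: int = 12
    n_units: int = 3
    n_states: int = 3
    n_frames: int = 600
    noise_sd: float = 0.05
    concentration: float = 800.0
    separation: float = 90.0
    weights: tuple | None = None
    n_waters: int = 2
    # clustering
    levels: str = "dihedral:auto"
    min_population: int = 10
    kT: float = sampling.KT_300K
    n_bins: int = 32
    # interactions
    d_hbond: float = 3.5
    d_hydrophobic: float = 4.0
    vdw_scale: float = 1.1
    # energy
    n_energy_samples: int = 500
    polar_method: str = "screened"
    sasa_points: int = 120
    # topography
    points_per_atom: int = 120
    probe_radius: float = 1.4
    mask_radius_deg: float = 10.0
    n_representatives: int = 3
    # run
    seed: int = 0
    outdir: str = "confrec_run"
    write_trajectories: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Sectioned key=value config; unknown keys are rejected."""
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(path)
        known = {f.name for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for section in parser.sections():
            for key, val in parser.items(section):
                if key not in known:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                default = getattr(cls, key)
                if key == "weights":
                    kwargs[key] = tuple(float(v) for v in val.split(","))
                elif isinstance(default, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(val)
                elif isinstance(default, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def select_representatives(frame_indices, projection_coords, n_random: int = 3,
                           seed: int = 0):
    """Centroid-nearest frame plus ``n_random`` uniform draws without
    replacement; if the cluster is smaller than requested, all frames."""
    frames = np.asarray(frame_indices, int)
    X = np.asarray(projection_coords, float)
    if frames.size == 0:
        raise ValueError("empty cluster")
    centroid = X.mean(axis=0)
    nearest = frames[int(np.argmin(np.linalg.norm(X - centroid, axis=1)))]
    rng = np.random.default_rng(seed)
    pool = frames[frames != nearest]
    if pool.size < n_random:
        warnings.warn("cluster smaller than requested representative count")
        chosen = pool
    else:
        chosen = rng.choice(pool, size=n_random, replace=False)
    return np.concatenate([[nearest], np.sort(chosen)])


def _parse_levels(spec: str, has_ligand: bool):
    """'cartesian:auto,dihedral:3,dihedral[ligand]:auto' → LevelSpec list."""
    levels = []
    for part in spec.split(","):
        part = part.strip()
        src, _, kspec = part.partition(":")
        segment = None
        if "[" in src:
            src, _, seg = src.partition("[")
            segment = seg.rstrip("]")
        if segment == "ligand" and not has_ligand:
            continue
        k = "auto" if (not kspec or kspec == "auto") else int(kspec)
        levels.append(sampling.LevelSpec(source=src, k=k, segment=segment))
    if not levels:
        raise ValueError(f"no usable levels in {spec!r}")
    return levels


def _state_specs(system, cfg: RunConfig):
    """Plant n_states metastable states on the leading mobile torsions."""
    base = {}
    for entry in system.zmatrix:
        if entry.torsion_name is not None:
            base[entry.torsion_name] = entry.torsion
    names = system.mobile_torsions
    ref = np.array([base[n] for n in names])
    if cfg.weights is not None:
        weights = np.asarray(cfg.weights, float)
        if len(weights) != cfg.n_states:
            raise ValueError("weights length must equal n_states")
    else:
        weights = np.arange(cfg.n_states, 0, -1, dtype=float)
    weights = weights / weights.sum()
    # plant the states on a window of mobile torsions, scanning from the
    # chain/ligand periphery inward for a window whose state means keep the
    # receptor-ligand interface clash-free (the pose stays "bound")
    moved = min(3, len(names))
    rec = system.atom_indices("receptor")
    lig = system.atom_indices("ligand")

    def build(window_start):
        specs = []
        sl = slice(window_start, window_start + moved)
        for s in range(cfg.n_states):
            means = ref.copy()
            means[sl] = means[sl] + s * cfg.separation
            specs.append(synth.StateSpec(
                mean_dihedrals=tuple(synth.wrap_degrees(means)),
                concentration=cfg.concentration,
                weight=float(weights[s]),
            ))
        return specs

    if lig.size == 0:
        return build(len(names) - moved)

    # probe each candidate window two ways, scanning from the periphery
    # inward: (a) a short trajectory under the real fluctuation model (every
    # torsion wobbles) and (b) ±3σ corner excursions of the planted torsions
    # around each state mean; the window must keep the receptor-ligand
    # interface clash-free in both
    def probe_interface(specs):
        probe, _ = synth.sample_metastable_trajectory(
            system, specs, n_frames=40, noise_sd=cfg.noise_sd,
            seed=stage_seed(cfg.seed, "window-probe"),
        )
        d = np.linalg.norm(
            probe.coords[:, rec][:, :, None, :] - probe.coords[:, lig][:, None, :, :],
            axis=3,
        )
        return float(d.min())

    dev = np.degrees(3.0 / np.sqrt(cfg.concentration))
    corners = [np.array(c) for c in itertools.product((-dev, 0.0, dev), repeat=moved)]

    def corner_interface(specs, window_start):
        sl = slice(window_start, window_start + moved)
        worst = np.inf
        for spec in specs:
            means = np.array(spec.mean_dihedrals)
            for corner in corners:
                p = means.copy()
                p[sl] = synth.wrap_degrees(p[sl] + corner)
                coords = system.rebuild_coords(dict(zip(names, p)))
                d = np.linalg.norm(
                    coords[rec][:, None, :] - coords[lig][None, :, :], axis=2
                )
                worst = min(worst, float(d.min()))
        return worst

    best_specs, best_worst = None, -np.inf
    for start in range(len(names) - moved, -1, -1):
        specs = build(start)
        worst = min(probe_interface(specs), corner_interface(specs, start))
        if worst >= 2.1:
            return specs
        if worst > best_worst:
            best_specs, best_worst = specs, worst
    warnings.warn(
        f"no clash-free torsion window found; worst interface {best_worst:.2f} Å"
    )
    return best_specs


def _write_csv(df: pd.DataFrame, path: Path, manifest, tag):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    manifest["artifacts"].append({"tag": tag, "path": path.name})


def _cluster_system(tag, traj, cfg, levels, outdir, manifest):
    ens = sampling.hierarchical_sample(
        traj, levels, seed=stage_seed(cfg.seed, f"cluster:{tag}"),
        min_population=cfg.min_population,
    )
    pops = pd.DataFrame({
        "conformer": sorted(ens.members),
        "population": [len(ens.members[c]) for c in sorted(ens.members)],
        "fraction": [len(ens.members[c]) / traj.n_frames for c in sorted(ens.members)],
        "provenance": [ens.provenance[c] for c in sorted(ens.members)],
    })
    _write_csv(pops, outdir / f"populations_{tag}.csv", manifest, f"populations:{tag}")
    frames = pd.DataFrame({
        "frame": np.concatenate([ens.members[c] for c in sorted(ens.members)]),
        "conformer": np.concatenate(
            [np.full(len(ens.members[c]), c) for c in sorted(ens.members)]
        ),
    }).sort_values("frame")
    _write_csv(frames, outdir / f"conformer_frames_{tag}.csv", manifest, f"frames:{tag}")
    # FEL on the first level's feature space, for the record
    feats = sampling._level_features(traj, levels[0], 1)
    proj = sampling.run_pca(feats, min(2, feats.values.shape[1], traj.n_frames - 1))
    if proj.projections.shape[1] >= 2:
        fel = sampling.free_energy_surface(proj, n_bins=cfg.n_bins, kT=cfg.kT)
        ix, iy = np.nonzero(np.ones_like(fel.probability, dtype=bool))
        fel_df = pd.DataFrame({
            "bin_x": ix, "bin_y": iy,
            "probability": fel.probability[ix, iy],
            "delta_g": fel.delta_g[ix, iy],
        })
        _write_csv(fel_df, outdir / f"fel_{tag}.csv", manifest, f"fel:{tag}")
    return ens, proj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study on the synthetic world; returns the manifest."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.digest(), "seed": cfg.seed, "artifacts": [],
                "stages": []}
    try:
        _run_stages(cfg, outdir, manifest)
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_stages(cfg: RunConfig, outdir: Path, manifest: dict):
    # (1) synthesize systems and trajectories
    manifest["stages"].append("synthesize")
    receptor = synth.make_toy_receptor(cfg.n_residues, stage_seed(cfg.seed, "receptor"))
    ligand = synth.make_toy_ligand(cfg.n_units, stage_seed(cfg.seed, "ligand"))
    complx = synth.make_toy_complex(receptor, ligand)
    trajs, truths = {}, {}
    for tag, system in (("free", receptor), ("bound", complx)):
        states = _state_specs(system, cfg)
        traj, truth = synth.sample_metastable_trajectory(
            system, states, cfg.n_frames, cfg.noise_sd,
            stage_seed(cfg.seed, f"traj:{tag}"),
        )
        trajs[tag], truths[tag] = traj, truth
        synth.write_truth_labels(outdir / f"truth_{tag}.txt", truth)
        manifest["artifacts"].append({"tag": f"truth:{tag}", "path": f"truth_{tag}.txt"})
        if cfg.write_trajectories:
            write_pdb(outdir / f"traj_{tag}.pdb", system, traj)
            manifest["artifacts"].append({"tag": f"traj:{tag}", "path": f"traj_{tag}.pdb"})

    # (2) hierarchical conformer extraction
    manifest["stages"].append("cluster")
    ensembles, projections = {}, {}
    for tag, traj in trajs.items():
        levels = _parse_levels(cfg.levels, has_ligand=(tag == "bound"))
        ensembles[tag], projections[tag] = _cluster_system(
            tag, traj, cfg, levels, outdir, manifest
        )
    subtrajs = {
        tag: sampling.extract_subtrajectories(trajs[tag], ensembles[tag])
        for tag in trajs
    }

    # (3) descriptors + similarity between free and bound conformers
    manifest["stages"].append("descriptors")
    receptor_atoms = receptor.atom_indices("receptor")
    profiles, labels, rows = [], [], []
    for tag in ("free", "bound"):
        sel = trajs[tag].system.atom_indices("receptor")
        for cid, sub in subtrajs[tag].items():
            r = desc.rmsd_series(sub, selection=sel)
            g = desc.radius_of_gyration(sub, selection=sel)
            rows.append({"system": tag, "conformer": cid, "n_frames": sub.n_frames,
                         "rmsd_mean": r.mean, "rmsd_sd": r.sd,
                         "rg_mean": g.mean, "rg_sd": g.sd})
            if sub.n_frames >= 2:
                prof = desc.rmsf(sub, selection=sel)
                profiles.append(prof)
                labels.append(f"{tag}_c{cid}")
    _write_csv(pd.DataFrame(rows), outdir / "descriptors.csv", manifest, "descriptors")
    if len(profiles) >= 2:
        sim = desc.pearson_similarity(profiles, labels=labels)
        sim_df = pd.DataFrame(sim.matrix, columns=sim.labels)
        sim_df.insert(0, "conformer", sim.labels)
        _write_csv(sim_df, outdir / "similarity_rmsf.csv", manifest, "similarity:rmsf")

    # (4) interaction fields + water bridges (complex only)
    manifest["stages"].append("interactions")
    params = mif.InteractionParams(d_hbond=cfg.d_hbond,
                                   d_hydrophobic=cfg.d_hydrophobic,
                                   vdw_scale=cfg.vdw_scale)
    rp_labels = [f"RP{i + 1}" for i in range(len(receptor.residue_keys()))]
    rp_map = ResiduePositionMap(
        labels=rp_labels,
        mapping={lab: key for lab, key in zip(rp_labels, receptor.residue_keys())},
    )
    records = mif.detect_over_trajectory(trajs["bound"], params=params)
    for kind in mif.KINDS:
        occ = mif.occurrence_matrix(records, ensembles["bound"], rp_map,
                                    trajs["bound"].system, kind)
        occ_df = pd.DataFrame(occ.values,
                              columns=[f"conformer_{c}" for c in occ.conformer_ids])
        occ_df.insert(0, "position", occ.row_labels)
        _write_csv(occ_df, outdir / f"occurrence_{kind}.csv", manifest,
                   f"occurrence:{kind}")
    watered = synth.add_water_bridges(complx, cfg.n_waters,
                                      stage_seed(cfg.seed, "waters"))
    bridges = mif.detect_water_bridges(watered, params=params)
    bridge_df = pd.DataFrame([
        {"water": r.water, "receptor_atom": r.receptor_atom,
         "ligand_atom": r.ligand_atom, "mean_distance": r.distance}
        for r in bridges
    ])
    _write_csv(bridge_df, outdir / "water_bridges.csv", manifest, "water_bridges")

    # (5) ensemble binding energies per bound conformer
    manifest["stages"].append("energetics")
    erows = []
    for cid, sub in subtrajs["bound"].items():
        bd = energy.ensemble_binding_energy(
            sub, n_samples=cfg.n_energy_samples,
            seed=stage_seed(cfg.seed, f"energy:{cid}"),
            polar_method=cfg.polar_method, sasa_points=cfg.sasa_points,
        )
        erows.append({
            "conformer": cid, "n_samples": bd.n_samples,
            "e_vdw": bd.e_vdw, "se_vdw": bd.se_vdw,
            "e_elec": bd.e_elec, "se_elec": bd.se_elec,
            "e_polar": bd.e_polar, "se_polar": bd.se_polar,
            "e_nonpolar": bd.e_nonpolar, "se_nonpolar": bd.se_nonpolar,
            "e_bind": bd.e_bind, "se_bind": bd.se_bind,
            "polar_method": bd.polar_method,
        })
    _write_csv(pd.DataFrame(erows), outdir / "binding_energies.csv", manifest,
               "binding_energies")

    # (6) representatives + topography maps
    manifest["stages"].append("topography")
    maps = {}
    for tag in ("free", "bound"):
        system = trajs[tag].system
        crd_keys = receptor.residue_keys()
        for cid, sub in subtrajs[tag].items():
            frames = ensembles[tag].members[cid]
            proj_rows = projections[tag].projections[np.asarray(frames, int)]
            reps = select_representatives(
                frames, proj_rows, n_random=cfg.n_representatives,
                seed=stage_seed(cfg.seed, f"reps:{tag}:{cid}"),
            )
            rep = int(reps[0])  # centroid-nearest structure carries the map
            coords = trajs[tag].coords[rep]
            surface = topo.dot_surface(system, residue_subset=crd_keys,
                                       probe_radius=cfg.probe_radius,
                                       points_per_atom=cfg.points_per_atom,
                                       coords=coords)
            lat, lon, centre = topo.spherical_project(surface.points)
            for prop, evaluate in (
                ("MEP", lambda p: topo.mep_at_points(p, system, coords=coords)),
                ("MHP", lambda p: topo.mhp_at_points(p, system, coords=coords)),
            ):
                vals = evaluate(surface.points)
                tmap = topo.interpolate_equal_area_grid(
                    lat, lon, vals, property_name=prop, centre=centre,
                    mask_radius_deg=cfg.mask_radius_deg,
                )
                maps[(tag, cid, prop)] = tmap
    summary = pd.DataFrame([
        {"system": tag, "conformer": cid, "property": prop,
         "n_nodes": int((~m.mask).sum()),
         "value_mean": float(np.nanmean(m.values)),
         "value_min": float(np.nanmin(m.values)),
         "value_max": float(np.nanmax(m.values))}
        for (tag, cid, prop), m in maps.items()
    ])
    _write_csv(summary, outdir / "topography_summary.csv", manifest, "topography")
    sim_rows = []
    keys = sorted(maps, key=str)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka[2] != kb[2]:
                continue
            r = topo.map_similarity(maps[ka], maps[kb])
            sim_rows.append({"property": ka[2],
                             "map_a": f"{ka[0]}_c{ka[1]}", "map_b": f"{kb[0]}_c{kb[1]}",
                             "pearson_r": r})
    _write_csv(pd.DataFrame(sim_rows), outdir / "topography_similarity.csv",
               manifest, "topography_similarity")
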