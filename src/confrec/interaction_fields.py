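"""Geometric detection of noncovalent receptor–ligand interactions.

Hydrogen bonds, hydrophobic contacts and van der Waals contacts are found by
distance (and, when hydrogens exist, donor–H···acceptor angle) rules over
every receptor–ligand atom pair; water bridges are waters whose oxygen
satisfies the H-bond distance rule with both sides at once.  Occurrence
matrices report, per conformer and conserved residue position, the
percentage of frames with at least one interaction of a kind — the
ensemble-level interaction fingerprint.  All cutoffs are inclusive and
configurable, since occurrence heatmaps depend directly on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conformer_sampling import ConformerEnsemble
from .structure_io import MolecularSystem, ResiduePositionMap

__all__ = [
    "InteractionParams",
    "InteractionRecord",
    "OccurrenceMatrix",
    "PointCloud",
    "detect_contacts",
    "detect_water_bridges",
    "detect_over_trajectory",
    "occurrence_matrix",
    "mif_point_cloud",
]

KINDS = ("hbond", "hydrophobic", "vdw")


@dataclass(frozen=True)
class InteractionParams:
    """Detection thresholds (Å / degrees); every rule is inclusive."""

    d_hbond: float = 3.5
    angle_hbond: float = 120.0
    d_hydrophobic: float = 4.0
    vdw_scale: float = 1.1


@dataclass(frozen=True)
class InteractionRecord:
    frame: int
    kind: str
    receptor_atom: int
    ligand_atom: int
    distance: float
    midpoint: tuple
    angle: float | None = None  # hbond only; None = distance-only fallback
    water: int | None = None  # bridging water oxygen (water_bridge only)

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")
        if self.angle is not None and not 0 <= self.angle <= 180:
            raise ValueError("hbond angle must lie in [0, 180]")
        if self.kind == "water_bridge" and self.water is None:
            raise ValueError("water_bridge records need a bridging water id")
        if self.kind != "water_bridge" and self.water is not None:
            raise ValueError("only water_bridge records carry a water id")


@dataclass
class OccurrenceMatrix:
    """residue-position × conformer percentage occurrence of one kind."""

    kind: str
    row_labels: list[str]
    conformer_ids: list[int]
    values: np.ndarray  # percent, [0, 100]

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if np.any(v < 0) or np.any(v > 100):
            raise ValueError("occurrence percentages must lie in [0, 100]")
        self.values = v


@dataclass
class PointCloud:
    kind: str
    points: np.ndarray  # (n, 3) interaction midpoints
    centroid: np.ndarray
    spread: float  # rms distance to the centroid
    by_conformer: dict = field(default_factory=dict)  # cid -> (centroid, spread, n)


def _bonded_hydrogens(system: MolecularSystem):
    """heavy-atom index -> list of bonded hydrogen indices."""
    out: dict[int, list[int]] = {}
    for i, j in system.bonds:
        if system.element[i] == "H" and system.element[j] != "H":
            out.setdefault(j, []).append(i)
        elif system.element[j] == "H" and system.element[i] != "H":
            out.setdefault(i, []).append(j)
    return out


def _angle_deg(a, b, c):
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1, 1))))


def detect_contacts(system: MolecularSystem, coords: np.ndarray | None = None,
                    kind: str = "hbond", params: InteractionParams = InteractionParams(),
                    frame: int = 0) -> list[InteractionRecord]:
    """Detect one kind of receptor–ligand contact on a single frame.

    hbond: polar(N/O) pair distance ≤ d_hbond; when the putative donor has
    bonded hydrogens, the best D–H···A angle must reach angle_hbond,
    otherwise the record is a flagged distance-only fallback (angle None).
    hydrophobic: apolar-carbon pair distance ≤ d_hydrophobic.
    vdw: distance ≤ vdw_scale·(r_i + r_j), excluding pairs already reported
    as hydrogen bonds.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown interaction kind {kind!r}")
    if coords is None:
        coords = system.coords
    rec_idx = system.atom_indices("receptor")
    lig_idx = system.atom_indices("ligand")
    if rec_idx.size == 0 or lig_idx.size == 0:
        raise ValueError("system must contain receptor and ligand segments")
    records = []
    hydrogens = _bonded_hydrogens(system)

    def make(i, j, d, angle=None):
        mid = tuple(0.5 * (coords[i] + coords[j]))
        return InteractionRecord(frame=frame, kind=kind, receptor_atom=int(i),
                                 ligand_atom=int(j), distance=float(d),
                                 midpoint=mid, angle=angle)

    if kind == "hbond":
        ri = rec_idx[system.is_polar[rec_idx]]
        lj = lig_idx[system.is_polar[lig_idx]]
        for i in ri:
            d = np.linalg.norm(coords[lj] - coords[i], axis=1)
            for j, dij in zip(lj, d):
                if dij > params.d_hbond or dij <= 0:
                    continue
                angle = None
                # D-H...A angle at H; the donor is whichever heavy atom owns h
                candidates = [(h, j) for h in hydrogens.get(int(i), [])]
                candidates += [(h, i) for h in hydrogens.get(int(j), [])]
                if candidates:
                    best = max(
                        _angle_deg(coords[donor_partner], coords[h], coords[acceptor])
                        for h, acceptor in candidates
                        for donor_partner in [i if acceptor == j else j]
                    )
                    if best < params.angle_hbond:
                        continue
                    angle = best
                records.append(make(i, j, dij, angle))
    elif kind == "hydrophobic":
        apolar = system.is_apolar_carbon
        ri = rec_idx[apolar[rec_idx]]
        lj = lig_idx[apolar[lig_idx]]
        for i in ri:
            d = np.linalg.norm(coords[lj] - coords[i], axis=1)
            for j, dij in zip(lj, d):
                if 0 < dij <= params.d_hydrophobic:
                    records.append(make(i, j, dij))
    else:  # vdw
        radii = system.vdw_radius
        if np.any(~np.isfinite(radii[np.concatenate([rec_idx, lig_idx])])):
            raise ValueError("vdW detection requires radii on all atoms")
        hb = {
            (r.receptor_atom, r.ligand_atom)
            for r in detect_contacts(system, coords, "hbond", params, frame)
        }
        for i in rec_idx:
            d = np.linalg.norm(coords[lig_idx] - coords[i], axis=1)
            cut = params.vdw_scale * (radii[i] + radii[lig_idx])
            for j, dij, cij in zip(lig_idx, d, cut):
                if 0 < dij <= cij and (int(i), int(j)) not in hb:
                    records.append(make(i, j, dij))
    return records


def detect_water_bridges(system: MolecularSystem, coords: np.ndarray | None = None,
                         params: InteractionParams = InteractionParams(),
                         frame: int = 0) -> list[InteractionRecord]:
    """Waters simultaneously H-bond-distance to receptor and ligand polar
    atoms; one record per (water, receptor atom, ligand atom) triple."""
    if coords is None:
        coords = system.coords
    waters = np.where((system.segment == "water") & (system.element == "O"))[0]
    records = []
    if waters.size == 0:
        return records
    rec = system.atom_indices("receptor")
    lig = system.atom_indices("ligand")
    rec = rec[system.is_polar[rec]]
    lig = lig[system.is_polar[lig]]
    for w in waters:
        dr = np.linalg.norm(coords[rec] - coords[w], axis=1)
        dl = np.linalg.norm(coords[lig] - coords[w], axis=1)
        near_r = rec[dr <= params.d_hbond]
        near_l = lig[dl <= params.d_hbond]
        for i in near_r:
            for j in near_l:
                di = np.linalg.norm(coords[i] - coords[w])
                dj = np.linalg.norm(coords[j] - coords[w])
                records.append(InteractionRecord(
                    frame=frame, kind="water_bridge", receptor_atom=int(i),
                    ligand_atom=int(j), distance=float(0.5 * (di + dj)),
                    midpoint=tuple(coords[w]), water=int(w),
                ))
    return records


def detect_over_trajectory(trajectory, kinds=KINDS,
                           params: InteractionParams = InteractionParams(),
                           include_water_bridges: bool = False):
    """Run per-frame detection over a whole (sub)trajectory."""
    records = []
    for f in range(trajectory.n_frames):
        for kind in kinds:
            records += detect_contacts(trajectory.system, trajectory.coords[f],
                                       kind, params, frame=f)
        if include_water_bridges:
            records += detect_water_bridges(trajectory.system, trajectory.coords[f],
                                            params, frame=f)
    return records


def occurrence_matrix(records, ensemble: ConformerEnsemble,
                      rp_map: ResiduePositionMap, system: MolecularSystem,
                      kind: str) -> OccurrenceMatrix:
    """Percentage of each conformer's frames in which a residue position has
    at least one interaction of ``kind``; unmapped residues land in 'other'."""
    key_to_label = {tuple(rp_map.mapping[lab]): lab for lab in rp_map.labels}
    row_labels = list(rp_map.labels)
    other_needed = False
    hits: dict[tuple[str, int], set] = {}
    for r in records:
        if r.kind != kind:
            continue
        key = (str(system.chain_id[r.receptor_atom]), int(system.residue_seq[r.receptor_atom]))
        lab = key_to_label.get(key)
        if lab is None:
            other_needed = True
            lab = "other"
        hits.setdefault(lab, set()).add(r.frame)
    if other_needed:
        warnings.warn("interaction records reference residues outside the position map")
        row_labels = row_labels + ["other"]
    cids = sorted(ensemble.members)
    values = np.zeros((len(row_labels), len(cids)))
    for c, cid in enumerate(cids):
        frames = set(int(f) for f in ensemble.members[cid])
        if not frames:
            continue
        for rlab, rframes in hits.items():
            row = row_labels.index(rlab)
            values[row, c] = 100.0 * len(rframes & frames) / len(frames)
    return OccurrenceMatrix(kind=kind, row_labels=row_labels,
                            conformer_ids=cids, values=values)


def mif_point_cloud(records, kind: str,
                    ensemble: ConformerEnsemble | None = None) -> PointCloud:
    """Pool interaction midpoints into a 3-D field; per-conformer centroids
    and spreads quantify cluster-to-cluster displacement."""
    pts = np.array([r.midpoint for r in records if r.kind == kind], float)
    if pts.size == 0:
        warnings.warn(f"no records of kind {kind!r}; empty cloud")
        return PointCloud(kind=kind, points=np.empty((0, 3)),
                          centroid=np.full(3, np.nan), spread=np.nan)
    centroid = pts.mean(axis=0)
    spread = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    by_conf = {}
    if ensemble is not None:
        for cid, idx in ensemble.members.items():
            frames = set(int(f) for f in idx)
            sub = np.array([r.midpoint for r in records
                            if r.kind == kind and r.frame in frames], float)
            if sub.size:
                c = sub.mean(axis=0)
                s = float(np.sqrt(((sub - c) ** 2).sum(axis=1).mean()))
                by_conf[cid] = (c, s, len(sub))
    return PointCloud(kind=kind, points=pts, centroid=centroid,
                      spread=spread, by_conformer=by_conf)
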