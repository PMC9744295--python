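"""Per-frame and per-residue structural descriptors and similarity maps.

RMSD and radius of gyration are per-frame series (Å); RMSF (Å) and SASA (Ų)
are per-residue profiles; profiles from different conformers are compared
with the Pearson product-moment correlation, optionally restricted to a
named residue-position map (e.g. the conserved recognition positions).

SASA uses the Shrake–Rupley point-sampling construction with deterministic
golden-spiral test points (no RNG), probe 1.4 Å and 960 points by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import kabsch
from .structure_io import MolecularSystem, ResiduePositionMap, Trajectory

__all__ = [
    "DescriptorSeries",
    "ResidueProfile",
    "SimilarityMatrix",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf",
    "sasa",
    "pearson_similarity",
]

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class DescriptorSeries:
    kind: str  # rmsd | rg
    values: np.ndarray  # per frame, Å
    selection: str
    mean: float = None
    sd: float = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=0)) if self.values.size > 1 else 0.0


@dataclass
class ResidueProfile:
    kind: str  # rmsf | sasa
    keys: list  # ordered (chain_id, residue_seq)
    values: np.ndarray
    conformer_id: int | None = None
    total: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.keys) != self.values.size:
            raise ValueError("profile keys and values differ in length")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.kind} values must be non-negative")


@dataclass
class SimilarityMatrix:
    labels: list[str]
    matrix: np.ndarray  # Pearson r; NaN marks undefined (zero-variance) pairs

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("similarity matrix must be square and match labels")
        finite = np.isfinite(m)
        if not np.allclose(np.where(finite, m, 0), np.where(finite.T, m.T, 0), atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        diag = np.diag(m)
        if np.any(np.abs(diag[np.isfinite(diag)] - 1) > 1e-9):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.any(np.abs(m[finite]) > 1 + 1e-9):
            raise ValueError("Pearson r must lie in [-1, 1]")
        self.matrix = m


def kabsch_superpose(reference, mobile, weights=None):
    """Optimal proper-rotation superposition; see :func:`confrec._geom.kabsch`.

    Returns ``(rotation, translation, rmsd)``.
    """
    return kabsch(reference, mobile, weights)


def _select(trajectory: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(trajectory.system.n_atoms)
    idx = np.asarray(selection, int)
    if idx.size == 0:
        raise ValueError("selection is empty")
    return idx


def rmsd_series(trajectory: Trajectory, reference_frame: int = 0,
                selection=None) -> DescriptorSeries:
    """Per-frame superposed RMSD (Å) against a reference frame."""
    if not 0 <= reference_frame < trajectory.n_frames:
        raise ValueError(f"reference frame {reference_frame} out of range")
    idx = _select(trajectory, selection)
    X = trajectory.coords[:, idx]
    ref = X[reference_frame]
    vals = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        _, _, vals[f] = kabsch(ref, X[f])
    return DescriptorSeries(kind="rmsd", values=vals,
                            selection=f"{idx.size} atoms vs frame {reference_frame}")


def radius_of_gyration(trajectory: Trajectory, selection=None,
                       mass_weighted: bool = False) -> DescriptorSeries:
    """Rg = sqrt(Σ w_i |r_i − r_com|² / Σ w_i) per frame (Å)."""
    idx = _select(trajectory, selection)
    if idx.size < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    X = trajectory.coords[:, idx]
    if mass_weighted:
        w = np.array([_MASSES.get(e, 12.0) for e in trajectory.system.element[idx]])
    else:
        w = np.ones(idx.size)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    com = (w[None, :, None] * X).sum(axis=1) / w.sum()
    d2 = ((X - com[:, None, :]) ** 2).sum(axis=2)
    vals = np.sqrt((w[None, :] * d2).sum(axis=1) / w.sum())
    return DescriptorSeries(kind="rg", values=vals,
                            selection=f"{idx.size} atoms, mass_weighted={mass_weighted}")


def superpose_to_mean(coords: np.ndarray, tol: float = 1e-6,
                      max_iter: int = 100) -> np.ndarray:
    """Iteratively superpose a coordinate stack onto its converged mean."""
    n_frames = coords.shape[0]
    ref = coords[0] - coords[0].mean(axis=0)
    fitted = np.empty_like(coords)
    for _ in range(max_iter):
        for f in range(n_frames):
            R, t, _ = kabsch(ref, coords[f])
            fitted[f] = coords[f] @ R.T + t
        mean = fitted.mean(axis=0)
        done = np.max(np.abs(mean - ref)) < tol
        ref = mean
        if done:
            break
    return fitted


def rmsf(trajectory: Trajectory, selection=None, per_residue: bool = True):
    """RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) after superposition onto the ensemble
    mean structure; per-residue values average the residue's atoms."""
    if trajectory.n_frames < 2:
        raise ValueError("RMSF undefined for fewer than 2 frames")
    idx = _select(trajectory, selection)
    fitted = superpose_to_mean(trajectory.coords[:, idx])
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    system = trajectory.system
    if not per_residue:
        keys = [(str(system.chain_id[i]), int(system.residue_seq[i]), str(system.name[i]))
                for i in idx]
        return ResidueProfile(kind="rmsf", keys=keys, values=per_atom)
    keys, values = [], []
    for key in system.residue_keys():
        mask = [
            k for k, i in enumerate(idx)
            if (str(system.chain_id[i]), int(system.residue_seq[i])) == key
        ]
        if mask:
            keys.append(key)
            values.append(per_atom[mask].mean())
    return ResidueProfile(kind="rmsf", keys=keys, values=np.array(values))


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(system: MolecularSystem, coords: np.ndarray | None = None,
         probe_radius: float = 1.4, n_sphere_points: int = 960,
         atom_subset=None) -> ResidueProfile:
    """Shrake–Rupley solvent-accessible surface area (Ų).

    Test points on each atom's solvent-expanded sphere are discarded when
    inside any neighbour's expanded sphere; per-atom area is the retained
    fraction of 4π(R+p)².  Returns residue sums with the grand total.
    """
    if coords is None:
        coords = system.coords
    idx = np.arange(system.n_atoms) if atom_subset is None else np.asarray(atom_subset, int)
    radii = system.vdw_radius[idx]
    missing = np.where(~np.isfinite(radii))[0]
    if missing.size:
        atoms = [str(system.name[idx[i]]) for i in missing[:5]]
        raise ValueError(f"missing vdW radius for atom(s) {atoms}")
    X = coords[idx]
    expanded = radii + probe_radius
    sphere = _golden_spiral(n_sphere_points)
    tree = cKDTree(X)
    areas = np.empty(idx.size)
    rmax = expanded.max()
    for a in range(idx.size):
        pts = X[a] + expanded[a] * sphere
        nbrs = [b for b in tree.query_ball_point(X[a], expanded[a] + rmax) if b != a]
        if nbrs:
            d = np.linalg.norm(pts[:, None, :] - X[nbrs][None, :, :], axis=2)
            buried = (d < expanded[nbrs][None, :]).any(axis=1)
        else:
            buried = np.zeros(n_sphere_points, bool)
        frac = 1.0 - buried.mean()
        areas[a] = frac * 4.0 * np.pi * expanded[a] ** 2
    keys, values = [], []
    for key in system.residue_keys():
        mask = [
            k for k, i in enumerate(idx)
            if (str(system.chain_id[i]), int(system.residue_seq[i])) == key
        ]
        if mask:
            keys.append(key)
            values.append(areas[mask].sum())
    return ResidueProfile(kind="sasa", keys=keys, values=np.array(values),
                          total=float(areas.sum()))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either side has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def pearson_similarity(profiles, labels=None,
                       restrict_to: ResiduePositionMap | None = None) -> SimilarityMatrix:
    """Pearson r between every pair of profiles sharing a key ordering.

    ``restrict_to`` limits the comparison to the mapped residue positions.
    Zero-variance profiles yield NaN (undefined), never 0.
    """
    arrays, keys0 = [], None
    for p in profiles:
        if isinstance(p, ResidueProfile):
            keys, vals = list(p.keys), p.values
        elif isinstance(p, DescriptorSeries):
            keys, vals = list(range(p.values.size)), p.values
        else:
            vals = np.asarray(p, float)
            keys = list(range(vals.size))
        if keys0 is None:
            keys0 = keys
        elif keys != keys0:
            raise ValueError("all profiles must share the same key ordering")
        arrays.append(np.asarray(vals, float))
    if restrict_to is not None:
        wanted = [tuple(restrict_to.mapping[lab]) for lab in restrict_to.labels]
        sel = [keys0.index(k) for k in wanted if k in keys0]
        if len(sel) < len(wanted):
            raise ValueError("restriction references residues absent from the profiles")
        arrays = [a[sel] for a in arrays]
    length = arrays[0].size
    if length < 3:
        warnings.warn(f"profiles of length {length} give a fragile correlation")
    n = len(arrays)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _pearson(arrays[i], arrays[j])
    if labels is None:
        labels = [f"profile{i}" for i in range(n)]
    return SimilarityMatrix(labels=list(labels), matrix=m)
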