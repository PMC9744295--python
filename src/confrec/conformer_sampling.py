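"""Hierarchical extraction of metastable conformers from a trajectory.

The levels mirror the standard hierarchy for ensemble refinement:
Cartesian PCA on superposed coordinates (cPCA), then dihedral PCA (dPCA) on
sin/cos-encoded torsions of progressively narrower selections (backbone,
recognition-domain, ligand).  Each level's 2-D essential subspace is binned
into a free-energy surface ΔG = −kT·ln(P/P_max) and geometrically separated
with k-means; levels refine the clusters of the previous level, and the
resulting leaves are the metastable conformers with their populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._geom import wrap_degrees
from .structure_io import MolecularSystem, Trajectory

__all__ = [
    "DihedralSeries",
    "FeatureMatrix",
    "PCProjection",
    "FreeEnergySurface",
    "ClusterModel",
    "ConformerEnsemble",
    "LevelSpec",
    "ConfigurationError",
    "compute_dihedrals",
    "encode_circular",
    "cartesian_features",
    "run_pca",
    "free_energy_surface",
    "kmeans_cluster",
    "hierarchical_sample",
    "extract_subtrajectories",
]

KT_300K = 2.494  # kJ/mol at 300 K; FEL kT is a free parameter, this is the convention


class ConfigurationError(ValueError):
    """A level requested features the system cannot provide."""


@dataclass
class DihedralSeries:
    labels: list[str]
    kinds: list[str]
    segments: list[str]
    angles: np.ndarray  # (n_frames, n_torsions) degrees in [-180, 180)
    flagged: np.ndarray | None = None  # (frame, torsion) pairs with ill-defined geometry

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("dihedral series contains non-finite angles")
        if np.any(self.angles < -180) or np.any(self.angles >= 180):
            raise ValueError("dihedral angles outside [-180, 180)")


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_frames, n_features)
    provenance: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class PCProjection:
    eigenvalues: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    projections: np.ndarray  # (n_frames, n_components)
    variance_fraction: np.ndarray

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(ev) > 1e-9) or np.any(ev < -1e-9):
            raise ValueError("eigenvalues must be non-increasing and non-negative")


@dataclass
class FreeEnergySurface:
    """2-D free-energy landscape over (PC1, PC2); unoccupied bins are NaN."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    probability: np.ndarray
    delta_g: np.ndarray  # kT units scaled by kT argument; min over occupied bins == 0
    kT: float

    def __post_init__(self):
        occ = self.probability > 0
        total = self.probability.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")
        if occ.any():
            if abs(np.nanmin(self.delta_g[occ])) > 1e-9:
                raise ValueError("minimum occupied-bin ΔG must be 0")
        if np.any(np.isfinite(self.delta_g[~occ])):
            raise ValueError("empty bins must carry the NaN sentinel")


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    populations: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, int)
        if self.populations.sum() != self.labels.size:
            raise ValueError("populations must sum to n_frames")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels outside [0, k)")


@dataclass
class ConformerEnsemble:
    """cluster id → ordered frame indices, with per-leaf provenance."""

    members: dict[int, np.ndarray]
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for cid, idx in self.members.items():
            idx = np.asarray(idx, int)
            self.members[cid] = idx
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"frame(s) {sorted(overlap)[:3]} assigned to multiple conformers")
            seen.update(idx.tolist())

    @property
    def populations(self) -> dict[int, int]:
        return {cid: len(idx) for cid, idx in self.members.items()}

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, int)
        for cid, idx in self.members.items():
            lab[idx] = cid
        return lab


@dataclass(frozen=True)
class LevelSpec:
    """One refinement level: feature source + cluster count.

    ``source``: 'cartesian' or 'dihedral'.  For dihedral levels the torsion
    set is filtered by ``segment`` (receptor/ligand/None=all) and ``kinds``
    (subset of phi/psi/chi/omega, None=all).  ``k`` is an integer or 'auto'.
    """

    source: str
    k: int | str = "auto"
    segment: str | None = None
    kinds: tuple | None = None


def compute_dihedrals(trajectory: Trajectory, kinds=None, segment=None,
                      torsion_names=None) -> DihedralSeries:
    """Signed dihedrals (degrees, [-180, 180)) for the selected torsions.

    Frames whose quadruple is geometrically degenerate (colinear triple) are
    flagged and the value set to 0; a warning reports the frames.
    """
    system = trajectory.system
    selected = []
    for t in system.torsions:
        if torsion_names is not None and t.name not in torsion_names:
            continue
        if kinds is not None and t.kind not in kinds:
            continue
        if segment is not None and t.segment != segment:
            continue
        selected.append(t)
    if not selected:
        raise ConfigurationError(
            f"no torsions match kinds={kinds!r}, segment={segment!r}"
        )
    X = trajectory.coords
    n_frames = X.shape[0]
    angles = np.empty((n_frames, len(selected)))
    flagged = []
    for j, t in enumerate(selected):
        p0, p1, p2, p3 = (X[:, i] for i in t.atoms)
        b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
        b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
        b1u = b1 / np.where(b1n > 1e-12, b1n, 1.0)
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        bad = (
            (np.linalg.norm(v, axis=-1) < 1e-8)
            | (np.linalg.norm(w, axis=-1) < 1e-8)
            | (b1n[:, 0] < 1e-12)
        )
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        ang = wrap_degrees(np.degrees(np.arctan2(y, x)))
        if bad.any():
            for f in np.where(bad)[0]:
                flagged.append((int(f), j))
            ang[bad] = 0.0
            warnings.warn(
                f"torsion {t.name}: undefined dihedral in frame(s) "
                f"{np.where(bad)[0].tolist()[:5]}"
            )
        angles[:, j] = ang
    return DihedralSeries(
        labels=[t.name for t in selected],
        kinds=[t.kind for t in selected],
        segments=[t.segment for t in selected],
        angles=angles,
        flagged=np.array(flagged, int) if flagged else None,
    )


def encode_circular(dihedrals: DihedralSeries) -> FeatureMatrix:
    """sin/cos-encode each torsion: θ → (sin θ, cos θ), 2 features per torsion."""
    rad = np.radians(dihedrals.angles)
    n_frames, n_tors = rad.shape
    feats = np.empty((n_frames, 2 * n_tors))
    feats[:, 0::2] = np.sin(rad)
    feats[:, 1::2] = np.cos(rad)
    prov = []
    for lab in dihedrals.labels:
        prov += [f"sin {lab}", f"cos {lab}"]
    return FeatureMatrix(values=feats, provenance=prov)


def cartesian_features(trajectory: Trajectory, atom_indices=None,
                       tol: float = 1e-6, max_iter: int = 100) -> FeatureMatrix:
    """Superpose every frame onto the iterated ensemble-mean structure and
    flatten the xyz coordinates (the cPCA feature set)."""
    from ._geom import kabsch

    X = trajectory.coords
    if atom_indices is not None:
        X = X[:, np.asarray(atom_indices, int)]
    n_frames, n_atoms, _ = X.shape
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms for Cartesian features")
    ref = X[0] - X[0].mean(axis=0)
    if np.linalg.matrix_rank(ref, tol=1e-8) < 2:
        raise ValueError("reference structure is degenerate (colinear atoms)")
    fitted = np.empty_like(X)
    for _ in range(max_iter):
        for f in range(n_frames):
            R, t, _ = kabsch(ref, X[f])
            fitted[f] = X[f] @ R.T + t
        mean = fitted.mean(axis=0)
        if np.max(np.abs(mean - ref)) < tol:
            ref = mean
            break
        ref = mean
    prov = [f"atom{i} {ax}" for i in range(n_atoms) for ax in "xyz"]
    return FeatureMatrix(values=fitted.reshape(n_frames, -1), provenance=prov)


def run_pca(features: FeatureMatrix, n_components: int) -> PCProjection:
    """Covariance-based PCA on mean-centred (never scaled) features."""
    X = features.values
    n_frames = X.shape[0]
    if not 1 <= n_components < n_frames:
        raise ValueError("need n_frames > n_components >= 1")
    n_components = min(n_components, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(X)
    total_var = X.var(axis=0, ddof=1).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_var > 0, pca.explained_variance_ / max(total_var, 1e-300), 0.0)
    return PCProjection(
        eigenvalues=pca.explained_variance_,
        components=pca.components_,
        projections=proj,
        variance_fraction=frac,
    )


def free_energy_surface(projection: PCProjection, n_bins: int = 32,
                        kT: float = KT_300K) -> FreeEnergySurface:
    """Bin (PC1, PC2) and convert occupancy to ΔG = −kT·ln(P/P_max).

    The global minimum is exactly 0; unoccupied bins carry NaN.
    """
    if projection.projections.shape[1] < 2:
        raise ValueError("need at least 2 principal components for a surface")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x, y = projection.projections[:, 0], projection.projections[:, 1]
    counts, ex, ey = np.histogram2d(x, y, bins=n_bins)
    prob = counts / counts.sum()
    occupied = prob > 0
    if occupied.sum() == 1:
        warnings.warn("all frames fall into a single bin")
    dg = np.full_like(prob, np.nan)
    pmax = prob.max()
    with np.errstate(divide="ignore"):
        dg[occupied] = -kT * np.log(prob[occupied] / pmax)
    return FreeEnergySurface(edges_x=ex, edges_y=ey, probability=prob,
                             delta_g=dg, kT=kT)


def kmeans_cluster(projection: PCProjection, k="auto", seed: int = 0,
                   n_restarts: int = 10, n_components: int = 2,
                   k_max: int = 8, variance_floor: float = 0.05) -> ClusterModel:
    """Best-of-restarts k-means (k-means++ seeding) on the leading PCs.

    ``k='auto'`` picks the k in {2..k_max} maximising mean silhouette, with
    a k=1 fallback when the retained-PC variance is below ``variance_floor``
    (a flat, single-basin landscape).
    """
    X = projection.projections[:, : min(n_components, projection.projections.shape[1])]
    n_frames = X.shape[0]
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"unknown k specification {k!r}")
        if X.var(axis=0, ddof=1).sum() < variance_floor or n_frames < 4:
            k = 1
        else:
            best_k, best_score = 1, -np.inf
            for kk in range(2, min(k_max, n_frames - 1) + 1):
                km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
                lab = km.fit_predict(X)
                if len(np.unique(lab)) < 2:
                    continue
                score = silhouette_score(X, lab)
                if score > best_score:
                    best_k, best_score = kk, score
            k = best_k
    if k > n_frames:
        raise ValueError(f"k={k} exceeds the {n_frames} available frames")
    if k == 1:
        labels = np.zeros(n_frames, int)
        centroids = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        centroids = km.cluster_centers_
    populations = np.bincount(labels, minlength=k)
    return ClusterModel(k=k, centroids=centroids, labels=labels, populations=populations)


def _level_features(trajectory: Trajectory, spec: LevelSpec, level_no: int) -> FeatureMatrix:
    if spec.source == "cartesian":
        return cartesian_features(trajectory)
    if spec.source == "dihedral":
        try:
            dih = compute_dihedrals(trajectory, kinds=spec.kinds, segment=spec.segment)
        except ConfigurationError as exc:
            raise ConfigurationError(f"level {level_no}: {exc}") from exc
        return encode_circular(dih)
    raise ConfigurationError(f"level {level_no}: unknown feature source {spec.source!r}")


def hierarchical_sample(trajectory: Trajectory, level_specs, seed: int = 0,
                        min_population: int = 10, n_components: int = 2,
                        n_restarts: int = 10) -> ConformerEnsemble:
    """Successive-refinement clustering: each level re-clusters every leaf of
    the previous level in its own feature space; leaves smaller than
    ``min_population`` are merged into the nearest sibling centroid."""
    level_specs = list(level_specs)
    if not level_specs:
        raise ValueError("need at least one level")
    leaves = [np.arange(trajectory.n_frames)]
    prov = ["root"]
    for lno, spec in enumerate(level_specs, start=1):
        new_leaves, new_prov = [], []
        for leaf, ptag in zip(leaves, prov):
            want_k = spec.k if not isinstance(spec.k, str) else 2
            if len(leaf) < max(2 * min_population, want_k, 4):
                new_leaves.append(leaf)
                new_prov.append(ptag)
                continue
            sub = trajectory.subset(leaf)
            feats = _level_features(sub, spec, lno)
            ncomp = min(n_components, feats.values.shape[1], len(leaf) - 1)
            proj = run_pca(feats, ncomp)
            model = kmeans_cluster(proj, k=spec.k, seed=seed, n_restarts=n_restarts,
                                   n_components=n_components)
            labels = model.labels.copy()
            # merge undersized clusters into the nearest sibling centroid
            X = proj.projections[:, : model.centroids.shape[1]]
            sizes = np.bincount(labels, minlength=model.k)
            big = np.where(sizes >= min_population)[0]
            if len(big) == 0:
                big = np.array([np.argmax(sizes)])
            for c in range(model.k):
                if c in big:
                    continue
                members = labels == c
                d = np.linalg.norm(
                    model.centroids[big][None, :, :] - X[members][:, None, :], axis=2
                )
                labels[members] = big[np.argmin(d, axis=1)]
            for c in sorted(set(labels.tolist())):
                new_leaves.append(leaf[labels == c])
                new_prov.append(f"{ptag}/L{lno}({spec.source}):{c}")
        leaves, prov = new_leaves, new_prov
    members = {cid: leaf for cid, leaf in enumerate(leaves)}
    provenance = {cid: tag for cid, tag in enumerate(prov)}
    return ConformerEnsemble(members=members, provenance=provenance)


def extract_subtrajectories(trajectory: Trajectory,
                            ensemble: ConformerEnsemble) -> dict[int, Trajectory]:
    """One trajectory per conformer; frame order preserved, empty leaves skipped."""
    out = {}
    for cid, idx in ensemble.members.items():
        if len(idx) == 0:
            warnings.warn(f"conformer {cid} is empty; skipped")
            continue
        idx = np.sort(np.asarray(idx, int))
        if idx.min() < 0 or idx.max() >= trajectory.n_frames:
            raise ValueError(f"conformer {cid} references frames outside the trajectory")
        out[cid] = trajectory.subset(idx)
    return out
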