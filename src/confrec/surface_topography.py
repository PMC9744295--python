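"""Protein surface topography: property maps on a sphere, drawn in Mollweide.

A solvent-accessible dot surface is built per conformer (golden-spiral
Shrake–Rupley retention), the molecular electrostatic potential (MEP) or
molecular hydrophobicity potential (MHP) is evaluated at each retained dot,
the dots are projected onto a sphere centred at the surface's geometric
centre (latitude = arcsin(z/|r|), longitude = atan2(y, x)), interpolated on
the regular 1° latitude × longitude grid, and rendered with the equal-area
Mollweide cartographic projection.  Maps from different conformers are
compared as Pearson correlations over co-occupied grid nodes.

The MHP kernel is MLP(r) = Σ_i f_i·exp(−|r − r_i|²) with distances in Å —
no length-scale constant — so absolute values are only comparable between
maps produced by this kernel; relative patterns are the object of study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .binding_energetics import COULOMB_KJ_NM
from .ensemble_descriptors import _golden_spiral, _pearson
from .structure_io import MolecularSystem, ScalarGrid

__all__ = [
    "SurfacePointSet",
    "TopographyMap",
    "dot_surface",
    "mhp_at_points",
    "mep_at_points",
    "spherical_project",
    "interpolate_equal_area_grid",
    "mollweide_forward",
    "mollweide_inverse",
    "render_mollweide",
    "map_similarity",
]


@dataclass
class SurfacePointSet:
    """Retained solvent-accessible dots; empty when the subset is fully buried."""

    points: np.ndarray  # (n, 3) Å
    parent_atom: np.ndarray  # atom index per point


@dataclass
class TopographyMap:
    """Property values on the 181 × 361 equal-step spherical grid."""

    property: str  # MEP | MHP
    latitudes: np.ndarray  # 181 values, -90..90
    longitudes: np.ndarray  # 361 values, -180..180
    values: np.ndarray  # (181, 361); masked nodes NaN
    mask: np.ndarray  # True = no data
    centre: np.ndarray

    def __post_init__(self):
        if self.values.shape != (181, 361):
            raise ValueError("topography grid must be 181 × 361 (1° steps)")
        if np.any(np.isfinite(self.values[self.mask])):
            raise ValueError("masked nodes must carry no value")
        if not np.all(np.isfinite(self.centre)):
            raise ValueError("sphere centre must be finite")


def dot_surface(system: MolecularSystem, residue_subset=None,
                probe_radius: float = 1.4, points_per_atom: int = 240,
                coords: np.ndarray | None = None) -> SurfacePointSet:
    """Solvent-accessible dot surface by Shrake–Rupley retention.

    ``residue_subset``: iterable of (chain_id, residue_seq) keys; occlusion
    is still tested against every atom of the system so buried faces of the
    subset are correctly removed.
    """
    if coords is None:
        coords = system.coords
    if residue_subset is None:
        subset_idx = np.arange(system.n_atoms)
    else:
        keys = [tuple(k) for k in residue_subset]
        if not keys:
            raise ValueError("residue subset is empty")
        subset_idx = np.concatenate([system.residue_atoms(k) for k in keys])
    radii = system.vdw_radius
    if np.any(~np.isfinite(radii[subset_idx])):
        raise ValueError("missing vdW radii on surface atoms")
    occluders = np.where(np.isfinite(radii))[0]
    expanded_all = radii[occluders] + probe_radius
    tree = cKDTree(coords[occluders])
    sphere = _golden_spiral(points_per_atom)
    rmax = expanded_all.max()
    pts, parents = [], []
    for a in subset_idx:
        ra = radii[a] + probe_radius
        cand = tree.query_ball_point(coords[a], ra + rmax)
        nbrs = [c for c in cand if occluders[c] != a]
        dots = coords[a] + ra * sphere
        if nbrs:
            d = np.linalg.norm(dots[:, None, :] - coords[occluders[nbrs]][None, :, :], axis=2)
            keep = ~(d < expanded_all[nbrs][None, :]).any(axis=1)
        else:
            keep = np.ones(points_per_atom, bool)
        pts.append(dots[keep])
        parents.append(np.full(keep.sum(), a))
    points = np.vstack(pts) if pts else np.empty((0, 3))
    parents = np.concatenate(parents) if parents else np.empty(0, int)
    if len(points) == 0:
        warnings.warn("no surface points retained (fully buried subset)")
    return SurfacePointSet(points=points, parent_atom=parents)


def mhp_at_points(points: np.ndarray, system: MolecularSystem,
                  coords: np.ndarray | None = None) -> np.ndarray:
    """MLP(r) = Σ_i f_i · exp(−|r − r_i|²), distances in Å, all atoms contribute."""
    if coords is None:
        coords = system.coords
    f = system.lipophilicity
    if np.any(~np.isfinite(f)):
        missing = [str(system.name[i]) for i in np.where(~np.isfinite(f))[0][:5]]
        raise ValueError(f"missing lipophilicity for atom(s) {missing}")
    pts = np.atleast_2d(points)
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2) @ f


def mep_at_points(points: np.ndarray, system: MolecularSystem,
                  method: str = "coulomb", grid: ScalarGrid | None = None,
                  eps_eff: float = 78.54,
                  coords: np.ndarray | None = None) -> np.ndarray:
    """Electrostatic potential at surface points (kJ/mol/e).

    ``external_dx`` interpolates an imported potential grid (the faithful
    route); ``coulomb`` is the approximate built-in Σ k_e q_i / (ε_eff r).
    """
    pts = np.atleast_2d(points)
    if method == "external_dx":
        if grid is None:
            raise ValueError("external_dx requires a ScalarGrid")
        return grid.interpolate(pts)
    if method == "coulomb":
        if coords is None:
            coords = system.coords
        q = system.partial_charge
        if np.any(~np.isfinite(q)):
            raise ValueError("missing charges for Coulomb potential")
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        if np.any(d < 1e-6):
            raise ValueError("evaluation point coincides with an atom")
        return (COULOMB_KJ_NM / eps_eff) * ((q[None, :] / (d / 10.0)).sum(axis=1))
    raise ValueError(f"unknown MEP method {method!r}")


def spherical_project(points: np.ndarray, centre="auto"):
    """(latitude°, longitude°) of each point on the sphere about ``centre``.

    latitude = arcsin(z/|r|); longitude = atan2(y, x) (quadrant-aware), so
    longitude ∈ (−180°, 180°].  centre='auto' uses the point centroid.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 0:
        raise ValueError("no points to project")
    c = pts.mean(axis=0) if isinstance(centre, str) else np.asarray(centre, float)
    r = pts - c
    norm = np.linalg.norm(r, axis=1)
    if np.any(norm < 1e-9):
        raise ValueError("point coincident with the sphere centre")
    lat = np.degrees(np.arcsin(np.clip(r[:, 2] / norm, -1, 1)))
    lon = np.degrees(np.arctan2(r[:, 1], r[:, 0]))
    return lat, lon, c


def _unit_vectors(lat_deg, lon_deg):
    lat = np.radians(np.asarray(lat_deg, float))
    lon = np.radians(np.asarray(lon_deg, float))
    return np.column_stack([
        np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)
    ])


def interpolate_equal_area_grid(lat, lon, values, property_name: str = "MEP",
                                centre=(0.0, 0.0, 0.0), mask_radius_deg: float = 10.0,
                                n_neighbors: int = 6, power: float = 2.0) -> TopographyMap:
    """Fill the 1° latitude/longitude grid from scattered samples.

    Great-circle nearest-neighbour fill with local inverse-distance
    weighting; the ±180° longitude seam is continuous because distances are
    measured on the sphere.  Nodes farther than ``mask_radius_deg`` from any
    sample are masked.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    values = np.asarray(values, float)
    if lat.size < 3:
        raise ValueError("need at least 3 samples")
    uv = _unit_vectors(lat, lon)
    if np.linalg.matrix_rank(uv - uv.mean(axis=0), tol=1e-9) < 1 or (
        np.allclose(uv, uv[0], atol=1e-12)
    ):
        raise ValueError("all samples at one location")
    lats = np.arange(-90.0, 91.0)
    lons = np.arange(-180.0, 181.0)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    nodes = _unit_vectors(glat.ravel(), glon.ravel())
    tree = cKDTree(uv)
    k = min(n_neighbors, lat.size)
    chord, idx = tree.query(nodes, k=k)
    chord = np.atleast_2d(chord.reshape(nodes.shape[0], k))
    idx = idx.reshape(nodes.shape[0], k)
    ang = np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0, 1)))
    out = np.full(nodes.shape[0], np.nan)
    masked = ang[:, 0] > mask_radius_deg
    exact = ang[:, 0] < 1e-9
    out[exact] = values[idx[exact, 0]]
    todo = ~masked & ~exact
    if todo.any():
        a = ang[todo]
        within = a <= mask_radius_deg
        w = np.where(within, 1.0 / np.maximum(a, 1e-12) ** power, 0.0)
        out[todo] = (w * values[idx[todo]]).sum(axis=1) / w.sum(axis=1)
    grid = out.reshape(181, 361)
    mask = ~np.isfinite(grid)
    return TopographyMap(property=property_name, latitudes=lats, longitudes=lons,
                         values=grid, mask=mask, centre=np.asarray(centre, float))


def mollweide_forward(lat_deg, lon_deg, radius: float = 1.0, tol: float = 1e-12,
                      max_iter: int = 100):
    """Standard Mollweide forward transform (iterative auxiliary angle).

    Solves 2θ + sin 2θ = π sin φ by Newton iteration, then
    x = (2√2/π)·R·λ·cos θ, y = √2·R·sin θ.
    """
    phi = np.radians(np.asarray(lat_deg, float))
    lam = np.radians(np.asarray(lon_deg, float))
    theta = np.array(phi, copy=True)
    target = np.pi * np.sin(phi)
    for _ in range(max_iter):
        f = 2 * theta + np.sin(2 * theta) - target
        df = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(df) > 1e-12, f / np.maximum(df, 1e-12), 0.0)
        theta = theta - step
        if np.max(np.abs(f)) < tol:
            break
    # poles: closed form θ = ±π/2
    pole = np.isclose(np.abs(phi), np.pi / 2)
    theta = np.where(pole, np.sign(phi) * np.pi / 2, theta)
    x = radius * (2.0 * np.sqrt(2.0) / np.pi) * lam * np.cos(theta)
    y = radius * np.sqrt(2.0) * np.sin(theta)
    return x, y


def mollweide_inverse(x, y, radius: float = 1.0):
    """Inverse Mollweide: (x, y) → (latitude°, longitude°)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s = np.clip(y / (radius * np.sqrt(2.0)), -1.0, 1.0)
    theta = np.arcsin(s)
    lat = np.degrees(np.arcsin(np.clip((2 * theta + np.sin(2 * theta)) / np.pi, -1, 1)))
    cos_t = np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        lon = np.degrees(np.pi * x / (2.0 * radius * np.sqrt(2.0) * cos_t))
    lon = np.where(cos_t < 1e-12, 0.0, lon)
    return lat, lon


def render_mollweide(topo_map: TopographyMap, path=None, clim=None,
                     radius: float = 1.0):
    """Project every grid node and (optionally) write a filled-contour image.

    Returns the forward-transform table as a structured array with columns
    (lat, lon, x, y, value) for testing and downstream use.
    """
    glat, glon = np.meshgrid(topo_map.latitudes, topo_map.longitudes, indexing="ij")
    x, y = mollweide_forward(glat.ravel(), glon.ravel(), radius=radius)
    table = np.rec.fromarrays(
        [glat.ravel(), glon.ravel(), x, y, topo_map.values.ravel()],
        names=["lat", "lon", "x", "y", "value"],
    )
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.8),
                               subplot_kw={"projection": "mollweide"})
        vals = np.ma.masked_invalid(topo_map.values)
        pc = ax.pcolormesh(
            np.radians(topo_map.longitudes), np.radians(topo_map.latitudes), vals,
            shading="auto", cmap="RdBu_r",
            vmin=None if clim is None else clim[0],
            vmax=None if clim is None else clim[1],
        )
        fig.colorbar(pc, ax=ax, shrink=0.7, label=topo_map.property)
        ax.grid(alpha=0.3)
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
    return table


def map_similarity(map_a: TopographyMap, map_b: TopographyMap) -> float:
    """Pearson r between two maps over co-unmasked grid nodes."""
    both = ~map_a.mask & ~map_b.mask
    if both.sum() < 3:
        raise ValueError("fewer than 3 co-occupied nodes")
    return _pearson(map_a.values[both], map_b.values[both])
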