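"""Single-trajectory mmPBSA-style binding-energy decomposition.

ΔE_bind = ΔE_vdW + ΔE_elec + ΔE_polar + ΔE_nonpolar, entropy excluded.
The single-trajectory convention reuses the complex geometry for the
separated receptor and ligand, so the molecular-mechanics terms reduce to
the receptor–ligand interaction sums (internal terms cancel exactly).

The polar solvation term is pluggable: imported potential grids (the
faithful route, e.g. from a Poisson–Boltzmann solver) or a built-in
screened-Coulomb distance-dependent-dielectric stand-in that is always
labelled approximate.  Ensemble averages are taken over frames sampled
uniformly without replacement (default 500), mean ± standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_descriptors import sasa
from .structure_io import MolecularSystem, ScalarGrid, Trajectory

__all__ = [
    "COULOMB_KJ_NM",
    "GAMMA_SASA",
    "B_SASA",
    "ClashError",
    "EnergyBreakdown",
    "mm_interaction_energy",
    "nonpolar_sasa_energy",
    "polar_solvation",
    "ensemble_binding_energy",
]

COULOMB_KJ_NM = 138.935458  # kJ·mol⁻¹·nm·e⁻², Coulomb constant in MD units
GAMMA_SASA = 0.0226778  # kJ·mol⁻¹·Å⁻², conventional SASA-model surface tension
B_SASA = 3.84928  # kJ·mol⁻¹, conventional SASA-model offset


class ClashError(ValueError):
    """Two atoms closer than the hard-sphere floor (0.1 Å)."""


@dataclass
class EnergyBreakdown:
    """Table-style ensemble decomposition: mean ± SE per term (kJ/mol)."""

    e_vdw: float
    e_elec: float
    e_polar: float
    e_nonpolar: float
    e_bind: float
    se_vdw: float
    se_elec: float
    se_polar: float
    se_nonpolar: float
    se_bind: float
    n_samples: int
    seed: int
    polar_method: str

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        total = self.e_vdw + self.e_elec + self.e_polar + self.e_nonpolar
        if abs(total - self.e_bind) > 1e-6:
            raise ValueError("binding energy must equal the sum of its components")


def _pair_arrays(system: MolecularSystem, coords: np.ndarray):
    rec = system.atom_indices("receptor")
    lig = system.atom_indices("ligand")
    if rec.size == 0 or lig.size == 0:
        raise ValueError("system must define receptor and ligand segments")
    r = np.linalg.norm(coords[rec][:, None, :] - coords[lig][None, :, :], axis=2)
    if np.any(r < 0.1):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ClashError(
            f"atoms {system.name[rec[i]]}/{system.name[lig[j]]} at {r[i, j]:.3f} Å"
        )
    return rec, lig, r


def mm_interaction_energy(system: MolecularSystem,
                          coords: np.ndarray | None = None) -> tuple[float, float]:
    """Gas-phase receptor–ligand (E_vdw, E_elec) in kJ/mol.

    Lennard-Jones 12-6 with Lorentz–Berthelot combination; Coulomb with
    k_e = 138.935458 kJ·mol⁻¹·nm·e⁻² (distances converted to nm); no cutoff.
    """
    if coords is None:
        coords = system.coords
    rec, lig, r = _pair_arrays(system, coords)
    for arr, what in ((system.partial_charge, "charges"),
                      (system.lj_sigma, "LJ sigma"), (system.lj_epsilon, "LJ epsilon")):
        if np.any(~np.isfinite(arr[np.concatenate([rec, lig])])):
            raise ValueError(f"missing {what} on receptor/ligand atoms")
    sigma = 0.5 * (system.lj_sigma[rec][:, None] + system.lj_sigma[lig][None, :])
    eps = np.sqrt(system.lj_epsilon[rec][:, None] * system.lj_epsilon[lig][None, :])
    sr6 = (sigma / r) ** 6
    e_vdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    qq = system.partial_charge[rec][:, None] * system.partial_charge[lig][None, :]
    e_elec = float(np.sum(COULOMB_KJ_NM * qq / (r / 10.0)))  # Å → nm
    return e_vdw, e_elec


def nonpolar_sasa_energy(system: MolecularSystem, coords: np.ndarray | None = None,
                         gamma: float = GAMMA_SASA, b: float = B_SASA,
                         probe_radius: float = 1.4,
                         n_sphere_points: int = 960) -> float:
    """ΔE_nonpolar = (γ·A + b)_complex − (γ·A + b)_receptor − (γ·A + b)_ligand,
    all areas from the complex geometry (single-trajectory convention)."""
    if coords is None:
        coords = system.coords
    rec = system.atom_indices("receptor")
    lig = system.atom_indices("ligand")
    both = np.concatenate([rec, lig])
    a_complex = sasa(system, coords, probe_radius, n_sphere_points, atom_subset=both).total
    a_rec = sasa(system, coords, probe_radius, n_sphere_points, atom_subset=rec).total
    a_lig = sasa(system, coords, probe_radius, n_sphere_points, atom_subset=lig).total
    return float(gamma * (a_complex - a_rec - a_lig) - b)


def polar_solvation(system: MolecularSystem, coords: np.ndarray | None = None,
                    method: str = "screened", grids: dict | None = None,
                    eps_int: float = 2.0, eps_solv: float = 78.54,
                    lam: float = 3.0) -> float:
    """Polar solvation contribution to binding (kJ/mol).

    ``external_dx``: E_state = ½ Σ q_i φ_state(r_i) per state with trilinear
    grid lookups; ΔE = E_complex − E_receptor − E_ligand.  ``grids`` must map
    {'complex', 'receptor', 'ligand'} to :class:`ScalarGrid` potentials in
    kJ/mol/e.

    ``screened``: APPROXIMATE stand-in — receptor–ligand Coulomb with a
    distance-dependent dielectric ε(r) = ε_int + (ε_solv − ε_int)(1 − e^(−r/λ))
    minus the vacuum reference, i.e. Σ k_e q_i q_j / r · (1/ε(r) − 1).
    """
    if coords is None:
        coords = system.coords
    if method == "external_dx":
        if not grids or set(grids) != {"complex", "receptor", "ligand"}:
            raise ValueError("external_dx needs grids for complex, receptor and ligand")
        rec = system.atom_indices("receptor")
        lig = system.atom_indices("ligand")
        both = np.concatenate([rec, lig])
        q = system.partial_charge

        def state_energy(grid: ScalarGrid, idx):
            phi = grid.interpolate(coords[idx])
            return 0.5 * float(np.sum(q[idx] * phi))

        return (state_energy(grids["complex"], both)
                - state_energy(grids["receptor"], rec)
                - state_energy(grids["ligand"], lig))
    if method == "screened":
        rec, lig, r = _pair_arrays(system, coords)
        qq = system.partial_charge[rec][:, None] * system.partial_charge[lig][None, :]
        eps_r = eps_int + (eps_solv - eps_int) * (1.0 - np.exp(-r / lam))
        return float(np.sum(COULOMB_KJ_NM * qq / (r / 10.0) * (1.0 / eps_r - 1.0)))
    raise ValueError(f"unknown polar method {method!r}")


def ensemble_binding_energy(subtrajectory: Trajectory, n_samples: int = 500,
                            seed: int = 0, polar_method: str = "screened",
                            grids: dict | None = None,
                            gamma: float = GAMMA_SASA, b: float = B_SASA,
                            sasa_points: int = 240) -> EnergyBreakdown:
    """Random-ensemble average of the decomposition over a conformer's frames.

    min(n_samples, n_frames) frames are drawn uniformly without replacement
    with the given seed; per-term mean ± standard error of the mean.
    """
    n_frames = subtrajectory.n_frames
    if n_frames < 1:
        raise ValueError("subtrajectory is empty")
    rng = np.random.default_rng(seed)
    n = min(n_samples, n_frames)
    frames = np.sort(rng.choice(n_frames, size=n, replace=False))
    system = subtrajectory.system
    terms = np.empty((n, 4))
    for row, f in enumerate(frames):
        coords = subtrajectory.coords[f]
        e_vdw, e_elec = mm_interaction_energy(system, coords)
        e_pol = polar_solvation(system, coords, method=polar_method, grids=grids)
        e_np = nonpolar_sasa_energy(system, coords, gamma=gamma, b=b,
                                    n_sphere_points=sasa_points)
        terms[row] = (e_vdw, e_elec, e_pol, e_np)
    means = terms.mean(axis=0)
    if n > 1:
        ses = terms.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        ses = np.zeros(4)
    e_bind = float(means.sum())
    se_bind = (
        float(terms.sum(axis=1).std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    )
    return EnergyBreakdown(
        e_vdw=float(means[0]), e_elec=float(means[1]), e_polar=float(means[2]),
        e_nonpolar=float(means[3]), e_bind=e_bind,
        se_vdw=float(ses[0]), se_elec=float(ses[1]), se_polar=float(ses[2]),
        se_nonpolar=float(ses[3]), se_bind=se_bind,
        n_samples=n, seed=seed, polar_method=polar_method,
    )
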