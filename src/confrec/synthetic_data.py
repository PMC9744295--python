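"""Toy receptor/ligand systems and trajectories with planted metastable states.

Every generator is a pure function of its arguments (seed included), so a
downstream stage can be verified against the planted ground truth: frames are
drawn from a small mixture of von Mises states on the mobile torsions, and
Cartesian coordinates are rebuilt from ideal internal geometry, so the
circular (dihedral) and Cartesian views of the ensemble stay consistent.

The per-atom parameter table shipped with the package is synthetic — it is a
plausible-magnitude stand-in, not a force field.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geom import internal_coords, wrap_degrees
from .structure_io import MolecularSystem, Torsion, ZEntry

__all__ = [
    "StateSpec",
    "SyntheticTruth",
    "WaterPlacementError",
    "make_toy_receptor",
    "make_toy_ligand",
    "make_toy_complex",
    "sample_metastable_trajectory",
    "add_water_bridges",
    "write_truth_labels",
    "read_truth_labels",
]

# ideal internal geometry (Å / degrees) used for every rebuild
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.46, 1.52, 1.33, 1.23, 1.53
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.0, 117.0, 121.0, 121.0, 110.0
_RING_BOND, _RING_ANGLE = 1.45, 120.0


class WaterPlacementError(RuntimeError):
    """Raised when fewer bridging waters could be placed than requested."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"could only place {placed} of {requested} bridging waters at the interface"
        )


@dataclass(frozen=True)
class StateSpec:
    """One planted metastable state over the system's mobile torsions."""

    mean_dihedrals: tuple
    concentration: float
    weight: float

    def __post_init__(self):
        object.__setattr__(self, "mean_dihedrals", tuple(float(a) for a in self.mean_dihedrals))
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        for a in self.mean_dihedrals:
            if not -180.0 <= a < 180.0:
                raise ValueError(f"mean dihedral {a} outside [-180, 180)")


@dataclass
class SyntheticTruth:
    """Planted per-frame state labels — the oracle for recovery tests."""

    frame_labels: np.ndarray
    state_specs: list[StateSpec]
    seed: int

    def __post_init__(self):
        self.frame_labels = np.asarray(self.frame_labels, int)
        k = len(self.state_specs)
        if self.frame_labels.size and (
            self.frame_labels.min() < 0 or self.frame_labels.max() >= k
        ):
            raise ValueError("frame labels outside [0, n_states)")


def _load_param_table():
    table = {}
    path = importlib.resources.files("confrec.data") / "synthetic_params.tsv"
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, atom, elem, q, sig, eps, f, vdw, arom = line.split("\t")
        table[(res, atom)] = dict(
            element=elem, charge=float(q), sigma=float(sig), epsilon=float(eps),
            f=float(f), vdw=float(vdw), aromatic=bool(int(arom)),
        )
    return table


_PARAMS = _load_param_table()


class _Builder:
    """Accumulates atoms / bonds / torsions / z-matrix entries."""

    def __init__(self):
        self.names, self.res_names, self.res_seq, self.chain = [], [], [], []
        self.segment = []
        self.charge, self.sigma, self.eps, self.f, self.vdw = [], [], [], [], []
        self.element, self.aromatic = [], []
        self.bonds, self.torsions, self.zmatrix = [], [], []
        self.mobile = []

    def add_atom(self, name, res_name, res_seq, chain, segment):
        p = _PARAMS[(res_name, name)]
        idx = len(self.names)
        self.names.append(name)
        self.res_names.append(res_name)
        self.res_seq.append(res_seq)
        self.chain.append(chain)
        self.segment.append(segment)
        self.element.append(p["element"])
        self.charge.append(p["charge"])
        self.sigma.append(p["sigma"])
        self.eps.append(p["epsilon"])
        self.f.append(p["f"])
        self.vdw.append(p["vdw"])
        self.aromatic.append(p["aromatic"])
        return idx

    def z(self, index, refs, bond, angle, torsion, torsion_name=None):
        self.zmatrix.append(ZEntry(index, tuple(refs), bond, angle, torsion, torsion_name))

    def build(self) -> MolecularSystem:
        n = len(self.names)
        system = MolecularSystem(
            serial=np.arange(1, n + 1),
            name=np.array(self.names, dtype="U6"),
            element=np.array(self.element, dtype="U2"),
            residue_name=np.array(self.res_names, dtype="U6"),
            residue_seq=np.array(self.res_seq, dtype=int),
            chain_id=np.array(self.chain, dtype="U4"),
            segment=np.array(self.segment, dtype="U8"),
            coords=np.zeros((n, 3)),
            partial_charge=np.array(self.charge, float),
            lj_sigma=np.array(self.sigma, float),
            lj_epsilon=np.array(self.eps, float),
            lipophilicity=np.array(self.f, float),
            vdw_radius=np.array(self.vdw, float),
            aromatic=np.array(self.aromatic, bool),
            bonds=self.bonds,
            torsions=self.torsions,
            mobile_torsions=self.mobile,
            zmatrix=self.zmatrix,
        )
        system.coords = system.rebuild_coords({})
        return system


def _receptor_residue_types(n_residues: int) -> list[str]:
    # guarantees >=2 aromatic and >=2 apolar residues for any n >= 4
    base = ["ARO", "APO", "ARO", "APO"]
    cycle = ["POL", "APO", "ARO", "POL"]
    types = list(base)
    i = 0
    while len(types) < n_residues:
        types.append(cycle[i % len(cycle)])
        i += 1
    return types[:n_residues]


def make_toy_receptor(n_residues: int, seed: int) -> MolecularSystem:
    """A pseudo-peptide chain: N/CA/C/O + one sidechain atom per residue.

    The reference conformation is an extended (β-like) chain with per-seed
    jitter on the backbone torsions.  Backbone φ/ψ are declared mobile so a
    trajectory sampler can plant metastable states on them.
    """
    if n_residues < 4:
        raise ValueError(f"n_residues must be >= 4, got {n_residues}")
    rng = np.random.default_rng(seed)
    types = _receptor_residue_types(n_residues)
    b = _Builder()
    N, CA, C, O, CB = [], [], [], [], []
    for i, res in enumerate(types):
        seq, ch, seg = i + 1, "A", "receptor"
        N.append(b.add_atom("N", res, seq, ch, seg))
        CA.append(b.add_atom("CA", res, seq, ch, seg))
        C.append(b.add_atom("C", res, seq, ch, seg))
        O.append(b.add_atom("O", res, seq, ch, seg))
        side = "OG" if res == "POL" else "CB"
        CB.append(b.add_atom(side, res, seq, ch, seg))
        b.bonds += [(N[i], CA[i]), (CA[i], C[i]), (C[i], O[i]), (CA[i], CB[i])]
        if i > 0:
            b.bonds.append((C[i - 1], N[i]))

    phi_ref = wrap_degrees(-120.0 + rng.uniform(-8, 8, n_residues))
    psi_ref = wrap_degrees(130.0 + rng.uniform(-8, 8, n_residues))

    b.z(N[0], (-1, -1, -1), 0.0, 0.0, 0.0)
    b.z(CA[0], (-1, -1, N[0]), _B_N_CA, 0.0, 0.0)
    b.z(C[0], (-1, N[0], CA[0]), _B_CA_C, _A_N_CA_C, 0.0)
    b.z(CB[0], (C[0], N[0], CA[0]), _B_CA_CB, _A_N_CA_CB, -120.0)
    for i in range(1, n_residues):
        psi_name = f"psi_{i - 1}"
        b.z(N[i], (N[i - 1], CA[i - 1], C[i - 1]), _B_C_N, _A_CA_C_N,
            float(psi_ref[i - 1]), torsion_name=psi_name)
        b.mobile.append(psi_name)
        b.torsions.append(
            Torsion(psi_name, "psi", "receptor", (N[i - 1], CA[i - 1], C[i - 1], N[i]))
        )
        b.z(O[i - 1], (N[i], CA[i - 1], C[i - 1]), _B_C_O, _A_CA_C_O, 180.0)
        b.z(CA[i], (CA[i - 1], C[i - 1], N[i]), _B_N_CA, _A_C_N_CA, 180.0)
        b.torsions.append(
            Torsion(f"omega_{i - 1}", "omega", "receptor",
                    (CA[i - 1], C[i - 1], N[i], CA[i]))
        )
        phi_name = f"phi_{i}"
        b.z(C[i], (C[i - 1], N[i], CA[i]), _B_CA_C, _A_N_CA_C,
            float(phi_ref[i]), torsion_name=phi_name)
        b.mobile.append(phi_name)
        b.torsions.append(
            Torsion(phi_name, "phi", "receptor", (C[i - 1], N[i], CA[i], C[i]))
        )
        b.z(CB[i], (C[i], N[i], CA[i]), _B_CA_CB, _A_N_CA_CB, -120.0)
    b.z(O[-1], (N[-1], CA[-1], C[-1]), _B_C_O, _A_CA_C_O, 0.0)
    return b.build()


def make_toy_ligand(n_units: int, seed: int) -> MolecularSystem:
    """A branched chain of pseudo-sugar rings.

    Each ring is a planar hexagon (C4-C5-O5-C1-C2-C3) with an exocyclic
    apolar carbon (C6) and two hydroxyl-like oxygens (O2, O3).  Units attach
    in a binary-tree topology through a glycosidic-like C1/C3-OL-C4 linkage;
    the inter-unit φ (O5-C1-OL-C4') and ψ (C1-OL-C4'-C5') torsions are the
    mobile degrees of freedom, so ``n_units`` rings carry ``n_units - 1``
    torsion pairs.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    rng = np.random.default_rng(seed)
    b = _Builder()
    ring = []  # per unit: dict of atom indices

    def add_ring(seq):
        seg, ch = "ligand", "B"
        r = {a: b.add_atom(a, "SUG", seq, ch, seg) for a in
             ("C4", "C5", "O5", "C1", "C2", "C3", "C6", "O2", "O3")}
        b.bonds += [
            (r["C4"], r["C5"]), (r["C5"], r["O5"]), (r["O5"], r["C1"]),
            (r["C1"], r["C2"]), (r["C2"], r["C3"]), (r["C3"], r["C4"]),
            (r["C5"], r["C6"]), (r["C2"], r["O2"]), (r["C3"], r["O3"]),
        ]
        return r

    def ring_zmatrix(r, after_c5_torsion=120.0):
        # ring closes exactly: equal bonds, 120° angles, planar torsions
        b.z(r["O5"], (r["C6"], r["C4"], r["C5"]), _RING_BOND, _RING_ANGLE, 180.0)
        b.z(r["C1"], (r["C4"], r["C5"], r["O5"]), _RING_BOND, _RING_ANGLE, 0.0)
        b.z(r["C2"], (r["C5"], r["O5"], r["C1"]), _RING_BOND, _RING_ANGLE, 0.0)
        b.z(r["C3"], (r["O5"], r["C1"], r["C2"]), _RING_BOND, _RING_ANGLE, 0.0)
        b.z(r["O2"], (r["O5"], r["C1"], r["C2"]), 1.42, 110.0, 120.0)
        b.z(r["O3"], (r["C1"], r["C2"], r["C3"]), 1.42, 110.0, 120.0)

    r0 = add_ring(1)
    ring.append(r0)
    b.z(r0["C4"], (-1, -1, -1), 0.0, 0.0, 0.0)
    b.z(r0["C5"], (-1, -1, r0["C4"]), _RING_BOND, 0.0, 0.0)
    b.z(r0["C6"], (-1, r0["C4"], r0["C5"]), 1.52, 110.0, 120.0)
    ring_zmatrix(r0)

    phi_ref = wrap_degrees(rng.uniform(-75, -45, max(n_units - 1, 1)))
    psi_ref = wrap_degrees(rng.uniform(100, 140, max(n_units - 1, 1)))

    for u in range(1, n_units):
        parent = ring[(u - 1) // 2]
        site = "C1" if (u - 1) % 2 == 0 else "C3"
        anchor = parent[site]
        prev2 = parent["O5"] if site == "C1" else parent["C2"]
        prev3 = parent["C2"] if site == "C1" else parent["C1"]
        seq = u + 1
        ol = b.add_atom("OL", "SUG", seq, "B", "ligand")
        r = add_ring(seq)
        ring.append(r)
        b.bonds += [(anchor, ol), (ol, r["C4"])]
        # OL orientation about the parent ring is fixed; φ/ψ rotate the child
        b.z(ol, (prev3, prev2, anchor), 1.41, 117.0, -60.0)
        phi_name, psi_name = f"gphi_{u}", f"gpsi_{u}"
        b.z(r["C4"], (prev2, anchor, ol), 1.41, 117.0, float(phi_ref[u - 1]),
            torsion_name=phi_name)
        b.z(r["C5"], (anchor, ol, r["C4"]), _RING_BOND, 112.0, float(psi_ref[u - 1]),
            torsion_name=psi_name)
        b.z(r["C6"], (ol, r["C4"], r["C5"]), 1.52, 110.0, -120.0)
        ring_zmatrix(r)
        b.mobile += [phi_name, psi_name]
        b.torsions.append(Torsion(phi_name, "phi", "ligand",
                                  (prev2, anchor, ol, r["C4"])))
        b.torsions.append(Torsion(psi_name, "psi", "ligand",
                                  (anchor, ol, r["C4"], r["C5"])))
    return b.build()


def _rotation_between(u, v):
    """Proper rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180°: rotate about any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def make_toy_complex(receptor: MolecularSystem, ligand: MolecularSystem,
                     gap: float = 3.0) -> MolecularSystem:
    """Dock the toy ligand into a shallow pocket on the receptor surface.

    The ligand is rigidly placed so its root ring sits ``gap`` Å outside the
    sidechain atom of the middle receptor residue, oriented away from the
    receptor centroid.  The merged internal-coordinate template roots the
    ligand on that sidechain, so complex trajectories can still be rebuilt
    from torsions (the ligand rides the receptor anchor).
    """
    n_rec = receptor.n_atoms
    res_keys = receptor.residue_keys("receptor")
    centroid = receptor.coords.mean(axis=0)

    # pocket mouth: the most surface-exposed sidechain, preferring polar
    # (hydroxyl-bearing) residues so hydrogen-bond partners exist; exposure =
    # few receptor atoms sticking out beyond the anchor along its outward axis
    def exposure(res_i):
        idx = receptor.residue_atoms(res_keys[res_i])
        names = list(receptor.name[idx])
        side = "OG" if "OG" in names else ("CB" if "CB" in names else names[-1])
        a = int(idx[names.index(side)])
        out = receptor.coords[a] - centroid
        nrm = np.linalg.norm(out)
        if nrm < 1e-9:
            return a, np.array([1.0, 0.0, 0.0]), receptor.n_atoms
        out = out / nrm
        proj = (receptor.coords - receptor.coords[a]) @ out
        return a, out, int((proj > 1.0).sum())

    middle = len(res_keys) // 2
    polar_res = [
        i for i, key in enumerate(res_keys)
        if "OG" in receptor.name[receptor.residue_atoms(key)]
    ]
    candidates = polar_res if polar_res else list(range(len(res_keys)))
    scored = sorted(
        ((exposure(i)[2], abs(i - middle), i) for i in candidates)
    )
    pick = scored[0][2]
    mid = res_keys[pick]
    res_idx = receptor.residue_atoms(mid)
    names = receptor.name[res_idx]
    anchor, outward, _ = exposure(pick)
    ca = int(res_idx[list(names).index("CA")])
    nn = int(res_idx[list(names).index("N")])

    # rigid placement of the ligand reference coordinates: root at the pocket
    # mouth, then a deterministic orientation scan that maximises polar
    # (H-bond-capable) contacts while keeping a clash-free pose
    root = 0  # ligand atom 0 is C4 of the root ring
    base = ligand.coords - ligand.coords[root]
    axis = base.mean(axis=0)
    if np.linalg.norm(axis) < 1e-8:
        axis = np.array([1.0, 0.0, 0.0])
    base = base @ _rotation_between(axis, outward).T
    target = receptor.coords[anchor] + gap * outward
    e1 = np.cross(outward, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(outward, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    rec_xyz = receptor.coords
    rec_polar = rec_xyz[receptor.is_polar]
    lig_polar_mask = ligand.is_polar
    rec_apolar = rec_xyz[receptor.is_apolar_carbon]
    lig_apolar_mask = ligand.is_apolar_carbon

    def axis_rot(u, deg):
        th = np.radians(deg)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)

    best, best_score = None, -np.inf
    fallback, fallback_dmin = None, -np.inf
    for extra_gap in (0.0, 1.0, 2.0):
        shifted_target = target + extra_gap * outward
        for azim in range(0, 360, 30):
            for tilt in (0, 15, 30, 45, 60, 75):
                R = axis_rot(e1, tilt) @ axis_rot(outward, azim)
                cand = base @ R.T + shifted_target
                d_all = np.linalg.norm(cand[:, None, :] - rec_xyz[None, :, :], axis=2)
                dmin = d_all.min()
                if dmin > fallback_dmin:
                    fallback, fallback_dmin = cand, dmin
                if dmin < 2.6:
                    continue
                dp = np.linalg.norm(
                    cand[lig_polar_mask][:, None, :] - rec_polar[None, :, :], axis=2
                )
                da = np.linalg.norm(
                    cand[lig_apolar_mask][:, None, :] - rec_apolar[None, :, :], axis=2
                )
                score = ((dp <= 3.4).sum() + 0.5 * (da <= 4.0).sum()
                         + 0.2 * (dp <= 5.0).sum() - abs(dmin - 3.0))
                if score > best_score:
                    best, best_score = cand, score
        if best is not None:
            break
    lig_coords = best if best is not None else fallback

    b = _Builder()
    for i in range(n_rec):
        b.add_atom(str(receptor.name[i]), str(receptor.residue_name[i]),
                   int(receptor.residue_seq[i]), str(receptor.chain_id[i]), "receptor")
    for i in range(ligand.n_atoms):
        b.add_atom(str(ligand.name[i]), str(ligand.residue_name[i]),
                   int(ligand.residue_seq[i]), "B", "ligand")
    b.bonds = list(receptor.bonds) + [(i + n_rec, j + n_rec) for i, j in ligand.bonds]
    b.torsions = list(receptor.torsions) + [
        Torsion(t.name, t.kind, t.segment, tuple(a + n_rec for a in t.atoms))
        for t in ligand.torsions
    ]
    b.mobile = list(receptor.mobile_torsions) + list(ligand.mobile_torsions)

    b.zmatrix = list(receptor.zmatrix)
    # re-root the ligand's first three z-entries on the receptor anchor triad
    lig_z = ligand.zmatrix
    first_three = [lig_z[0].index, lig_z[1].index, lig_z[2].index]
    refs_sets = [
        (nn, ca, anchor),
        (ca, anchor, first_three[0] + n_rec),
        (anchor, first_three[0] + n_rec, first_three[1] + n_rec),
    ]
    for k in range(3):
        refs = refs_sets[k]
        coords_refs = [
            receptor.coords[r] if r < n_rec else lig_coords[r - n_rec] for r in refs
        ]
        bond, angle, tors = internal_coords(*coords_refs, lig_coords[first_three[k]])
        b.zmatrix.append(ZEntry(first_three[k] + n_rec, refs, bond, angle, tors))
    for entry in lig_z[3:]:
        b.zmatrix.append(ZEntry(
            entry.index + n_rec, tuple(r + n_rec for r in entry.refs),
            entry.bond, entry.angle, entry.torsion, entry.torsion_name,
        ))
    system = b.build()
    return system


def sample_metastable_trajectory(system: MolecularSystem, states, n_frames: int,
                                 noise_sd: float, seed: int):
    """Draw frames from a mixture of von Mises states on the mobile torsions.

    Each frame's state is drawn categorically by weight; its mobile torsions
    are drawn independently from von Mises distributions centred on that
    state's means (``concentration = inf`` means the exact mean — the fully
    degenerate ensemble); Cartesian coordinates are rebuilt from the
    internal-coordinate template, then isotropic Gaussian jitter of
    ``noise_sd`` Å is added to every atom.

    Returns ``(Trajectory, SyntheticTruth)``.
    """
    from .structure_io import Trajectory

    states = list(states)
    weights = np.array([s.weight for s in states], float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"state weights must sum to 1, got {weights.sum()}")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not system.mobile_torsions:
        raise ValueError("system has no mobile torsions")
    if system.zmatrix is None:
        raise ValueError("system has no internal-coordinate template to rebuild from")
    n_torsions = len(system.mobile_torsions)
    for s in states:
        if len(s.mean_dihedrals) != n_torsions:
            raise ValueError(
                f"state specifies {len(s.mean_dihedrals)} dihedrals, "
                f"system has {n_torsions} mobile torsions"
            )
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(states), size=n_frames, p=weights)
    means = np.array([s.mean_dihedrals for s in states])  # (k, T) degrees
    kappas = np.array([s.concentration for s in states])
    angles = np.empty((n_frames, n_torsions))
    finite = np.isfinite(kappas)
    mu = np.radians(means[labels])
    if finite.all():
        angles = np.degrees(rng.vonmises(mu, kappas[labels][:, None]))
    else:
        angles = np.degrees(mu)
        mask = finite[labels]
        if mask.any():
            angles[mask] = np.degrees(
                rng.vonmises(mu[mask], kappas[labels[mask]][:, None])
            )
    angles = wrap_degrees(angles)

    coords = np.empty((n_frames, system.n_atoms, 3))
    tnames = system.mobile_torsions
    for f in range(n_frames):
        coords[f] = system.rebuild_coords(dict(zip(tnames, angles[f])))
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    traj = Trajectory(coords=coords, frame_times=np.arange(n_frames, dtype=float),
                      system=system)
    truth = SyntheticTruth(frame_labels=labels, state_specs=states, seed=seed)
    return traj, truth


def add_water_bridges(complex_system: MolecularSystem, n_waters: int, seed: int,
                      d_hbond: float = 3.5) -> MolecularSystem:
    """Place 3-site waters whose oxygen simultaneously lies within H-bond
    distance of one receptor polar atom and one ligand polar atom.

    Water oxygens go at the midpoint of eligible receptor/ligand polar pairs
    (pair gap in (2·2.4, 2·d_hbond) Å), hydrogens point toward each partner.
    Raises :class:`WaterPlacementError` if fewer than ``n_waters`` disjoint
    placements exist.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be non-negative")
    segs = set(complex_system.segment)
    if not {"receptor", "ligand"} <= segs:
        raise ValueError("complex must contain receptor and ligand segments")
    if n_waters == 0:
        return complex_system.replace(coords=complex_system.coords.copy())

    polar = complex_system.is_polar
    rec = np.where((complex_system.segment == "receptor") & polar)[0]
    lig = np.where((complex_system.segment == "ligand") & polar)[0]
    coords = complex_system.coords
    pairs = []
    for i in rec:
        d = np.linalg.norm(coords[lig] - coords[i], axis=1)
        for j, dij in zip(lig, d):
            if 4.8 <= dij <= 2 * d_hbond:
                pairs.append((float(dij), int(i), int(j)))
    rng = np.random.default_rng(seed)
    order = sorted(pairs)  # nearest interfaces first, then seed-shuffled ties
    rng.shuffle(order)
    order.sort(key=lambda p: round(p[0], 1))
    placed = []
    for dij, i, j in order:
        o = 0.5 * (coords[i] + coords[j])
        if any(np.linalg.norm(o - prev[0]) < 1.5 for prev in placed):
            continue
        h1 = o + 0.96 * (coords[i] - o) / np.linalg.norm(coords[i] - o)
        h2 = o + 0.96 * (coords[j] - o) / np.linalg.norm(coords[j] - o)
        placed.append((o, h1, h2))
        if len(placed) == n_waters:
            break
    if len(placed) < n_waters:
        raise WaterPlacementError(n_waters, len(placed))

    b = _Builder()
    for i in range(complex_system.n_atoms):
        b.add_atom(str(complex_system.name[i]), str(complex_system.residue_name[i]),
                   int(complex_system.residue_seq[i]), str(complex_system.chain_id[i]),
                   str(complex_system.segment[i]))
    new_coords = [complex_system.coords]
    for w, (o, h1, h2) in enumerate(placed):
        seq = w + 1
        io = b.add_atom("O", "HOH", seq, "W", "water")
        ih1 = b.add_atom("H1", "HOH", seq, "W", "water")
        ih2 = b.add_atom("H2", "HOH", seq, "W", "water")
        b.bonds += [(io, ih1), (io, ih2)]
        new_coords.append(np.array([o, h1, h2]))
    b.bonds = list(complex_system.bonds) + b.bonds
    b.torsions = list(complex_system.torsions)
    b.mobile = list(complex_system.mobile_torsions)
    b.zmatrix = None  # waters are not part of the torsion template
    out = MolecularSystem(
        serial=np.arange(1, len(b.names) + 1),
        name=np.array(b.names, dtype="U6"),
        element=np.array(b.element, dtype="U2"),
        residue_name=np.array(b.res_names, dtype="U6"),
        residue_seq=np.array(b.res_seq, dtype=int),
        chain_id=np.array(b.chain, dtype="U4"),
        segment=np.array(b.segment, dtype="U8"),
        coords=np.vstack(new_coords),
        partial_charge=np.array(b.charge, float),
        lj_sigma=np.array(b.sigma, float),
        lj_epsilon=np.array(b.eps, float),
        lipophilicity=np.array(b.f, float),
        vdw_radius=np.array(b.vdw, float),
        aromatic=np.array(b.aromatic, bool),
        bonds=b.bonds,
        torsions=b.torsions,
        mobile_torsions=b.mobile,
        zmatrix=None,
    )
    return out


def write_truth_labels(path, truth: SyntheticTruth):
    """Two-column plain text: frame index, planted state id."""
    with open(path, "w") as fh:
        fh.write("# frame\tstate\n")
        for i, lab in enumerate(truth.frame_labels):
            fh.write(f"{i}\t{int(lab)}\n")


def read_truth_labels(path) -> np.ndarray:
    labels = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            labels.append(int(line.split()[1]))
    return np.asarray(labels, int)
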