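"""Core molecular data model and the plain-text formats the pipeline touches.

Unit discipline (asserted here, never converted implicitly elsewhere):
lengths in Å, energies in kJ/mol, charges in elementary charge units (e),
times in ps.

Structures and multi-model trajectories travel as PDB (via biotite),
per-atom charges/radii as PQR, scalar potential grids as OpenDX ``.dx``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ._geom import place_atom

__all__ = [
    "FormatError",
    "Torsion",
    "ZEntry",
    "MolecularSystem",
    "Trajectory",
    "ScalarGrid",
    "ResiduePositionMap",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "write_pqr",
    "read_dx",
    "write_dx",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Torsion:
    """A named torsion quadruple (atom indices) with its class and owner."""

    name: str
    kind: str  # phi | psi | chi | omega
    segment: str  # receptor | ligand
    atoms: tuple[int, int, int, int]


@dataclass(frozen=True)
class ZEntry:
    """One internal-coordinate record: atom placed w.r.t. three references.

    ``torsion_name`` marks mobile torsions; fixed entries carry the numeric
    ``torsion`` only.  The first three atoms of a system use sentinel
    references (-1) and are placed canonically.
    """

    index: int
    refs: tuple[int, int, int]
    bond: float
    angle: float
    torsion: float
    torsion_name: str | None = None


@dataclass
class MolecularSystem:
    """Static topology: atoms, parameters, bonds and torsion definitions."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_seq: np.ndarray
    chain_id: np.ndarray
    segment: np.ndarray  # receptor | ligand | water
    coords: np.ndarray  # (n_atoms, 3) Å, reference frame
    partial_charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    lipophilicity: np.ndarray
    vdw_radius: np.ndarray
    aromatic: np.ndarray = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    torsions: list[Torsion] = field(default_factory=list)
    mobile_torsions: list[str] = field(default_factory=list)
    zmatrix: list[ZEntry] | None = None

    def __post_init__(self):
        n = self.n_atoms
        if self.aromatic is None:
            self.aromatic = np.zeros(n, dtype=bool)
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.lj_sigma[np.isfinite(self.lj_sigma)] <= 0):
            raise ValueError("lj_sigma must be positive")
        keys = list(zip(self.chain_id, self.residue_seq, self.name))
        if len(set(keys)) != n:
            raise ValueError("atoms must be unique by (chain, residue_seq, name)")
        for t in self.torsions:
            if any(i < 0 or i >= n for i in t.atoms):
                raise ValueError(f"torsion {t.name} indexes a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def net_charge(self) -> float:
        return float(np.nansum(self.partial_charge))

    def atom_indices(self, segment: str | None = None) -> np.ndarray:
        if segment is None:
            return np.arange(self.n_atoms)
        return np.where(self.segment == segment)[0]

    def residue_keys(self, segment: str | None = None) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_seq) keys."""
        idx = self.atom_indices(segment)
        seen, out = set(), []
        for i in idx:
            key = (str(self.chain_id[i]), int(self.residue_seq[i]))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_atoms(self, key: tuple[str, int]) -> np.ndarray:
        chain, seq = key
        return np.where((self.chain_id == chain) & (self.residue_seq == seq))[0]

    @property
    def is_polar(self) -> np.ndarray:
        """Hydrogen-bond-capable heavy atoms (N or O)."""
        return np.isin(self.element, ("N", "O"))

    @property
    def is_apolar_carbon(self) -> np.ndarray:
        """Carbons with no bonded N/O/S (bond list required, else bare C)."""
        apolar = self.element == "C"
        if self.bonds:
            polar_nbr = np.zeros(self.n_atoms, dtype=bool)
            for i, j in self.bonds:
                if self.element[j] in ("N", "O", "S"):
                    polar_nbr[i] = True
                if self.element[i] in ("N", "O", "S"):
                    polar_nbr[j] = True
            apolar = apolar & ~polar_nbr
        return apolar

    def torsion_by_name(self, name: str) -> Torsion:
        for t in self.torsions:
            if t.name == name:
                return t
        raise KeyError(f"no torsion named {name!r}")

    def rebuild_coords(self, torsion_values: dict[str, float]) -> np.ndarray:
        """Rebuild Cartesian coordinates from the internal-coordinate template,
        overriding named mobile torsions (degrees)."""
        if self.zmatrix is None:
            raise ValueError("system carries no internal-coordinate template")
        coords = np.zeros((self.n_atoms, 3))
        for k, entry in enumerate(self.zmatrix):
            tor = entry.torsion
            if entry.torsion_name is not None and entry.torsion_name in torsion_values:
                tor = torsion_values[entry.torsion_name]
            i = entry.index
            if k == 0:
                coords[i] = 0.0
            elif k == 1:
                coords[i] = (entry.bond, 0.0, 0.0)
            elif k == 2:
                b = coords[entry.refs[2]]
                a = coords[entry.refs[1]]
                coords[i] = place_atom(a + (0, 0, 1.0), a, b, entry.bond, entry.angle, tor)
            else:
                a, bb, c = (coords[r] for r in entry.refs)
                coords[i] = place_atom(a, bb, c, entry.bond, entry.angle, tor)
        return coords

    def replace(self, **changes) -> "MolecularSystem":
        return dataclasses.replace(self, **changes)


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with strictly increasing times (ps)."""

    coords: np.ndarray
    frame_times: np.ndarray
    system: MolecularSystem

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.frame_times = np.asarray(self.frame_times, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.system.n_atoms:
            raise ValueError("trajectory atom count does not match system")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")
        if len(self.frame_times) != self.n_frames:
            raise ValueError("frame_times length mismatch")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def subset(self, frame_indices: Sequence[int]) -> "Trajectory":
        idx = np.asarray(frame_indices, int)
        return Trajectory(self.coords[idx], self.frame_times[idx], self.system)


@dataclass
class ScalarGrid:
    """Regular scalar field: origin (Å), per-axis spacing (Å) and counts."""

    origin: np.ndarray
    spacing: np.ndarray
    counts: tuple[int, int, int]
    values: np.ndarray  # shape == counts

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.shape != tuple(self.counts):
            raise FormatError(
                f"grid value count {self.values.size} does not match counts {self.counts}"
            )

    def axes(self):
        return [
            self.origin[d] + self.spacing[d] * np.arange(self.counts[d])
            for d in range(3)
        ]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear lookup at arbitrary points (Å); raises if out of grid."""
        pts = np.atleast_2d(np.asarray(points, float))
        interp = RegularGridInterpolator(
            self.axes(), self.values, method="linear", bounds_error=False
        )
        out = interp(pts)
        oob = np.isnan(out)
        if np.any(oob):
            raise ValueError(f"{int(oob.sum())} point(s) outside the grid")
        return out if np.asarray(points).ndim > 1 else float(out[0])


@dataclass
class ResiduePositionMap:
    """Ordered labels (e.g. RP1..RP14) → (chain_id, residue_seq)."""

    labels: list[str]
    mapping: dict[str, tuple[str, int]]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("residue-position labels must be unique")
        for lab in self.labels:
            if lab not in self.mapping:
                raise ValueError(f"label {lab} has no mapped residue")

    def validate(self, system: MolecularSystem):
        keys = set(system.residue_keys())
        for lab in self.labels:
            if tuple(self.mapping[lab]) not in keys:
                raise ValueError(f"label {lab} maps to a residue absent from the system")

    def label_of(self, key: tuple[str, int]) -> str | None:
        for lab in self.labels:
            if tuple(self.mapping[lab]) == tuple(key):
                return lab
        return None


# ---------------------------------------------------------------------------
# PDB

_DEFAULT_SEGMENT_BY_CHAIN = None


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA"):
        # two-letter elements only when the name is exactly that element
        if stripped.upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
            return stripped.capitalize()
    return stripped[0].upper()


def _segment_for(chain: str, resname: str, segment_map: dict | None) -> str:
    if segment_map and chain in segment_map:
        return segment_map[chain]
    if resname.strip() in WATER_RESNAMES:
        return "water"
    if chain in ("B", "L"):
        return "ligand"
    return "receptor"


def read_pdb(path, model_handling: str = "first", segment_map: dict | None = None):
    """Read a (multi-model) PDB file.

    Returns a :class:`MolecularSystem` for ``model_handling='first'`` or a
    ``(MolecularSystem, Trajectory)`` pair for ``'all'``.  MODEL records
    become frames; elements are inferred from atom names when the element
    column is blank.  Segment tags come from ``segment_map`` (chain → tag)
    with a water-residue / chain-id fallback.
    """
    if model_handling not in ("first", "all"):
        raise ValueError("model_handling must be 'first' or 'all'")
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on per-model atom-count mismatch
        raise FormatError(f"inconsistent PDB models in {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    n = stack.array_length()
    elements = np.array(
        [
            e.capitalize() if e.strip() else _infer_element(nm)
            for e, nm in zip(stack.element, stack.atom_name)
        ],
        dtype="U2",
    )
    chains = np.array([c if c.strip() else "A" for c in stack.chain_id], dtype="U4")
    segments = np.array(
        [
            _segment_for(c, rn, segment_map)
            for c, rn in zip(chains, stack.res_name)
        ],
        dtype="U8",
    )
    nanv = np.full(n, np.nan)
    system = MolecularSystem(
        serial=np.arange(1, n + 1),
        name=np.array(stack.atom_name, dtype="U6"),
        element=elements,
        residue_name=np.array(stack.res_name, dtype="U6"),
        residue_seq=np.array(stack.res_id, dtype=int),
        chain_id=chains,
        segment=segments,
        coords=np.asarray(stack.coord[0], float),
        partial_charge=nanv.copy(),
        lj_sigma=nanv.copy(),
        lj_epsilon=nanv.copy(),
        lipophilicity=nanv.copy(),
        vdw_radius=nanv.copy(),
    )
    if model_handling == "first":
        return system
    nframes = stack.stack_depth()
    traj = Trajectory(
        coords=np.asarray(stack.coord, float),
        frame_times=np.arange(nframes, dtype=float),
        system=system,
    )
    return system, traj


def write_pdb(path, system: MolecularSystem, trajectory: Trajectory | None = None):
    """Write the system (or every trajectory frame as MODEL records) as PDB."""
    n = system.n_atoms
    if trajectory is not None:
        coords = trajectory.coords
    else:
        coords = system.coords[None, :, :]
    atoms = struc.AtomArray(n)
    atoms.chain_id = np.array(system.chain_id, dtype="U4")
    atoms.res_id = np.array(system.residue_seq, dtype=int)
    atoms.res_name = np.array(system.residue_name, dtype="U5")
    atoms.atom_name = np.array(system.name, dtype="U6")
    atoms.element = np.array(system.element, dtype="U2")
    atoms.hetero = np.array(system.segment != "receptor")
    if coords.shape[0] == 1:
        atoms.coord = coords[0]
        structure = atoms
    else:
        structure = struc.stack([atoms] * coords.shape[0])
        structure.coord = coords
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# PQR


def read_pqr(path, system: MolecularSystem | None = None):
    """Read a whitespace-delimited PQR file.

    Standalone: returns ``(records, None)`` where records is a list of dicts.
    With ``system``: merges charge/radius onto matching atoms
    (chain, residue_seq, name) and returns ``(system, unmatched)`` where
    ``unmatched`` lists system atom indices that found no PQR record.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            # chain id is optional in PQR: 11 fields with, 10 without
            if len(fields) == 11:
                _, serial, name, resname, chain, resseq, x, y, z, q, r = fields
            elif len(fields) == 10:
                _, serial, name, resname, resseq, x, y, z, q, r = fields
                chain = ""
            else:
                raise FormatError(f"{path}:{lineno}: unexpected field count {len(fields)}")
            try:
                charge = float(q)
                radius = float(r)
                resseq_i = int(resseq)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric charge/radius") from exc
            if radius < 0:
                raise FormatError(f"{path}:{lineno}: negative radius")
            records.append(
                dict(name=name, residue_name=resname, chain_id=chain,
                     residue_seq=resseq_i, charge=charge, radius=radius,
                     coords=(float(x), float(y), float(z)))
            )
    if not records:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    if system is None:
        return records, None
    lookup = {}
    for rec in records:
        lookup[(rec["chain_id"], rec["residue_seq"], rec["name"])] = rec
        lookup.setdefault((rec["residue_seq"], rec["name"]), rec)
    unmatched = []
    charge = system.partial_charge.copy()
    radius = system.vdw_radius.copy()
    for i in range(system.n_atoms):
        key3 = (str(system.chain_id[i]), int(system.residue_seq[i]), str(system.name[i]))
        rec = lookup.get(key3) or lookup.get(key3[1:])
        if rec is None:
            unmatched.append(i)
            continue
        charge[i] = rec["charge"]
        radius[i] = rec["radius"]
    if unmatched:
        warnings.warn(f"{len(unmatched)} atom(s) had no matching PQR record")
    merged = system.replace(partial_charge=charge, vdw_radius=radius)
    return merged, unmatched


def write_pqr(path, system: MolecularSystem):
    with open(path, "w") as fh:
        for i in range(system.n_atoms):
            q = system.partial_charge[i]
            r = system.vdw_radius[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<4s}{chain:1s}{seq:>5d}    "
                "{x:8.3f} {y:8.3f} {z:8.3f} {q:8.4f} {r:7.4f}\n".format(
                    serial=int(system.serial[i]),
                    name=str(system.name[i]),
                    res=str(system.residue_name[i]),
                    chain=str(system.chain_id[i])[:1] or "A",
                    seq=int(system.residue_seq[i]),
                    x=system.coords[i, 0], y=system.coords[i, 1], z=system.coords[i, 2],
                    q=0.0 if np.isnan(q) else q,
                    r=0.0 if np.isnan(r) else r,
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def read_dx(path) -> ScalarGrid:
    """Read an OpenDX scalar grid (gridpositions/gridconnections/array dialect).

    Values are stored x-major (z fastest), matching APBS/pyMLP output.
    """
    counts = origin = None
    deltas = []
    values = []
    n_expected = None
    with open(path) as fh:
        for line in fh:
            ls = line.strip()
            if not ls or ls.startswith("#"):
                continue
            if ls.startswith("object") and "gridpositions" in ls:
                counts = tuple(int(t) for t in ls.split()[-3:])
            elif ls.startswith("origin"):
                origin = [float(t) for t in ls.split()[1:4]]
            elif ls.startswith("delta"):
                deltas.append([float(t) for t in ls.split()[1:4]])
            elif ls.startswith("object") and "class array" in ls:
                toks = ls.split()
                n_expected = int(toks[toks.index("items") + 1])
            elif ls.startswith(("object", "attribute", "component", "end")):
                continue
            else:
                try:
                    values.extend(float(t) for t in ls.split())
                except ValueError as exc:
                    raise FormatError(f"non-numeric grid data in {path}: {ls!r}") from exc
    if counts is None or origin is None or len(deltas) != 3:
        raise FormatError(f"missing grid header in {path}")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    n_vals = int(np.prod(counts))
    if n_expected is not None and n_expected != n_vals:
        raise FormatError(f"header declares {n_expected} items but grid needs {n_vals}")
    if len(values) != n_vals:
        raise FormatError(
            f"grid value count mismatch in {path}: got {len(values)}, need {n_vals}"
        )
    data = np.array(values).reshape(counts)
    return ScalarGrid(origin=np.array(origin), spacing=spacing, counts=counts, values=data)


def write_dx(path, grid: ScalarGrid, comment: str = "scalar grid"):
    nx, ny, nz = grid.counts
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = grid.values.reshape(-1)
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
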