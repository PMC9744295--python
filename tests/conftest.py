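"""Shared fixtures: toy systems, trajectories and an ad-hoc system factory."""

from __future__ import annotations

import numpy as np
import pytest

from confrec import synthetic_data as syn
from confrec.structure_io import MolecularSystem, Trajectory


@pytest.fixture(scope="session")
def receptor():
    return syn.make_toy_receptor(10, seed=1)


@pytest.fixture(scope="session")
def ligand():
    return syn.make_toy_ligand(3, seed=7)


@pytest.fixture(scope="session")
def complex_system(receptor, ligand):
    return syn.make_toy_complex(receptor, ligand)


@pytest.fixture(scope="session")
def watered_complex(complex_system):
    return syn.add_water_bridges(complex_system, 2, seed=5)


def _three_state_specs(system, separation=90.0, concentration=100.0,
                       weights=(0.5, 0.3, 0.2)):
    base = {z.torsion_name: z.torsion for z in system.zmatrix if z.torsion_name}
    ref = np.array([base[n] for n in system.mobile_torsions])
    specs = []
    for s, w in enumerate(weights):
        m = ref.copy()
        m[-3:] = m[-3:] + s * separation
        specs.append(syn.StateSpec(tuple(syn.wrap_degrees(m)), concentration, w))
    return specs


@pytest.fixture(scope="session")
def three_state_specs(receptor):
    return _three_state_specs(receptor)


@pytest.fixture(scope="session")
def planted_trajectory(receptor, three_state_specs):
    """600-frame free-receptor trajectory with 3 planted states."""
    return syn.sample_metastable_trajectory(receptor, three_state_specs,
                                            n_frames=600, noise_sd=0.05, seed=42)


def make_system(coords, elements=None, charges=None, radii=None, sigmas=None,
                epsilons=None, lipophilicity=None, segments=None, bonds=None,
                names=None):
    """Ad-hoc system: one pseudo-residue per atom, everything overridable."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]

    def arr(x, default):
        if x is None:
            return np.full(n, default, float)
        return np.asarray(x, float)

    elements = np.array(elements if elements is not None else ["C"] * n, dtype="U2")
    segments = np.array(segments if segments is not None else ["receptor"] * n,
                        dtype="U8")
    names = np.array(names if names is not None else [f"X{i}" for i in range(n)],
                     dtype="U6")
    return MolecularSystem(
        serial=np.arange(1, n + 1),
        name=names,
        element=elements,
        residue_name=np.array(["UNK"] * n, dtype="U6"),
        residue_seq=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n, dtype="U4"),
        segment=segments,
        coords=coords,
        partial_charge=arr(charges, 0.0),
        lj_sigma=arr(sigmas, 3.4),
        lj_epsilon=arr(epsilons, 0.4),
        lipophilicity=arr(lipophilicity, 0.0),
        vdw_radius=arr(radii, 1.7),
        bonds=bonds or [],
    )


def make_trajectory(coords_stack, system=None, **kwargs):
    coords_stack = np.asarray(coords_stack, float)
    if system is None:
        system = make_system(coords_stack[0], **kwargs)
    return Trajectory(coords=coords_stack,
                      frame_times=np.arange(coords_stack.shape[0], dtype=float),
                      system=system)


@pytest.fixture
def system_factory():
    return make_system


@pytest.fixture
def trajectory_factory():
    return make_trajectory
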