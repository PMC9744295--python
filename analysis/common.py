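"""Shared world definition for the numbered analysis scripts.

Every script rebuilds the same synthetic study deterministically from this
configuration, so the scripts can run independently and in any order.
"""

from pathlib import Path

from confrec.pipeline import RunConfig, _state_specs, stage_seed
from confrec import synthetic_data as syn

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

CONFIG = RunConfig(
    n_residues=12, n_units=3, n_states=3, n_frames=600,
    noise_sd=0.05, concentration=800.0, separation=90.0,
    n_waters=2, seed=2025, outdir=str(SCRATCH / "analysis_run"),
)


def build_systems():
    receptor = syn.make_toy_receptor(CONFIG.n_residues,
                                     stage_seed(CONFIG.seed, "receptor"))
    ligand = syn.make_toy_ligand(CONFIG.n_units, stage_seed(CONFIG.seed, "ligand"))
    complx = syn.make_toy_complex(receptor, ligand)
    return receptor, ligand, complx


def build_trajectories():
    receptor, ligand, complx = build_systems()
    trajs, truths = {}, {}
    for tag, system in (("free", receptor), ("bound", complx)):
        specs = _state_specs(system, CONFIG)
        trajs[tag], truths[tag] = syn.sample_metastable_trajectory(
            system, specs, CONFIG.n_frames, CONFIG.noise_sd,
            stage_seed(CONFIG.seed, f"traj:{tag}"),
        )
    return receptor, ligand, complx, trajs, truths


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "figures").mkdir(parents=True, exist_ok=True)
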