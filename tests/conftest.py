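"""Shared fixtures.

The expensive planted-hot-spot simulation battery (ten charged runs plus
ten zero-charge controls) is session-scoped and shared between the module
tests and the acceptance tests, so the whole suite pays for it once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pipsites import benchmarks, contact_analysis as ca
from pipsites.topology import BeadTopology, Frame, Trajectory

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

BATTERY_SEEDS = tuple(range(10))


def make_topology(classes, charges=None, phosphate=None, leaflets=None,
                  residue_ids=None, molecule_ids=None):
    """Hand-build a small topology from per-bead molecule classes."""
    n = len(classes)
    classes = np.asarray(classes, dtype=object)
    lipid = np.isin(classes, ("DOPC", "PIP2"))
    if leaflets is None:
        leaflets = np.where(lipid, "upper", "").astype(object)
    if phosphate is None:
        phosphate = classes == "PIP2"
    return BeadTopology(
        bead_name=np.where(classes == "protein", "BB", "HD").astype(object),
        residue_id=np.arange(1, n + 1) if residue_ids is None else np.asarray(residue_ids),
        residue_name=np.where(classes == "protein", "ALA", classes).astype(object),
        molecule_id=np.arange(1, n + 1) if molecule_ids is None else np.asarray(molecule_ids),
        molecule_class=classes,
        charge=np.zeros(n) if charges is None else np.asarray(charges, dtype=float),
        is_phosphate=np.asarray(phosphate, dtype=bool),
        leaflet=np.asarray(leaflets, dtype=object),
    )


def single_frame_traj(topology, coords, box=10.0, time=0.0):
    return Trajectory(topology, [Frame(np.asarray(coords, dtype=float),
                                       np.full(3, float(box)), time=time)])


@pytest.fixture(scope="session")
def planted_battery():
    """Ten charged planted-hot-spot runs + ten zero-charge controls.

    Returns a dict with the charged trajectories, their timelines, per-run
    binding fractions for both arms, and the per-run residue occupancy
    tables — everything the recovery, partition, monotonicity and
    electrostatic-driving checks consume.
    """
    charged_trajs, charged_fracs, control_fracs = [], [], []
    occupancies = []
    timelines = []
    for seed in BATTERY_SEEDS:
        traj = benchmarks.run_planted(seed)
        charged_trajs.append(traj)
        timeline = ca.binding_indicator(traj)
        timelines.append(timeline)
        charged_fracs.append(ca.binding_fraction(timeline))
        table = ca.residue_contact_fraction(traj)
        if table.defined and table.n_bound_frames >= benchmarks.MIN_BOUND_FRAMES:
            occupancies.append(
                table.residues.set_index("residue_id")["occupancy"])
        control = benchmarks.run_planted(seed, charged=False)
        control_fracs.append(ca.binding_fraction(ca.binding_indicator(control)))
    mean_occupancy = pd.concat(occupancies, axis=1).mean(axis=1)
    return {
        "seeds": BATTERY_SEEDS,
        "trajectories": charged_trajs,
        "timelines": timelines,
        "charged_fractions": charged_fracs,
        "control_fractions": control_fracs,
        "mean_occupancy": mean_occupancy,
        "n_occupancy_runs": len(occupancies),
    }
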