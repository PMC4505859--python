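"""Overdamped Langevin (Brownian) dynamics of a rigid protein over a bilayer.

The simulator reproduces the phenomenology that the contact analyses assume,
nothing more: a rigid charged body diffusing over a fluid membrane, attracted
to polyanionic head beads through screened electrostatics, binding and
unbinding many times over a run.

Model
-----
* Nonbonded forces act between protein beads and membrane/ion beads:
  a Debye–Hückel screened Coulomb term ``k_e q_i q_j exp(-r/λ_D)/(ε_r r)``
  plus a 12-6 Lennard-Jones term, both plainly truncated at
  ``nonbond_cutoff`` (no shift — documented dialect). Lipid–lipid and
  ion–lipid interactions are neglected (ideal in-plane fluid).
* The protein moves as one rigid body: the net force translates the centre
  of geometry, the net torque rotates the bead cloud about it
  (small-angle axis–angle update), and both carry thermal noise consistent
  with the grouped friction.
* Lipid head beads diffuse in x-y, are harmonically restrained in z to
  their leaflet plane, and feel the reaction force of the protein.
* Ion beads diffuse freely in all dimensions.
* All coordinates are wrapped into the orthorhombic box each step; the
  protein is wrapped as a unit so intra-protein distances are exact.

Units: nm, ns, kJ/mol, elementary charges, K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrationError, ValidationError
from .topology import (
    BeadTopology,
    ElasticNetwork,
    Frame,
    Trajectory,
    as_indices,
    minimum_image,
)

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008314462618
#: Coulomb constant, kJ mol^-1 nm e^-2
COULOMB_KE = 138.935458


@dataclass
class SimParams:
    """Parameters of the toy Brownian simulator.

    timestep : ns — integrator step (overdamped; displacements are capped
        at ``max_displacement`` to keep the steep LJ core stable).
    n_steps, save_interval : run length and saving stride in steps.
    temperature : K.
    friction : kJ mol^-1 ns nm^-2 per bead — Stokes drag; the bead
        diffusion coefficient is kT/friction (~0.1 nm²/ns at defaults,
        the accelerated-dynamics regime typical of coarse-grained models).
    debye_length : nm — electrostatic screening length (~1 nm at
        physiological ionic strength).
    dielectric : relative permittivity of the implicit solvent.
    lj_sigma, lj_epsilon : nm / kJ mol^-1 — excluded-volume term.
    nonbond_cutoff : nm — plain truncation for both nonbonded terms.
    leaflet_restraint_k : kJ mol^-1 nm^-2 — harmonic z-restraint holding
        each lipid head bead to its leaflet plane.
    """

    timestep: float = 0.01
    n_steps: int = 5000
    save_interval: int = 10
    temperature: float = 320.0
    friction: float = 25.0
    debye_length: float = 1.0
    dielectric: float = 80.0
    lj_sigma: float = 0.43
    lj_epsilon: float = 2.0
    nonbond_cutoff: float = 1.2
    leaflet_restraint_k: float = 100.0
    max_displacement: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.debye_length <= 0:
            raise ValidationError("debye_length must be positive")
        if self.dielectric <= 0:
            raise ValidationError("dielectric must be positive")
        if self.n_steps < 0 or self.save_interval < 1:
            raise ValidationError("n_steps >= 0 and save_interval >= 1 required")
        for name in ("temperature", "friction", "lj_sigma", "lj_epsilon",
                     "nonbond_cutoff", "leaflet_restraint_k", "max_displacement"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative")

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass
class EnergyBreakdown:
    """Pairwise interaction energy between two bead groups at one time point."""

    electrostatic: float
    van_der_waals: float
    time: float


def screened_coulomb_energy(
    q1: float, q2: float, r: float,
    debye_length: float = 1.0, dielectric: float = 80.0,
) -> float:
    """Debye–Hückel pair energy  k_e q1 q2 exp(-r/λ_D) / (ε_r r)  in kJ/mol."""
    if np.any(np.asarray(r) <= 0):
        raise ValidationError("pair distance must be positive")
    return COULOMB_KE * q1 * q2 * np.exp(-r / debye_length) / (dielectric * r)


def lennard_jones_energy(r, sigma: float, epsilon: float):
    sr6 = (sigma / np.asarray(r)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def total_interaction_energy(
    topology: BeadTopology,
    frame: Frame,
    group_a,
    group_b,
    params: SimParams,
) -> EnergyBreakdown:
    """Sum screened-Coulomb and LJ terms over all cross pairs of two groups.

    Uses minimum-image distances and the plain ``nonbond_cutoff`` truncation;
    symmetric in the two groups.
    """
    ia = as_indices(group_a, topology.n_beads)
    ib = as_indices(group_b, topology.n_beads)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("both groups must be nonempty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("groups must be disjoint")

    d = frame.coordinates[ia][:, None, :] - frame.coordinates[ib][None, :, :]
    r = np.sqrt((minimum_image(d, frame.box) ** 2).sum(axis=-1))
    within = r < params.nonbond_cutoff
    qq = topology.charge[ia][:, None] * topology.charge[ib][None, :]
    elec = np.where(
        within & (qq != 0.0),
        COULOMB_KE * qq * np.exp(-r / params.debye_length) / (params.dielectric * np.where(r > 0, r, 1.0)),
        0.0,
    ).sum()
    vdw = np.where(
        within,
        lennard_jones_energy(np.where(r > 0, r, params.lj_sigma), params.lj_sigma, params.lj_epsilon),
        0.0,
    ).sum()
    return EnergyBreakdown(float(elec), float(vdw), frame.time)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _pair_forces(coords_a, coords_b, q_a, q_b, box, params):
    """Force on each bead of group a from group b (and the negative on b)."""
    d = coords_a[:, None, :] - coords_b[None, :, :]
    d = minimum_image(d, box)
    r2 = (d * d).sum(axis=-1)
    r = np.sqrt(np.where(r2 > 0, r2, 1.0))
    within = (r2 < params.nonbond_cutoff ** 2) & (r2 > 0)

    # dE/dr of the screened Coulomb term: -A e^{-r/λ}(1/r² + 1/(λ r))
    qq = q_a[:, None] * q_b[None, :]
    a = COULOMB_KE * qq / params.dielectric
    f_elec = a * np.exp(-r / params.debye_length) * (1.0 / r2 + 1.0 / (params.debye_length * r))

    sr6 = (params.lj_sigma / r) ** 6
    f_lj = 24.0 * params.lj_epsilon * (2.0 * sr6 * sr6 - sr6) / r

    fmag = np.where(within, f_elec + f_lj, 0.0)
    fvec = (fmag / r)[:, :, None] * d
    return fvec.sum(axis=1), -fvec.sum(axis=0)


def compute_forces(
    topology: BeadTopology,
    frame: Frame,
    params: SimParams,
    leaflet_planes: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-bead forces: protein↔(lipid, ion) nonbonded + lipid z-restraints."""
    coords = frame.coordinates
    forces = np.zeros_like(coords)
    prot = np.flatnonzero(topology.protein_mask)
    other = np.flatnonzero(~topology.protein_mask)
    if len(prot) and len(other):
        f_p, f_o = _pair_forces(
            coords[prot], coords[other],
            topology.charge[prot], topology.charge[other],
            frame.box, params,
        )
        forces[prot] += f_p
        forces[other] += f_o

    if leaflet_planes is None:
        leaflet_planes = estimate_leaflet_planes(topology, frame)
    for leaf, z0 in leaflet_planes.items():
        sel = topology.lipid_mask & (topology.leaflet == leaf)
        dz = minimum_image(coords[sel, 2] - z0, frame.box[2])
        forces[sel, 2] += -params.leaflet_restraint_k * dz
    return forces


def estimate_leaflet_planes(topology: BeadTopology, frame: Frame) -> dict[str, float]:
    """Mean z of each leaflet's head beads — the membrane surface planes."""
    planes = {}
    for leaf in ("upper", "lower"):
        sel = topology.lipid_mask & (topology.leaflet == leaf)
        if sel.any():
            planes[leaf] = float(frame.coordinates[sel, 2].mean())
    return planes


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def _rotation_from_axis_angle(omega: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for rotation vector omega (rad)."""
    theta = np.linalg.norm(omega)
    if theta < 1e-14:
        return np.eye(3)
    k = omega / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def _cap(vectors: np.ndarray, limit: float) -> np.ndarray:
    norm = np.linalg.norm(vectors, axis=-1, keepdims=True)
    scale = np.where(norm > limit, limit / np.where(norm > 0, norm, 1.0), 1.0)
    return vectors * scale


def step(
    topology: BeadTopology,
    frame: Frame,
    elastic: ElasticNetwork | None,
    params: SimParams,
    rng: np.random.Generator | None = None,
    leaflet_planes: dict[str, float] | None = None,
) -> Frame:
    """One Euler–Maruyama Brownian step; returns a new frame at t + dt.

    The elastic network is accepted for interface completeness but exerts no
    force: the protein is integrated as a single rigid body, which preserves
    every network bond exactly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if leaflet_planes is None:
        leaflet_planes = estimate_leaflet_planes(topology, frame)

    forces = compute_forces(topology, frame, params, leaflet_planes)
    if not np.isfinite(forces).all():
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise IntegrationError(f"non-finite force on bead {bad} at t={frame.time} ns")

    dt = params.timestep
    kT = params.kT
    gamma = params.friction
    box = frame.box
    coords = frame.coordinates.copy()

    prot = np.flatnonzero(topology.protein_mask)
    # noise draws happen in a fixed order for reproducibility:
    # protein translation, protein rotation, lipids, ions
    if len(prot):
        x = coords[prot]
        com = x.mean(axis=0)
        rel = x - com
        gamma_t = gamma * len(prot)
        f_net = forces[prot].sum(axis=0)
        noise_t = np.sqrt(2.0 * kT * dt / gamma_t) * rng.standard_normal(3)
        dcom = _cap(f_net * dt / gamma_t + noise_t, params.max_displacement)

        moment = (rel * rel).sum()
        if moment > 0:
            gamma_r = gamma * moment
            torque = np.cross(rel, forces[prot]).sum(axis=0)
            noise_r = np.sqrt(2.0 * kT * dt / gamma_r) * rng.standard_normal(3)
            omega = torque * dt / gamma_r + noise_r
            r_max = np.sqrt((rel * rel).sum(axis=1).max())
            max_angle = params.max_displacement / max(r_max, 1e-9)
            omega = _cap(omega[None, :], max_angle)[0]
            rel = rel @ _rotation_from_axis_angle(omega).T
        else:
            rng.standard_normal(3)
        new_com = com + dcom
        # wrap the rigid body as a unit
        new_com = np.mod(new_com, box)
        coords[prot] = new_com + rel

    lip = np.flatnonzero(topology.lipid_mask)
    if len(lip):
        noise = np.sqrt(2.0 * kT * dt / gamma) * rng.standard_normal((len(lip), 3))
        disp = _cap(forces[lip] * dt / gamma + noise, params.max_displacement)
        coords[lip] = np.mod(coords[lip] + disp, box)

    ion = np.flatnonzero(topology.class_mask("ion"))
    if len(ion):
        noise = np.sqrt(2.0 * kT * dt / gamma) * rng.standard_normal((len(ion), 3))
        disp = _cap(forces[ion] * dt / gamma + noise, params.max_displacement)
        coords[ion] = np.mod(coords[ion] + disp, box)

    if not np.isfinite(coords).all():
        bad = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise IntegrationError(f"non-finite coordinate on bead {bad} at t={frame.time} ns")
    return Frame(coords, box.copy(), time=frame.time + dt)


def run(
    topology: BeadTopology,
    frame0: Frame,
    params: SimParams,
    elastic: ElasticNetwork | None = None,
) -> Trajectory:
    """Run ``n_steps`` Brownian steps, saving every ``save_interval`` steps.

    The initial frame is always saved; the final frame is saved whether or
    not it falls on the stride. Fully reproducible under ``params.seed``.
    Leaflet planes are anchored from the initial frame so the membrane does
    not drift with the restraint.
    """
    if frame0.n_beads != topology.n_beads:
        raise ValidationError("frame and topology bead counts differ")
    rng = np.random.default_rng(params.seed)
    planes = estimate_leaflet_planes(topology, frame0)
    frames = [frame0.copy()]
    current = frame0
    for i in range(1, params.n_steps + 1):
        current = step(topology, current, elastic, params, rng=rng,
                       leaflet_planes=planes)
        if i % params.save_interval == 0 or i == params.n_steps:
            frames.append(current.copy())
    return Trajectory(topology, frames)


def energy_series(
    traj: Trajectory,
    group_a,
    group_b,
    params: SimParams,
) -> list[EnergyBreakdown]:
    """total_interaction_energy evaluated on every frame of a trajectory."""
    return [total_interaction_energy(traj.topology, fr, group_a, group_b, params)
            for fr in traj]
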