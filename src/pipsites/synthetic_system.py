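"""Builders for synthetic coarse-grained membrane–protein systems.

These emulate the structure of a classic peripheral-binding setup: a planar
two-leaflet DOPC bilayer in which a chosen fraction of one leaflet is
replaced by polyanionic PIP2, and a rigid quasi-spherical protein decorated
with basic surface residues, placed at a controlled gap above the membrane
surface. Lipids are represented by a single head bead — all downstream
analyses touch only head/phosphate beads and minimal distances, never lipid
internal structure.

All randomness flows through an explicit integer seed per operation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .topology import (
    BeadTopology,
    ElasticNetwork,
    Frame,
    concatenate_topologies,
)

#: conventional net charge of the PIP2 head bead, elementary charges
DEFAULT_PIP2_CHARGE = -5.0


def build_bilayer(
    n_per_leaflet: int,
    area_per_lipid: float = 0.7,
    z_separation: float = 4.0,
    box_z: float | None = None,
) -> tuple[BeadTopology, Frame]:
    """Build a two-leaflet DOPC bilayer of single-head-bead lipids.

    Each leaflet holds ``n_per_leaflet`` lipids on a square lattice whose
    x-y area is ``n_per_leaflet * area_per_lipid`` (so the box edge is the
    square root of that). Leaflet planes sit ``z_separation`` apart, centred
    in a box of height ``box_z`` (default: z_separation + 15.1 nm, leaving
    generous head room for a protein).

    Returns the topology and a single frame at t = 0.
    """
    if n_per_leaflet < 1:
        raise ValidationError("n_per_leaflet must be >= 1")
    if area_per_lipid <= 0 or z_separation <= 0:
        raise ValidationError("area_per_lipid and z_separation must be positive")
    if box_z is None:
        box_z = z_separation + 15.1
    if box_z <= z_separation:
        raise ValidationError("box_z must exceed z_separation")

    edge = math.sqrt(n_per_leaflet * area_per_lipid)
    m = math.ceil(math.sqrt(n_per_leaflet))
    spacing = edge / m
    idx = np.arange(n_per_leaflet)
    gx = (idx % m + 0.5) * spacing
    gy = (idx // m + 0.5) * spacing

    z_mid = box_z / 2.0
    coords = np.zeros((2 * n_per_leaflet, 3))
    coords[:n_per_leaflet, 0] = gx
    coords[:n_per_leaflet, 1] = gy
    coords[:n_per_leaflet, 2] = z_mid + z_separation / 2.0
    coords[n_per_leaflet:, 0] = gx
    coords[n_per_leaflet:, 1] = gy
    coords[n_per_leaflet:, 2] = z_mid - z_separation / 2.0

    n = 2 * n_per_leaflet
    leaflet = np.array(["upper"] * n_per_leaflet + ["lower"] * n_per_leaflet,
                       dtype=object)
    topology = BeadTopology(
        bead_name=np.full(n, "HD", dtype=object),
        residue_id=np.arange(1, n + 1),
        residue_name=np.full(n, "DOPC", dtype=object),
        molecule_id=np.arange(1, n + 1),
        molecule_class=np.full(n, "DOPC", dtype=object),
        charge=np.zeros(n),
        is_phosphate=np.zeros(n, dtype=bool),
        leaflet=leaflet,
    )
    frame = Frame(coords, np.array([edge, edge, box_z]), time=0.0)
    return topology, frame


def assign_pip2(
    system: tuple[BeadTopology, Frame],
    fraction: float,
    leaflet: str = "upper",
    seed: int = 0,
    head_charge: float = DEFAULT_PIP2_CHARGE,
) -> tuple[BeadTopology, Frame]:
    """Randomly relabel a fraction of one leaflet's lipids as PIP2.

    ``round(fraction * leaflet lipid count)`` lipids (round half up) are
    drawn uniformly without replacement and converted in place: residue and
    molecule class become PIP2, the head bead becomes the phosphate contact
    reference and carries ``head_charge``. All other beads are untouched;
    coordinates never change.
    """
    topology, frame = system
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    if leaflet not in ("upper", "lower"):
        raise ValidationError(f"unknown leaflet {leaflet!r}")

    topology = topology.copy()
    candidates = np.flatnonzero(
        (topology.molecule_class == "DOPC") & (topology.leaflet == leaflet)
    )
    n_replace = math.floor(fraction * len(candidates) + 0.5)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_replace, replace=False)
    chosen.sort()

    topology.residue_name[chosen] = "PIP2"
    topology.molecule_class[chosen] = "PIP2"
    topology.bead_name[chosen] = "P1"
    topology.is_phosphate[chosen] = True
    topology.charge[chosen] = head_charge
    topology.validate()
    return topology, frame.copy()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly-equidistant unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_toy_protein(
    n_residues: int,
    radius: float = 1.2,
    basic_residue_ids: Sequence[int] = (),
    basic_charge: float = 1.0,
    seed: int = 0,
) -> tuple[BeadTopology, Frame]:
    """Rigid quasi-spherical protein with one backbone bead per residue.

    Beads sit on a golden-spiral shell of the given radius, randomly rotated
    under ``seed`` so repeated builds present different surface orientations,
    and the centre of geometry is shifted to the origin. Residues listed in
    ``basic_residue_ids`` (1-based) model surface lysines/arginines and carry
    ``basic_charge``; all others are neutral.
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    basic = set(int(r) for r in basic_residue_ids)
    unknown = basic - set(range(1, n_residues + 1))
    if unknown:
        raise ValidationError(f"unknown residue id(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    directions = _fibonacci_sphere(n_residues) @ _random_rotation(rng).T
    coords = radius * directions
    coords -= coords.mean(axis=0)

    resid = np.arange(1, n_residues + 1)
    is_basic = np.isin(resid, sorted(basic))
    topology = BeadTopology(
        bead_name=np.full(n_residues, "BB", dtype=object),
        residue_id=resid,
        residue_name=np.where(is_basic, "LYS", "ALA").astype(object),
        molecule_id=np.ones(n_residues, dtype=np.int64),
        molecule_class=np.full(n_residues, "protein", dtype=object),
        charge=np.where(is_basic, float(basic_charge), 0.0),
        is_phosphate=np.zeros(n_residues, dtype=bool),
        leaflet=np.full(n_residues, "", dtype=object),
    )
    box = np.full(3, max(4.0 * radius, 1.0))
    frame = Frame(coords + box / 2.0, box, time=0.0)
    return topology, frame


def build_elastic_network(
    frame: Frame,
    protein_beads,
    cutoff: float = 0.9,
    force_constant: float = 500.0,
) -> ElasticNetwork:
    """Harmonic network over all bead pairs closer than ``cutoff`` (nm).

    Rest lengths are the build-time pair distances; one bond per unordered
    pair, indices referring to the full system. Distances are plain
    Euclidean — the protein is compact and never built across a periodic
    boundary.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    from .topology import as_indices

    idx = as_indices(protein_beads, frame.n_beads)
    coords = frame.coordinates[idx]
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d < cutoff  # strict: query_pairs includes r == cutoff
        pairs, d = pairs[keep], d[keep]
    else:
        d = np.empty(0)
    gi = idx[pairs[:, 0]] if len(pairs) else np.empty(0, dtype=np.int64)
    gj = idx[pairs[:, 1]] if len(pairs) else np.empty(0, dtype=np.int64)
    lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
    order = np.lexsort((hi, lo))
    return ElasticNetwork(
        bonds=np.column_stack([lo, hi])[order] if len(pairs) else np.empty((0, 2), dtype=np.int64),
        rest_length=d[order],
        force_constant=np.full(len(pairs), float(force_constant)),
    )


def place_protein(
    bilayer_system: tuple[BeadTopology, Frame],
    protein_system: tuple[BeadTopology, Frame],
    gap: float,
) -> tuple[BeadTopology, Frame]:
    """Merge a protein into a bilayer system at a controlled surface gap.

    The protein is centred in x-y and translated in z so that its lowest
    bead sits exactly ``gap`` nm above the membrane surface, defined as the
    mean z of the upper-leaflet head beads. The merged system keeps the
    bilayer box.
    """
    bil_top, bil_frame = bilayer_system
    prot_top, prot_frame = protein_system
    if gap < 0:
        raise ValidationError("gap must be non-negative")
    upper = bil_top.leaflet_mask("upper")
    if not upper.any():
        raise ValidationError("bilayer has no upper-leaflet beads")

    plane = bil_frame.coordinates[upper, 2].mean()
    prot = prot_frame.coordinates.copy()
    box = bil_frame.box
    shift_xy = box[:2] / 2.0 - prot[:, :2].mean(axis=0)
    prot[:, 0] += shift_xy[0]
    prot[:, 1] += shift_xy[1]
    prot[:, 2] += (plane + gap) - prot[:, 2].min()
    if prot[:, 2].max() > box[2]:
        raise ValidationError(
            f"gap {gap} nm pushes the protein above the box (z_max "
            f"{prot[:, 2].max():.3f} > {box[2]:.3f} nm)")

    topology = concatenate_topologies(bil_top, prot_top)
    coords = np.vstack([bil_frame.coordinates, prot])
    return topology, Frame(coords, box.copy(), time=bil_frame.time)
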