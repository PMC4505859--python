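"""Spatial structure analyses: pair correlations, orientations, binding poses.

The radial distribution function answers whether the protein reorganizes the
lipid field (recruitment would show as g(r) enhancement among PIP2 head beads
near contact); the principal-axis distribution answers whether a preferred
binding pose exists; the two-site pose classifier assigns each bound frame to
one of four classes (only site I in contact, only site II, both, neither),
which partition the bound frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_analysis import AnalysisParams, BindingTimeline, residues_in_contact
from .errors import DegenerateGeometryError, ValidationError
from .topology import (
    BeadTopology,
    Frame,
    Trajectory,
    as_indices,
    minimum_image,
)

POSE_LABELS = ("I_only", "II_only", "both", "neither")


@dataclass(frozen=True)
class SiteDefinition:
    """A named set of protein residue ids forming one candidate binding site."""

    name: str
    residue_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValidationError(f"site {self.name!r} has no residues")
        object.__setattr__(self, "residue_ids", frozenset(int(r) for r in self.residue_ids))


def validate_site_scheme(*sites: SiteDefinition) -> None:
    """Sites of one classification scheme may not share residues."""
    seen: set[int] = set()
    for site in sites:
        overlap = seen & site.residue_ids
        if overlap:
            raise ValidationError(f"sites overlap on residues {sorted(overlap)}")
        seen |= site.residue_ids


# FAK residue numbering: Group I spans the FERM F2 basic ridge (KAKTLRK)
# plus the adjacent kinase C-lobe; Group II sits at the kinase N-/C-lobe
# interface and is the novel candidate site.
FAK_GROUP_I = SiteDefinition("Group I", frozenset({191, 216, 218, 221, 222, 229, 640, 657, 665}))
FAK_GROUP_II = SiteDefinition("Group II", frozenset({508, 514, 515, 578, 621, 627}))


@dataclass
class RDFProfile:
    """g(r) over uniform bins; reference/target recorded for provenance."""

    bin_centers: np.ndarray
    g: np.ndarray
    mode: str
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.bin_centers, "g": self.g})


def rdf(
    traj: Trajectory,
    reference,
    target,
    r_max: float,
    n_bins: int = 50,
    mode: str = "3d",
    frame_range: tuple[int, int] | None = None,
) -> RDFProfile:
    """Radial distribution function of target beads around reference beads.

    ``mode='3d'`` normalizes counts by spherical-shell volume and the mean
    3-D target density; ``mode='lateral'`` uses x-y distances, annular shell
    areas and the areal density (appropriate for quasi-planar lipids).
    Self-pairs are excluded when the selections overlap. ``frame_range``
    restricts analysis to frames [start, stop) — e.g. to drop an approach
    transient.
    """
    if mode not in ("3d", "lateral"):
        raise ValidationError(f"unknown rdf mode {mode!r}")
    if n_bins < 1 or r_max <= 0:
        raise ValidationError("need r_max > 0 and n_bins >= 1")
    top = traj.topology
    ref_idx = as_indices(reference, top.n_beads)
    tgt_idx = as_indices(target, top.n_beads)
    if len(ref_idx) == 0 or len(tgt_idx) == 0:
        raise ValidationError("reference and target selections must be nonempty")
    box = traj.frames[0].box
    dims = 3 if mode == "3d" else 2
    if r_max > box[:dims].min() / 2.0:
        raise ValidationError("r_max exceeds half the smallest box edge "
                              "(minimum image would be violated)")

    frames = traj.frames if frame_range is None else traj.frames[slice(*frame_range)]
    if not frames:
        raise ValidationError("frame range selects no frames")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    overlap = np.intersect1d(ref_idx, tgt_idx)
    n_self = len(overlap)
    for fr in frames:
        d = fr.coordinates[ref_idx][:, None, :dims] - fr.coordinates[tgt_idx][None, :, :dims]
        d = minimum_image(d, fr.box[:dims])
        r = np.sqrt((d * d).sum(axis=-1))
        if n_self:
            # mask the zero-distance self pairs
            same = ref_idx[:, None] == tgt_idx[None, :]
            r = r[~same]
        counts += np.histogram(r, bins=edges)[0]

    if mode == "3d":
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        volume = float(np.prod(box))
    else:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        volume = float(box[0] * box[1])
    # mean number of targets available to each reference bead
    pairs_per_ref = len(tgt_idx) - (1 if n_self else 0)
    density = pairs_per_ref / volume
    norm = len(frames) * len(ref_idx) * density * shell
    g = counts / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(centers, g, mode, len(frames))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def principal_axis(frame: Frame, protein_beads) -> np.ndarray:
    """First principal axis of the bead cloud, sign-fixed to z >= 0.

    Eigenvector of the coordinate covariance matrix with the largest
    eigenvalue. Degenerate clouds (all beads coincident, or an isotropic
    top eigenpair within 1e-10 of zero spread) raise DegenerateGeometryError.
    """
    idx = as_indices(protein_beads, frame.n_beads)
    if len(idx) < 2:
        raise DegenerateGeometryError("need at least two beads")
    x = frame.coordinates[idx]
    cov = np.cov((x - x.mean(axis=0)).T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] < 1e-10:
        raise DegenerateGeometryError("coincident beads: no principal axis")
    axis = vecs[:, -1]
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass
class OrientationHistogram:
    """Probability of the principal-axis z-component per bin over [-1, 1]."""

    bin_edges: np.ndarray
    probability: np.ndarray
    folded: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])
        return pd.DataFrame({"v_z": centers, "p": self.probability})


def orientation_distribution(
    traj: Trajectory,
    protein_beads,
    n_bins: int = 20,
    folded: bool = False,
) -> OrientationHistogram:
    """Histogram of the per-frame principal-axis z-component.

    With ``folded=True`` the histogram is over |V_z| on [0, 1] — useful
    because the sign convention makes V_z >= 0 by construction when the axis
    itself is sign-ambiguous.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    vz = np.array([principal_axis(fr, protein_beads)[2] for fr in traj])
    if folded:
        vz = np.abs(vz)
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts = np.histogram(vz, bins=edges)[0].astype(float)
    return OrientationHistogram(edges, counts / counts.sum(), folded)


def com_axis(frame: Frame, topology: BeadTopology, residues_a, residues_b) -> np.ndarray:
    """Unit vector from the centroid of residue set a to that of set b.

    Beads carry equal mass (coarse-grained beads are near-uniform); residue
    sets are 1-based residue ids on the protein.
    """
    prot = topology.protein_mask
    out = []
    for res_set in (residues_a, residues_b):
        sel = prot & np.isin(topology.residue_id, list(res_set))
        if not sel.any():
            raise ValidationError("residue set selects no protein beads")
        out.append(frame.coordinates[sel].mean(axis=0))
    vec = out[1] - out[0]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise DegenerateGeometryError("coincident centers of mass")
    return vec / norm


# ---------------------------------------------------------------------------
# pose classification
# ---------------------------------------------------------------------------

def classify_pose(
    frame: Frame,
    topology: BeadTopology,
    site_i: SiteDefinition,
    site_ii: SiteDefinition,
    params: AnalysisParams | None = None,
) -> str:
    """Label a *bound* frame by which sites touch PIP2: I_only/II_only/both/neither."""
    params = params or AnalysisParams()
    validate_site_scheme(site_i, site_ii)
    contacts = residues_in_contact(frame, topology, params)
    if not contacts:
        raise ValidationError("classify_pose called on an unbound frame")
    in_i = bool(contacts & site_i.residue_ids)
    in_ii = bool(contacts & site_ii.residue_ids)
    if in_i and in_ii:
        return "both"
    if in_i:
        return "I_only"
    if in_ii:
        return "II_only"
    return "neither"


def annotate_poses(
    traj: Trajectory,
    timeline: BindingTimeline,
    site_i: SiteDefinition,
    site_ii: SiteDefinition,
    params: AnalysisParams | None = None,
) -> BindingTimeline:
    """Fill the timeline's pose labels (None on unbound frames)."""
    params = params or AnalysisParams()
    from .contact_analysis import _analysis_frames

    frames = _analysis_frames(traj, params)
    if len(frames) != timeline.n_frames:
        raise ValidationError("timeline does not match trajectory frame count")
    pose = np.array([
        classify_pose(fr, traj.topology, site_i, site_ii, params)
        if timeline.bound[k] else ""
        for k, fr in enumerate(frames)
    ], dtype=object)
    timeline.pose = pose
    return timeline


def aggregate_poses(timeline: BindingTimeline) -> dict[str, float]:
    """Percentage of bound frames per pose class; the four classes sum to 100."""
    if timeline.pose is None:
        raise ValidationError("timeline has no pose labels; run annotate_poses")
    labels = timeline.pose[timeline.bound]
    if len(labels) == 0:
        return {label: 0.0 for label in POSE_LABELS}
    return {
        label: 100.0 * float((labels == label).sum()) / len(labels)
        for label in POSE_LABELS
    }
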