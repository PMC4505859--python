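"""Protein–lipid contact statistics from coarse-grained trajectories.

The central criterion: the protein is *bound* in a frame when the minimal
distance between any protein bead and any PIP2 phosphate bead is strictly
less than the contact cutoff (default 0.52 nm). Everything else derives
from that boolean, frame by frame:

* the binding fraction (% of analyzed frames bound);
* the stoichiometry distribution — how often the protein touches
  n_P = 1, 2, 3, 4+ distinct PIP2 molecules simultaneously, normalized
  over *bound* frames so the classes partition to 100%;
* per-residue contact occupancies x_i = n_i / N, where n_i counts frames
  in which residue i touches a phosphate bead and N counts frames in which
  the protein as a whole is bound;
* a per-lipid contact census N_L: the number of lipids of each class whose
  contact fraction exceeds a threshold (5% and 10% by default);
* the residue selection rule used to call binding sites: x_i > 5% in at
  least two independent simulations, or x_i > 10% in any one.

Frames exactly at the cutoff resolve to unbound (strict less-than).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .topology import (
    BeadTopology,
    Frame,
    Trajectory,
    as_indices,
    pairwise_distances,
)


@dataclass
class AnalysisParams:
    """Knobs of the contact analysis.

    contact_cutoff : nm — strict upper bound on protein-bead–phosphate-bead
        distance defining a contact (default 0.52).
    residue_thresh_major / residue_thresh_minor : occupancy fractions of the
        site-selection rule (defaults 0.10 / 0.05, strict inequalities).
    min_sims_minor : how many simulations must clear the minor threshold.
    lipid_census_thresholds : contact-fraction thresholds of the lipid census.
    equilibration_skip : ns discarded from the start of every trajectory.
    phosphate_only : measure residue contacts to PIP2 phosphate beads only
        (default) or to every PIP2 bead.
    """

    contact_cutoff: float = 0.52
    residue_thresh_major: float = 0.10
    residue_thresh_minor: float = 0.05
    min_sims_minor: int = 2
    lipid_census_thresholds: tuple[float, ...] = (0.05, 0.10)
    equilibration_skip: float = 0.0
    phosphate_only: bool = True

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValidationError("contact_cutoff must be positive")
        for t in (self.residue_thresh_major, self.residue_thresh_minor,
                  *self.lipid_census_thresholds):
            if not 0.0 < t < 1.0:
                raise ValidationError("thresholds must lie in (0, 1)")
        if self.equilibration_skip < 0:
            raise ValidationError("equilibration_skip must be non-negative")


@dataclass
class BindingTimeline:
    """Per-frame binding record: bound flag, PIP2 stoichiometry, distances."""

    time: np.ndarray
    bound: np.ndarray
    n_p: np.ndarray
    min_dist: np.ndarray
    pose: np.ndarray | None = None
    cutoff: float = 0.52

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        self.n_p = np.asarray(self.n_p, dtype=np.int64)
        self.min_dist = np.asarray(self.min_dist, dtype=float)
        n = len(self.time)
        if not (len(self.bound) == len(self.n_p) == len(self.min_dist) == n):
            raise ValidationError("timeline arrays must have equal length")
        if np.any(self.bound != (self.min_dist < self.cutoff)):
            raise ValidationError("bound flag inconsistent with min_dist/cutoff")
        if np.any(self.bound != (self.n_p >= 1)):
            raise ValidationError("n_p inconsistent with bound flag")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.time, "bound": self.bound,
            "n_p": self.n_p, "min_dist": self.min_dist,
        })
        if self.pose is not None:
            df["pose"] = self.pose
        return df


@dataclass
class ContactTable:
    """Residue- and lipid-side contact occupancies for one trajectory.

    ``residues`` columns: residue_id, residue_name, n_contact, occupancy
    (x_i = n_i/N over bound frames). ``lipids`` columns: molecule_id,
    lipid_class, n_contact, fraction. ``census`` columns: lipid_class,
    threshold, n_lipids. ``defined`` is False when the trajectory never
    binds (N = 0), in which case occupancies are NaN.
    """

    residues: pd.DataFrame
    n_bound_frames: int
    n_frames: int
    lipids: pd.DataFrame | None = None
    census: pd.DataFrame | None = None
    defined: bool = True


# ---------------------------------------------------------------------------
# frame-level primitives
# ---------------------------------------------------------------------------

def min_distance(frame: Frame, topology: BeadTopology, group_a, group_b) -> float:
    """Minimum over all cross pairs of the minimum-image distance (nm)."""
    ia = as_indices(group_a, topology.n_beads)
    ib = as_indices(group_b, topology.n_beads)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("both groups must be nonempty")
    return float(pairwise_distances(
        frame.coordinates[ia], frame.coordinates[ib], frame.box).min())


def _reference_mask(topology: BeadTopology, params: AnalysisParams) -> np.ndarray:
    """PIP2 beads residue contacts are measured against."""
    if params.phosphate_only:
        return topology.phosphate_mask
    return topology.class_mask("PIP2")


def _contact_matrix(frame: Frame, topology: BeadTopology,
                    prot_idx: np.ndarray, ref_idx: np.ndarray,
                    cutoff: float) -> np.ndarray:
    """Boolean (protein bead, reference bead) contact matrix for one frame."""
    d = pairwise_distances(frame.coordinates[prot_idx],
                           frame.coordinates[ref_idx], frame.box)
    return d < cutoff


def residues_in_contact(frame: Frame, topology: BeadTopology,
                        params: AnalysisParams) -> set[int]:
    """Protein residue ids with ≥1 bead within cutoff of a PIP2 reference bead."""
    prot_idx = np.flatnonzero(topology.protein_mask)
    ref_idx = np.flatnonzero(_reference_mask(topology, params))
    if len(prot_idx) == 0 or len(ref_idx) == 0:
        return set()
    contact = _contact_matrix(frame, topology, prot_idx, ref_idx,
                              params.contact_cutoff).any(axis=1)
    return set(topology.residue_id[prot_idx[contact]].tolist())


def _analysis_frames(traj: Trajectory, params: AnalysisParams) -> list[Frame]:
    if params.equilibration_skip <= 0:
        return list(traj.frames)
    t0 = traj.frames[0].time + params.equilibration_skip
    kept = [fr for fr in traj if fr.time >= t0]
    if not kept:
        raise ValidationError("equilibration_skip discards every frame")
    return kept


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------

def binding_indicator(traj: Trajectory, params: AnalysisParams | None = None) -> BindingTimeline:
    """Evaluate the binding criterion on every analyzed frame.

    bound: min distance from any protein bead to any PIP2 phosphate bead
    < cutoff (strict). n_P: number of distinct PIP2 molecules with at least
    one phosphate bead within cutoff of any protein bead.
    """
    params = params or AnalysisParams()
    top = traj.topology
    prot_idx = np.flatnonzero(top.protein_mask)
    phos_idx = np.flatnonzero(top.phosphate_mask)
    if len(prot_idx) == 0:
        raise ValidationError("topology contains no protein beads")
    if len(phos_idx) == 0:
        raise ValidationError("topology contains no PIP2 phosphate beads")
    phos_mol = top.molecule_id[phos_idx]

    frames = _analysis_frames(traj, params)
    times = np.empty(len(frames))
    min_d = np.empty(len(frames))
    n_p = np.zeros(len(frames), dtype=np.int64)
    for k, fr in enumerate(frames):
        d = pairwise_distances(fr.coordinates[prot_idx],
                               fr.coordinates[phos_idx], fr.box)
        times[k] = fr.time
        min_d[k] = d.min()
        in_contact = (d < params.contact_cutoff).any(axis=0)
        n_p[k] = len(np.unique(phos_mol[in_contact]))
    bound = min_d < params.contact_cutoff
    return BindingTimeline(times, bound, n_p, min_d, cutoff=params.contact_cutoff)


def binding_fraction(timeline: BindingTimeline) -> float:
    """Percentage of analyzed frames in which the protein is bound."""
    if timeline.n_frames == 0:
        raise ValidationError("empty timeline")
    return 100.0 * timeline.n_bound / timeline.n_frames


@dataclass
class StoichiometryDistribution:
    """% of bound frames with each simultaneous-PIP2 count (partition of 100)."""

    labels: list[str]
    percent: np.ndarray
    n_bound: int
    empty: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.percent.tolist()))


def stoichiometry_distribution(timeline: BindingTimeline, max_n: int = 6) -> StoichiometryDistribution:
    """Distribute bound frames over n_P = 1, 2, 3, 4–max_n classes."""
    if timeline.n_frames == 0:
        raise ValidationError("empty timeline")
    labels = ["1", "2", "3", f"4-{max_n}"]
    if timeline.n_bound == 0:
        return StoichiometryDistribution(labels, np.zeros(4), 0, empty=True)
    npv = timeline.n_p[timeline.bound]
    counts = np.array([
        (npv == 1).sum(), (npv == 2).sum(), (npv == 3).sum(),
        ((npv >= 4) & (npv <= max_n)).sum() + (npv > max_n).sum(),
    ], dtype=float)
    return StoichiometryDistribution(labels, 100.0 * counts / timeline.n_bound,
                                     timeline.n_bound)


def mean_bound_distance(timeline: BindingTimeline) -> tuple[float, float]:
    """Mean and sd (population) of the minimal distance over bound frames, nm."""
    d = timeline.min_dist[timeline.bound]
    if len(d) == 0:
        raise ValidationError("no bound frames")
    return float(d.mean()), float(d.std(ddof=0))


def first_binding_time(timeline: BindingTimeline) -> float | None:
    """Time (ns) of the earliest bound frame, or None if never bound."""
    idx = np.flatnonzero(timeline.bound)
    return float(timeline.time[idx[0]]) if len(idx) else None


# ---------------------------------------------------------------------------
# residue and lipid occupancies
# ---------------------------------------------------------------------------

def residue_contact_fraction(traj: Trajectory, params: AnalysisParams | None = None) -> ContactTable:
    """Per-residue contact occupancy x_i = n_i / N.

    n_i counts frames in which residue i has a bead within cutoff of a PIP2
    reference bead; N counts frames in which the protein as a whole is bound.
    With N = 0 the table is returned with NaN occupancies and defined=False.
    """
    params = params or AnalysisParams()
    top = traj.topology
    prot_idx = np.flatnonzero(top.protein_mask)
    ref_idx = np.flatnonzero(_reference_mask(top, params))
    if len(prot_idx) == 0:
        raise ValidationError("topology contains no protein beads")
    if len(ref_idx) == 0:
        raise ValidationError("topology contains no PIP2 beads")

    resid = top.residue_id[prot_idx]
    uniq, inverse = np.unique(resid, return_inverse=True)
    names = pd.Series(top.residue_name[prot_idx], index=resid).groupby(level=0).first()
    n_i = np.zeros(len(uniq), dtype=np.int64)
    n_bound = 0
    frames = _analysis_frames(traj, params)
    for fr in frames:
        contact_bead = _contact_matrix(fr, top, prot_idx, ref_idx,
                                       params.contact_cutoff).any(axis=1)
        if contact_bead.any():
            n_bound += 1
            hit = np.zeros(len(uniq), dtype=bool)
            hit[inverse[contact_bead]] = True
            n_i += hit
    defined = n_bound > 0
    occupancy = n_i / n_bound if defined else np.full(len(uniq), np.nan)
    residues = pd.DataFrame({
        "residue_id": uniq,
        "residue_name": names.loc[uniq].to_numpy(),
        "n_contact": n_i,
        "occupancy": occupancy,
    })
    return ContactTable(residues, n_bound, len(frames), defined=defined)


def lipid_contact_census(traj: Trajectory, params: AnalysisParams | None = None) -> ContactTable:
    """Per-lipid contact fractions and census counts, per lipid class.

    For each class (PIP2, DOPC) a lipid's contact count is the number of
    frames its head bead lies within cutoff of any protein bead, normalized
    by the total number of frames the protein contacts *any* lipid of that
    class. N_L(threshold) counts lipids whose fraction exceeds the threshold
    (strict), one census row per class and threshold.
    """
    params = params or AnalysisParams()
    top = traj.topology
    prot_idx = np.flatnonzero(top.protein_mask)
    if len(prot_idx) == 0:
        raise ValidationError("topology contains no protein beads")

    frames = _analysis_frames(traj, params)
    lipid_rows = []
    census_rows = []
    for cls in ("PIP2", "DOPC"):
        lip_idx = np.flatnonzero(top.class_mask(cls))
        mols = top.molecule_id[lip_idx]
        uniq = np.unique(mols)
        counts = pd.Series(0, index=uniq, dtype=np.int64)
        n_class_bound = 0
        for fr in frames:
            if len(lip_idx) == 0:
                continue
            contact = _contact_matrix(fr, top, prot_idx, lip_idx,
                                      params.contact_cutoff).any(axis=0)
            if contact.any():
                n_class_bound += 1
                counts.loc[np.unique(mols[contact])] += 1
        frac = counts / n_class_bound if n_class_bound else counts * np.nan
        for mol in uniq:
            lipid_rows.append({
                "molecule_id": int(mol), "lipid_class": cls,
                "n_contact": int(counts.loc[mol]),
                "fraction": float(frac.loc[mol]),
            })
        for thresh in sorted(params.lipid_census_thresholds):
            n_l = int((frac > thresh).sum()) if n_class_bound else 0
            census_rows.append({
                "lipid_class": cls, "threshold": thresh, "n_lipids": n_l,
                "percent_time_bound": 100.0 * n_class_bound / len(frames),
            })
    lipids = pd.DataFrame(lipid_rows,
                          columns=["molecule_id", "lipid_class", "n_contact", "fraction"])
    census = pd.DataFrame(census_rows,
                          columns=["lipid_class", "threshold", "n_lipids",
                                   "percent_time_bound"])
    residues = pd.DataFrame(columns=["residue_id", "residue_name",
                                     "n_contact", "occupancy"])
    return ContactTable(residues, 0, len(frames), lipids=lipids, census=census)


def select_binding_residues(
    occupancy: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> list:
    """Apply the binding-site selection rule across simulations.

    ``occupancy``: one row per simulation, one column per residue, values as
    occupancy *fractions* (x_i in [0, 1]). A residue is selected when
    x_i > minor threshold in at least ``min_sims_minor`` simulations, or
    x_i > major threshold in any simulation — both strict. Returns the
    selected column labels in column order.
    """
    params = params or AnalysisParams()
    vals = occupancy.to_numpy(dtype=float)
    minor = (vals > params.residue_thresh_minor).sum(axis=0) >= params.min_sims_minor
    major = (vals > params.residue_thresh_major).any(axis=0)
    keep = minor | major
    return [c for c, k in zip(occupancy.columns, keep) if k]


def occupancy_matrix(tables: Mapping[str, ContactTable]) -> pd.DataFrame:
    """Stack per-simulation ContactTables into a sims × residues x_i matrix."""
    rows = {}
    for label, table in tables.items():
        rows[label] = table.residues.set_index("residue_id")["occupancy"]
    return pd.DataFrame(rows).T.sort_index(axis=1)


# ---------------------------------------------------------------------------
# sensitivity and leaflet analyses
# ---------------------------------------------------------------------------

def cutoff_sweep(
    traj: Trajectory,
    cutoffs: Sequence[float],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Residue contact occupancy at several cutoffs (residues × cutoffs).

    Occupancies here are normalized by the *total* number of analyzed frames
    (percentage of simulation time the residue is in contact), which makes
    each residue's column non-decreasing in the cutoff by construction.
    Table-3-style x_i at one cutoff comes from residue_contact_fraction.
    """
    params = params or AnalysisParams()
    if any(c < 0 for c in cutoffs):
        raise ValidationError("cutoffs must be non-negative")
    top = traj.topology
    prot_idx = np.flatnonzero(top.protein_mask)
    ref_idx = np.flatnonzero(_reference_mask(top, params))
    if len(prot_idx) == 0 or len(ref_idx) == 0:
        raise ValidationError("need protein and PIP2 beads")
    resid = top.residue_id[prot_idx]
    uniq, inverse = np.unique(resid, return_inverse=True)

    frames = _analysis_frames(traj, params)
    out = {}
    for cutoff in cutoffs:
        n_i = np.zeros(len(uniq), dtype=np.int64)
        if cutoff > 0:
            for fr in frames:
                d = pairwise_distances(fr.coordinates[prot_idx],
                                       fr.coordinates[ref_idx], fr.box)
                contact_bead = (d < cutoff).any(axis=1)
                if contact_bead.any():
                    hit = np.zeros(len(uniq), dtype=bool)
                    hit[inverse[contact_bead]] = True
                    n_i += hit
        out[float(cutoff)] = n_i / len(frames)
    return pd.DataFrame(out, index=pd.Index(uniq, name="residue_id"))


def top_k_residues(occupancies: pd.Series | pd.DataFrame, k: int) -> set[int]:
    """The k residues with the highest (mean) occupancy."""
    if isinstance(occupancies, pd.DataFrame):
        occupancies = occupancies.mean(axis=0)
    return set(occupancies.sort_values(ascending=False, kind="stable").index[:k])


def leaflet_min_distance_series(traj: Trajectory) -> pd.DataFrame:
    """Per-frame minimal distance from the protein to each leaflet's beads.

    Columns ``dist_upper``/``dist_lower`` plus ``time``; the frame attribute
    ``pip2_leaflet`` records which leaflet (if any single one) holds PIP2.
    """
    top = traj.topology
    prot = np.flatnonzero(top.protein_mask)
    if len(prot) == 0:
        raise ValidationError("topology contains no protein beads")
    rows = {"time": traj.times}
    for leaf in ("upper", "lower"):
        sel = np.flatnonzero(top.lipid_mask & (top.leaflet == leaf))
        if len(sel) == 0:
            raise ValidationError(f"no lipids in {leaf} leaflet")
        rows[f"dist_{leaf}"] = [
            min_distance(fr, top, prot, sel) for fr in traj
        ]
    df = pd.DataFrame(rows)
    df.attrs["pip2_leaflet"] = top.pip2_leaflet()
    return df
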