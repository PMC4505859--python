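"""Core in-memory containers for coarse-grained membrane–protein systems.

A system is a :class:`BeadTopology` (static per-bead metadata: identity,
residue, molecule, charge, analysis flags) plus one or more :class:`Frame`
objects (coordinates in nm, an orthorhombic box, a time stamp in ns).
A :class:`Trajectory` bundles a topology with a time-ordered frame list.

Conventions
-----------
* lengths in nm, times in ns, charges in elementary-charge units,
  energies in kJ/mol;
* bead ids are 0-based and contiguous; residue and molecule ids are 1-based;
* the leaflet flag is ``"upper"``/``"lower"`` for lipid beads and the empty
  string for protein and ion beads;
* phosphate head beads are the contact reference for PIP2: every PIP2
  molecule carries at least one, and only PIP2 beads may carry the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

MOLECULE_CLASSES = ("protein", "DOPC", "PIP2", "ion")
LIPID_CLASSES = ("DOPC", "PIP2")

#: Column order of the on-disk topology sidecar (see trajectory_io).
TOPOLOGY_COLUMNS = [
    "bead_id",
    "bead_name",
    "residue_id",
    "residue_name",
    "molecule_id",
    "molecule_class",
    "charge",
    "is_phosphate",
    "leaflet",
]


@dataclass
class BeadTopology:
    """Static description of every bead in a coarse-grained system."""

    bead_name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    molecule_id: np.ndarray
    molecule_class: np.ndarray
    charge: np.ndarray
    is_phosphate: np.ndarray
    leaflet: np.ndarray
    extras: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bead_name = np.asarray(self.bead_name, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.molecule_class = np.asarray(self.molecule_class, dtype=object)
        self.charge = np.asarray(self.charge, dtype=np.float64)
        self.is_phosphate = np.asarray(self.is_phosphate, dtype=bool)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.bead_name)
        for name in ("residue_id", "residue_name", "molecule_id",
                     "molecule_class", "charge", "is_phosphate", "leaflet"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name!r} has wrong length")
        unknown = set(self.molecule_class) - set(MOLECULE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown molecule class(es): {sorted(unknown)}")
        if not np.isfinite(self.charge).all():
            raise ValidationError("non-finite charge")
        pip2 = self.molecule_class == "PIP2"
        if np.any(self.is_phosphate & ~pip2):
            raise ValidationError("phosphate flag set on a non-PIP2 bead")
        for mol in np.unique(self.molecule_id[pip2]):
            sel = pip2 & (self.molecule_id == mol)
            if not self.is_phosphate[sel].any():
                raise ValidationError(f"PIP2 molecule {mol} has no phosphate bead")
        lipid = np.isin(self.molecule_class, LIPID_CLASSES)
        bad = lipid & ~np.isin(self.leaflet, ("upper", "lower"))
        if bad.any():
            raise ValidationError("lipid bead without a leaflet assignment")
        bad = ~lipid & (self.leaflet != "")
        if bad.any():
            raise ValidationError("leaflet assigned to a non-lipid bead")

    # -- basic queries ---------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.bead_name)

    @property
    def bead_id(self) -> np.ndarray:
        return np.arange(self.n_beads, dtype=np.int64)

    def class_mask(self, molecule_class: str) -> np.ndarray:
        return self.molecule_class == molecule_class

    @property
    def protein_mask(self) -> np.ndarray:
        return self.class_mask("protein")

    @property
    def lipid_mask(self) -> np.ndarray:
        return np.isin(self.molecule_class, LIPID_CLASSES)

    @property
    def phosphate_mask(self) -> np.ndarray:
        return self.is_phosphate.copy()

    def leaflet_mask(self, leaflet: str) -> np.ndarray:
        return self.leaflet == leaflet

    def pip2_leaflet(self) -> str | None:
        """Leaflet holding PIP2, or None if absent/in both."""
        leaves = set(self.leaflet[self.class_mask("PIP2")])
        if len(leaves) == 1:
            return leaves.pop()
        return None

    def molecule_count(self, molecule_class: str) -> int:
        mask = self.class_mask(molecule_class)
        return len(np.unique(self.molecule_id[mask])) if mask.any() else 0

    def copy(self) -> "BeadTopology":
        return BeadTopology(
            self.bead_name.copy(), self.residue_id.copy(),
            self.residue_name.copy(), self.molecule_id.copy(),
            self.molecule_class.copy(), self.charge.copy(),
            self.is_phosphate.copy(), self.leaflet.copy(),
            None if self.extras is None else self.extras.copy(),
        )

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bead_id": self.bead_id,
            "bead_name": self.bead_name,
            "residue_id": self.residue_id,
            "residue_name": self.residue_name,
            "molecule_id": self.molecule_id,
            "molecule_class": self.molecule_class,
            "charge": self.charge,
            "is_phosphate": self.is_phosphate,
            "leaflet": self.leaflet,
        })
        if self.extras is not None:
            for col in self.extras.columns:
                df[col] = self.extras[col].to_numpy()
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BeadTopology":
        extras_cols = [c for c in df.columns if c not in TOPOLOGY_COLUMNS]
        extras = df[extras_cols].reset_index(drop=True) if extras_cols else None
        bead_id = df["bead_id"].to_numpy()
        if not np.array_equal(np.sort(bead_id), np.arange(len(df))):
            raise ValidationError("bead_ids must be unique and contiguous from 0")
        order = np.argsort(bead_id, kind="stable")
        df = df.iloc[order]
        return cls(
            df["bead_name"].to_numpy(dtype=object),
            df["residue_id"].to_numpy(),
            df["residue_name"].to_numpy(dtype=object),
            df["molecule_id"].to_numpy(),
            df["molecule_class"].to_numpy(dtype=object),
            df["charge"].to_numpy(dtype=float),
            df["is_phosphate"].to_numpy(dtype=bool),
            df["leaflet"].fillna("").to_numpy(dtype=object),
            None if extras is None else extras.iloc[order].reset_index(drop=True),
        )


def concatenate_topologies(first: BeadTopology, second: BeadTopology) -> BeadTopology:
    """Merge two topologies; molecule ids of the second are offset to stay unique."""
    offset = int(first.molecule_id.max()) if first.n_beads else 0
    return BeadTopology(
        np.concatenate([first.bead_name, second.bead_name]),
        np.concatenate([first.residue_id, second.residue_id]),
        np.concatenate([first.residue_name, second.residue_name]),
        np.concatenate([first.molecule_id, second.molecule_id + offset]),
        np.concatenate([first.molecule_class, second.molecule_class]),
        np.concatenate([first.charge, second.charge]),
        np.concatenate([first.is_phosphate, second.is_phosphate]),
        np.concatenate([first.leaflet, second.leaflet]),
    )


@dataclass
class Frame:
    """Coordinates (nm) of every bead plus an orthorhombic box and a time stamp."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must have shape (n_beads, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("non-finite coordinate")
        if self.box.shape != (3,) or not (self.box > 0).all():
            raise ValidationError("box must be three positive lengths")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


@dataclass
class Trajectory:
    """A topology plus its time-ordered frames."""

    topology: BeadTopology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("trajectory must contain at least one frame")
        n = self.topology.n_beads
        for i, fr in enumerate(self.frames):
            if fr.n_beads != n:
                raise ValidationError(
                    f"frame {i} has {fr.n_beads} beads, topology has {n}")
        times = self.times
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise ValidationError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def coordinates(self) -> np.ndarray:
        """(n_frames, n_beads, 3) stacked coordinate array."""
        return np.stack([fr.coordinates for fr in self.frames])


@dataclass
class ElasticNetwork:
    """Harmonic bonds preserving tertiary structure of a coarse-grained protein.

    ``bonds`` rows are (bead_i, bead_j) with i < j; rest lengths are the
    build-time pair distances (nm); force constants in kJ mol^-1 nm^-2.
    """

    bonds: np.ndarray
    rest_length: np.ndarray
    force_constant: np.ndarray

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.rest_length = np.asarray(self.rest_length, dtype=np.float64)
        self.force_constant = np.asarray(self.force_constant, dtype=np.float64)
        if len(self.bonds) != len(self.rest_length) or len(self.bonds) != len(self.force_constant):
            raise ValidationError("bond arrays must have equal length")
        if len(self.bonds):
            if not (self.bonds[:, 0] < self.bonds[:, 1]).all():
                raise ValidationError("bonds must satisfy i < j")
            pairs = {tuple(b) for b in self.bonds}
            if len(pairs) != len(self.bonds):
                raise ValidationError("duplicate bonds")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def as_tuples(self) -> list[tuple[int, int, float, float]]:
        return [
            (int(i), int(j), float(r), float(k))
            for (i, j), r, k in zip(self.bonds, self.rest_length, self.force_constant)
        ]


# ---------------------------------------------------------------------------
# Periodic-boundary geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to their minimum periodic image."""
    return displacement - box * np.round(displacement / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image Euclidean distances."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, box)
    return np.sqrt((d * d).sum(axis=-1))


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def as_indices(selection, n: int) -> np.ndarray:
    """Normalize a bead selection (mask or index sequence) to an index array."""
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValidationError("boolean selection has wrong length")
        return np.flatnonzero(sel)
    sel = sel.astype(np.int64).ravel()
    if len(sel) and (sel.min() < 0 or sel.max() >= n):
        raise ValidationError("bead index out of range")
    return sel
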