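"""Readers and writers for every on-disk artifact.

Formats
-------
GRO   fixed-column GROMACS coordinate format, nm; a trajectory is stored as
      the portable concatenated multi-frame dialect (title line carries the
      time stamp as ``t= <ns>``). The GRO file holds no charges, classes or
      flags, so every written system is accompanied by a topology TSV
      sidecar, which is the authoritative source of bead metadata; reading a
      bare GRO infers what it can (molecule class from residue names,
      leaflets from head-bead z) and should be followed by attaching the
      sidecar when available.
TSV   topology sidecars, analysis tables and timelines; writers prepend
      header comments recording tool version, config hash and seed.
PDB   read-only, via MDAnalysis; chain and insertion codes are preserved as
      extra metadata columns.

All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import IntegrityError, ParseError, SchemaError, ValidationError
from .topology import (
    BeadTopology,
    Frame,
    Trajectory,
    TOPOLOGY_COLUMNS,
)

_FIXTURE_NAME = "fak_pip2_contact_matrix.tsv"
_FIXTURE_SHA256 = "4922a10746a18a90129c610be3af169044406bc329bdc0716d45dce75369eb75"


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _format_gro_frame(topology: BeadTopology, frame: Frame, title: str) -> str:
    lines = [f"{title} t= {frame.time:.6f}", f"{frame.n_beads:5d}"]
    for i in range(frame.n_beads):
        resid = int(topology.residue_id[i]) % 100000
        atomid = (i + 1) % 100000
        x, y, z = frame.coordinates[i]
        lines.append(
            f"{resid:5d}{str(topology.residue_name[i])[:5]:<5s}"
            f"{str(topology.bead_name[i])[:5]:>5s}{atomid:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    return "\n".join(lines) + "\n"


def write_gro(
    path,
    topology: BeadTopology,
    frames: Frame | Sequence[Frame],
    title: str = "pipsites coarse-grained system",
) -> None:
    """Write one or more frames as (multi-frame) GRO."""
    if isinstance(frames, Frame):
        frames = [frames]
    if not frames:
        raise ValidationError("no frames to write")
    for fr in frames:
        if fr.n_beads != topology.n_beads:
            raise ValidationError("frame bead count does not match topology")
    with open(path, "w", newline="\n") as fh:
        for fr in frames:
            fh.write(_format_gro_frame(topology, fr, title))


_CLASS_FROM_RESNAME = {"DOPC": "DOPC", "PIP2": "PIP2",
                       "NA": "ion", "CL": "ion", "ION": "ion"}


def _infer_topology(names, resids, resnames, coords0) -> BeadTopology:
    """Best-effort bead metadata from a bare coordinate file.

    Molecule classes come from residue names; leaflets from each lipid's z
    relative to the lipid median; charges and phosphate flags are guessed
    from PIP2 head-bead naming. Attach a topology TSV for authoritative data.
    """
    n = len(names)
    resnames = np.asarray(resnames, dtype=object)
    cls = np.array([_CLASS_FROM_RESNAME.get(str(r), "protein") for r in resnames],
                   dtype=object)
    lipid = np.isin(cls, ("DOPC", "PIP2"))
    leaflet = np.full(n, "", dtype=object)
    if lipid.any():
        z_mid = np.median(coords0[lipid, 2])
        leaflet[lipid] = np.where(coords0[lipid, 2] >= z_mid, "upper", "lower")
    is_phos = (cls == "PIP2") & np.char.startswith(
        np.asarray(names, dtype=str), "P")
    # molecules: one per lipid/ion residue, one for the whole protein chain
    mol = np.zeros(n, dtype=np.int64)
    next_mol = 1
    prot = cls == "protein"
    if prot.any():
        mol[prot] = next_mol
        next_mol += 1
    key = None
    for i in np.flatnonzero(~prot):
        k = (resids[i], str(resnames[i]))
        if k != key:
            key = k
            mol[i] = next_mol
            next_mol += 1
        else:
            mol[i] = mol[i - 1]
    charge = np.where(is_phos, -5.0, 0.0)
    return BeadTopology(
        np.asarray(names, dtype=object), np.asarray(resids, dtype=np.int64),
        resnames, mol, cls, charge, is_phos, leaflet,
    )


def read_gro(path) -> tuple[BeadTopology, list[Frame]]:
    """Read a single- or multi-frame GRO file.

    Returns a *partial* topology (inferred — see module docstring) and the
    frame list. Malformed counts or truncation raise ParseError with the
    offending line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError("empty GRO file", path=path, line=1)

    frames: list[Frame] = []
    meta = None
    lineno = 0
    while lineno < len(lines):
        if lines[lineno].strip() == "" and all(
                not l.strip() for l in lines[lineno:]):
            break
        title = lines[lineno]
        if lineno + 1 >= len(lines):
            raise ParseError("missing atom count line", path=path, line=lineno + 2)
        try:
            natoms = int(lines[lineno + 1].strip())
        except ValueError:
            raise ParseError(
                f"malformed atom count line {lines[lineno + 1]!r}",
                path=path, line=lineno + 2) from None
        start = lineno + 2
        end = start + natoms
        if end + 1 > len(lines):
            raise ParseError("truncated frame", path=path, line=len(lines))
        names, resids, resnames = [], [], []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            line = lines[start + k]
            try:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
                coords[k] = [float(line[20:28]), float(line[28:36]),
                             float(line[36:44])]
            except (ValueError, IndexError):
                raise ParseError(f"malformed atom line {line!r}",
                                 path=path, line=start + k + 1) from None
        box_fields = lines[end].split()
        if len(box_fields) < 3:
            raise ParseError("malformed box line", path=path, line=end + 1)
        box = np.array([float(v) for v in box_fields[:3]])
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                time = 0.0
        if meta is None:
            meta = (names, resids, resnames)
        frames.append(Frame(coords, box, time=time))
        lineno = end + 1

    if not frames:
        raise ParseError("no frames found", path=path, line=1)
    names, resids, resnames = meta
    topology = _infer_topology(names, np.asarray(resids), resnames,
                               frames[0].coordinates)
    return topology, frames


# ---------------------------------------------------------------------------
# topology sidecar TSV
# ---------------------------------------------------------------------------

def write_topology_tsv(path, topology: BeadTopology) -> None:
    df = topology.to_dataframe()
    df["leaflet"] = df["leaflet"].replace("", "none")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_topology_tsv(path) -> BeadTopology:
    """Read a topology sidecar; lossless round trip of all fields.

    Unknown columns are preserved in ``topology.extras``. A charge column
    containing a unicode minus sign (−) is rejected outright — ambiguous
    numerics are an error, not a guess.
    """
    df = pd.read_csv(path, sep="\t", dtype={"charge": str, "leaflet": str})
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"topology file {path} lacks required column(s): "
                          + ", ".join(missing))
    bad = df["charge"].astype(str).str.contains("−")
    if bad.any():
        raise SchemaError(
            f"topology file {path}: charge column contains a unicode minus "
            f"sign (row {int(np.flatnonzero(bad)[0]) + 2}); use ASCII '-'")
    try:
        df["charge"] = df["charge"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"topology file {path}: non-numeric charge ({exc})") from None
    df["leaflet"] = df["leaflet"].fillna("none").replace("none", "")
    if df["is_phosphate"].dtype == object:
        df["is_phosphate"] = df["is_phosphate"].astype(str).str.lower().map(
            {"true": True, "false": False})
        if df["is_phosphate"].isna().any():
            raise SchemaError(f"topology file {path}: non-boolean is_phosphate")
    return BeadTopology.from_dataframe(df)


# ---------------------------------------------------------------------------
# PDB (read-only, via MDAnalysis)
# ---------------------------------------------------------------------------

def read_pdb(path) -> tuple[BeadTopology, Frame]:
    """Read protein (heavy-atom or CG bead) coordinates from a PDB file.

    Coordinates are converted from Å to nm. Chain identifiers and insertion
    codes survive in ``topology.extras``. All atoms are classed as protein
    with zero charge — a topology sidecar overrides when present.
    """
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse PDB: {exc}", path=path) from exc
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise ParseError("PDB contains no atoms", path=path)
    extras = pd.DataFrame({
        "chain": [getattr(a, "chainID", "") or getattr(a, "segid", "") for a in atoms],
        "insertion_code": [getattr(a, "icode", "") for a in atoms],
    })
    topology = BeadTopology(
        np.array([a.name for a in atoms], dtype=object),
        np.array([a.resid for a in atoms], dtype=np.int64),
        np.array([a.resname for a in atoms], dtype=object),
        np.ones(n, dtype=np.int64),
        np.full(n, "protein", dtype=object),
        np.zeros(n),
        np.zeros(n, dtype=bool),
        np.full(n, "", dtype=object),
        extras=extras,
    )
    coords = atoms.positions.astype(np.float64) / 10.0
    box = u.dimensions[:3] / 10.0 if u.dimensions is not None else None
    if box is None or not (box > 0).all():
        span = coords.max(axis=0) - coords.min(axis=0)
        box = span + 2.0
    return topology, Frame(coords, np.asarray(box, dtype=float), time=0.0)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table_tsv(path, df: pd.DataFrame, metadata: Mapping[str, object] | None = None) -> None:
    """Write a results table with a reproducibility header comment."""
    header = {"tool": f"pipsites {__version__}"}
    if metadata:
        header.update(metadata)
    buf = io.StringIO()
    for key, value in header.items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# packaged contact-matrix fixture
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrixFixture:
    """A published per-residue contact-occupancy matrix (% units).

    Rows are independent simulations, columns residue labels in the
    one-letter-amino-acid + residue-number convention (e.g. K621).
    """

    simulations: list[str]
    residues: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.simulations), len(self.residues)):
            raise ValidationError("fixture dimensions inconsistent")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValidationError("fixture percentages outside [0, 100]")

    def value(self, simulation: str, residue: str) -> float:
        return float(self.values[self.simulations.index(simulation),
                                 self.residues.index(residue)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.simulations,
                            columns=self.residues)

    def fractions(self) -> pd.DataFrame:
        """The matrix as occupancy fractions (divided by 100)."""
        return self.to_dataframe() / 100.0

    def residue_numbers(self) -> dict[str, int]:
        """Map residue labels to integer residue ids (K621 -> 621)."""
        return {label: int(label[1:]) for label in self.residues}


def load_contact_fixture() -> ContactMatrixFixture:
    """Load the packaged FAK–PIP2 per-residue contact matrix (3 sims × 15 residues)."""
    resource = importlib.resources.files("pipsites").joinpath(
        "data", _FIXTURE_NAME)
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"packaged fixture {_FIXTURE_NAME} failed its checksum "
            f"({digest[:12]}... != {_FIXTURE_SHA256[:12]}...)")
    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    sims = df["simulation"].astype(str).tolist()
    residues = [c for c in df.columns if c != "simulation"]
    return ContactMatrixFixture(sims, residues,
                                df[residues].to_numpy(dtype=float))


def write_trajectory(path, traj: Trajectory, title: str = "pipsites trajectory") -> None:
    write_gro(path, traj.topology, traj.frames, title=title)


def read_trajectory(gro_path, topology_path=None) -> Trajectory:
    """Read a multi-frame GRO, attaching an authoritative topology sidecar if given."""
    inferred, frames = read_gro(gro_path)
    topology = read_topology_tsv(topology_path) if topology_path else inferred
    if topology.n_beads != frames[0].n_beads:
        raise ValidationError("topology sidecar bead count does not match GRO")
    return Trajectory(topology, frames)
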