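"""Data model and I/O: trajectories, tables, configuration.

A :class:`Trajectory` is the package's in-memory container for time-ordered
particle coordinates.  It can be populated from standard MD formats
(PDB topology plus DCD/XTC coordinates, via MDAnalysis) or from a plain CSV
dialect designed for hand-written test fixtures::

    time_ns,id,species,x,y,z

with one row per particle per frame.  Protein fixtures may carry three extra
columns ``resname,resid,name``.  Coordinates are stored in angstrom and times
in ns; particles are persistent (same id set in every frame) and frame times
must be strictly increasing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("porekinetics")

SPECIES_ION_CL = "ion:Cl"
SPECIES_ION_K = "ion:K"
SPECIES_ION_CA = "ion:Ca"
SPECIES_WATER = "water"
SPECIES_PROTEIN = "protein"

#: default mapping from force-field residue names to species labels.
#: User-extensible: pass an updated copy to :func:`read_trajectory`.
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "CLA": SPECIES_ION_CL,
    "CL": SPECIES_ION_CL,
    "POT": SPECIES_ION_K,
    "K": SPECIES_ION_K,
    "CAL": SPECIES_ION_CA,
    "CA2": SPECIES_ION_CA,
    "TIP3": SPECIES_WATER,
    "TIP3P": SPECIES_WATER,
    "HOH": SPECIES_WATER,
    "SOL": SPECIES_WATER,
    "WAT": SPECIES_WATER,
}

_KNOWN_SPECIES = {SPECIES_ION_CL, SPECIES_ION_K, SPECIES_ION_CA,
                  SPECIES_WATER, SPECIES_PROTEIN}


class UnknownSpeciesError(ValueError):
    """Raised when a residue name cannot be mapped to a species."""


@dataclass
class Trajectory:
    """Time-ordered frames of labeled particle coordinates.

    Attributes
    ----------
    times : (n_frames,) float array, ns
    coords : (n_frames, n_particles, 3) float array, angstrom
    species : (n_particles,) str array, one of ion:Cl, ion:K, ion:Ca,
        water, protein
    ids : (n_particles,) int array, persistent particle identifiers
    box : (3,) float array, box lengths in angstrom
    resnames, resids, atomnames : optional per-particle protein metadata
    """

    times: np.ndarray
    coords: np.ndarray
    species: np.ndarray
    ids: np.ndarray
    box: np.ndarray
    resnames: np.ndarray | None = None
    resids: np.ndarray | None = None
    atomnames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.species = np.asarray(self.species)
        self.ids = np.asarray(self.ids)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if self.coords.shape[1] != self.species.shape[0]:
            raise ValueError("species and coords disagree on particle count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def select(self, species: str) -> np.ndarray:
        """Boolean mask of particles of a given species."""
        return self.species == species

    def frame_spacing(self) -> float:
        """Time between saved frames in ns (constant spacing assumed)."""
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        return float(self.times[1] - self.times[0])

    @property
    def total_time_ns(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class RunConfig:
    """Analysis run configuration.

    Every stochastic operation consumes an explicit seed so that identical
    configurations yield identical outputs.
    """

    temperature: float = 303.15
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def species_from_resname(resname: str,
                         species_map: Mapping[str, str] | None = None,
                         strict: bool = False) -> str:
    """Map a residue name to a species label.

    Unmapped residue names fall back to ``protein``; with ``strict=True``
    they raise :class:`UnknownSpeciesError` naming the offending residue.
    """
    m = DEFAULT_SPECIES_MAP if species_map is None else species_map
    name = resname.upper()
    if name in m:
        return m[name]
    if strict:
        raise UnknownSpeciesError(f"unknown residue name: {resname!r}")
    return SPECIES_PROTEIN


_CSV_COLUMNS = ["time_ns", "id", "species", "x", "y", "z"]
_CSV_META = ["resname", "resid", "name"]


def read_trajectory(topology_path: str | Path | None = None,
                    coords_path: str | Path | None = None,
                    table_path: str | Path | None = None,
                    box: Sequence[float] | None = None,
                    species_map: Mapping[str, str] | None = None) -> Trajectory:
    """Read a trajectory from PDB(+DCD/XTC) or from the CSV fixture dialect.

    Exactly one source must be given: ``table_path`` for CSV, or
    ``topology_path`` (with an optional ``coords_path``) for MD formats.
    """
    if table_path is not None:
        return _read_trajectory_csv(table_path, box=box)
    if topology_path is None:
        raise ValueError("need either topology_path or table_path")
    return _read_trajectory_md(topology_path, coords_path, species_map=species_map)


def _read_trajectory_csv(path: str | Path, box: Sequence[float] | None = None) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV trajectory missing columns: {missing}")
    bad = set(df["species"].unique()) - _KNOWN_SPECIES
    if bad:
        raise UnknownSpeciesError(f"unknown species labels in CSV: {sorted(bad)}")
    times = np.array(sorted(df["time_ns"].unique()), dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("non-monotonic frame times")
    first = df[df["time_ns"] == times[0]].sort_values("id")
    ids = first["id"].to_numpy()
    species = first["species"].to_numpy()
    n = len(ids)
    coords = np.empty((times.size, n, 3))
    for k, t in enumerate(times):
        fr = df[df["time_ns"] == t].sort_values("id")
        if len(fr) != n or not np.array_equal(fr["id"].to_numpy(), ids):
            raise ValueError(f"frame at t={t} ns has an inconsistent particle set")
        coords[k] = fr[["x", "y", "z"]].to_numpy()
    has_meta = all(c in df.columns for c in _CSV_META)
    resnames = first["resname"].to_numpy() if has_meta else None
    resids = first["resid"].to_numpy() if has_meta else None
    atomnames = first["name"].to_numpy() if has_meta else None
    if box is None:
        span = coords.reshape(-1, 3).max(axis=0) - coords.reshape(-1, 3).min(axis=0)
        box = np.maximum(span, 1.0)
    return Trajectory(times=times, coords=coords, species=species, ids=ids,
                      box=np.asarray(box, float), resnames=resnames,
                      resids=resids, atomnames=atomnames)


def _read_trajectory_md(topology_path, coords_path, species_map=None) -> Trajectory:
    import MDAnalysis as mda

    if coords_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(coords_path))
    atoms = u.atoms
    species = np.array([species_from_resname(rn, species_map) for rn in atoms.resnames])
    ids = np.arange(atoms.n_atoms)
    times, frames, boxes = [], [], []
    for ts in u.trajectory:
        times.append(ts.time / 1000.0)  # MDAnalysis ps -> ns
        frames.append(atoms.positions.astype(float).copy())
        boxes.append(ts.dimensions[:3].copy() if ts.dimensions is not None else None)
    times = np.asarray(times)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        # some writers store zero/constant times; synthesize a unit grid
        if np.allclose(np.diff(times), 0):
            times = np.arange(times.size, dtype=float)
        else:
            raise ValueError("non-monotonic frame times in trajectory")
    box = boxes[-1]
    if box is None or np.all(box == 0):
        span = np.concatenate(frames).max(axis=0) - np.concatenate(frames).min(axis=0)
        box = np.maximum(span, 1.0)
    return Trajectory(times=times, coords=np.stack(frames), species=species,
                      ids=ids, box=np.asarray(box, float),
                      resnames=atoms.resnames.copy(),
                      resids=atoms.resids.copy(),
                      atomnames=atoms.names.copy())


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the CSV fixture dialect (round-trips with read)."""
    n_frames, n, _ = traj.coords.shape
    data = {
        "time_ns": np.repeat(traj.times, n),
        "id": np.tile(traj.ids, n_frames),
        "species": np.tile(traj.species, n_frames),
        "x": traj.coords[:, :, 0].ravel(),
        "y": traj.coords[:, :, 1].ravel(),
        "z": traj.coords[:, :, 2].ravel(),
    }
    if traj.resnames is not None:
        data["resname"] = np.tile(traj.resnames, n_frames)
        data["resid"] = np.tile(traj.resids, n_frames)
        data["name"] = np.tile(traj.atomnames, n_frames)
    pd.DataFrame(data).to_csv(path, index=False)


def write_table(rows, schema: Sequence[str], path: str | Path) -> None:
    """Write rows as CSV with a header; re-reading reproduces the input.

    ``rows`` may be a DataFrame (columns must match the schema), a sequence of
    dicts, or a sequence of tuples in schema order.
    """
    if isinstance(rows, pd.DataFrame):
        if list(rows.columns) != list(schema):
            raise ValueError(f"schema mismatch: {list(rows.columns)} != {list(schema)}")
        df = rows
    else:
        rows = list(rows)
        if rows and isinstance(rows[0], dict):
            for r in rows:
                if set(r) != set(schema):
                    raise ValueError(f"schema mismatch in row: {sorted(r)}")
            df = pd.DataFrame(rows, columns=list(schema))
        else:
            for r in rows:
                if len(r) != len(schema):
                    raise ValueError("schema mismatch: wrong number of fields")
            df = pd.DataFrame(rows, columns=list(schema))
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def aggregate_subunit_time_us(n_replicates: int, n_models: int,
                              t_us_per_run: float, n_subunits: int = 2) -> float:
    """Total per-subunit simulation time for a replicated multi-model campaign.

    Each run simulates one dimer for ``t_us_per_run`` microseconds; each of
    the ``n_subunits`` pores contributes independently, so e.g. 3 replicates
    of 4 starting models at 1 us each total 24 us of subunit time.
    """
    return float(n_replicates * n_models * t_us_per_run * n_subunits)
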