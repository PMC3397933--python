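"""File formats and configuration: COLVAR/HILLS tables, XYZ, minimal PDB, YAML.

COLVAR and HILLS files are whitespace tables with a single '#' header line
naming the columns, following the conventions of metadynamics plugins.
Coordinates are nm internally; PDB files use Angstrom (converted on the way
in and out), XYZ files carry a ``units=`` tag in the comment line and default
to nm.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .cvs import CVDefinition, Wall
from .metad import GaussianHill, HillsLedger

__all__ = [
    "ParseError",
    "read_colvar", "write_colvar",
    "read_hills", "write_hills",
    "read_conformations", "write_conformations",
    "RunConfig", "load_config", "dump_config",
    "RunManifest",
]


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


# ---------------------------------------------------------------------------
# COLVAR / HILLS whitespace tables

def _read_table(path, expected_min_cols: int) -> tuple[list, list]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise ParseError(f"{path}:1: missing '#' header line")
    header = lines[0].lstrip("#").split()
    if len(header) < expected_min_cols:
        raise ParseError(f"{path}:1: header names {len(header)} columns, "
                         f"expected at least {expected_min_cols}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return header, rows


def read_colvar(path) -> pd.DataFrame:
    """Read a COLVAR-style table; the time column must be non-decreasing."""
    header, rows = _read_table(path, 2)
    if header[0] != "time":
        raise ParseError(f"{path}:1: first column must be 'time', got {header[0]!r}")
    df = pd.DataFrame(rows, columns=header)
    t = df["time"].to_numpy()
    bad = np.where(np.diff(t) < 0)[0]
    if bad.size:
        raise ParseError(f"{path}:{int(bad[0]) + 3}: time column decreases")
    if "assignment" in df.columns:
        df["assignment"] = df["assignment"].astype(int)
    return df


def write_colvar(path, df: pd.DataFrame) -> None:
    cols = list(df.columns)
    with open(path, "w") as fh:
        fh.write("# " + " ".join(cols) + "\n")
        for _, row in df.iterrows():
            fh.write(" ".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if float(v).is_integer() and abs(v) < 1e15:
        return "%.1f" % v
    return repr(float(v))


def read_hills(path, cv_name: Optional[str] = None) -> HillsLedger:
    """Read a HILLS-style table (time, center, sigma, height) into a ledger."""
    header, rows = _read_table(path, 4)
    want = ["time", "center", "sigma", "height"]
    if header[:4] != want:
        raise ParseError(f"{path}:1: expected columns {want}, got {header[:4]}")
    times = [r[0] for r in rows]
    if len(times) >= 2:
        pace = times[1] - times[0]
    elif times:
        pace = times[0]
    else:
        pace = 1.0
    ledger = HillsLedger(cv_name or Path(path).stem, pace)
    for lineno, r in enumerate(rows, start=2):
        t, c, s, h = r[:4]
        if s <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive sigma {s}")
        if h < 0:
            raise ParseError(f"{path}:{lineno}: negative height {h}")
        try:
            ledger.append(GaussianHill(center=c, width=s, height=h, deposit_time=t))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return ledger


def write_hills(path, ledger: HillsLedger) -> None:
    with open(path, "w") as fh:
        fh.write("# time center sigma height\n")
        for c, w, h, t in zip(ledger.centers, ledger.widths, ledger.heights, ledger.times):
            fh.write(f"{_fmt(t)} {_fmt(c)} {_fmt(w)} {_fmt(h)}\n")


# ---------------------------------------------------------------------------
# conformations: XYZ and minimal PDB

def write_conformations(path, coords: np.ndarray, labels: Optional[list] = None,
                        fmt: Optional[str] = None, times: Optional[np.ndarray] = None) -> None:
    """Write a stack of conformations (n_frames, n_atoms, 3; nm) as XYZ or PDB."""
    path = Path(path)
    fmt = fmt or ("pdb" if path.suffix.lower() == ".pdb" else "xyz")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    if labels is None:
        names = ["X"] * n_atoms
    else:
        names = [_primary_label(l) for l in labels]
    if fmt == "xyz":
        with open(path, "w") as fh:
            for f in range(n_frames):
                fh.write(f"{n_atoms}\n")
                t = times[f] if times is not None else f
                fh.write(f"frame={f} time={t} units=nm\n")
                for a in range(n_atoms):
                    x, y, z = (float(v) for v in coords[f, a])
                    fh.write(f"{names[a]:<6s} {x!r} {y!r} {z!r}\n")
    elif fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile
        arr = struc.AtomArrayStack(n_frames, n_atoms)
        arr.coord = coords * 10.0  # nm -> Angstrom
        arr.atom_name = np.array([n[:4] for n in names])
        arr.res_name = np.array(["BEA"] * n_atoms)
        arr.res_id = np.arange(1, n_atoms + 1)
        arr.chain_id = np.array(["A"] * n_atoms)
        arr.element = np.array(["C"] * n_atoms)
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _primary_label(label) -> str:
    if isinstance(label, str):
        return label
    for pref in ("ligand_c1", "ligand", "calpha", "cgamma", "proton"):
        if pref in label:
            return {"ligand_c1": "LC1", "ligand": "LIG", "calpha": "CA",
                    "cgamma": "CG", "proton": "H"}[pref]
    return sorted(label)[0][:4]


def read_conformations(path, fmt: Optional[str] = None):
    """Read conformations; returns (coords [n_frames, n_atoms, 3] in nm, names)."""
    path = Path(path)
    fmt = fmt or ("pdb" if path.suffix.lower() == ".pdb" else "xyz")
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure()
        coords = np.asarray(arr.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        return coords / 10.0, list(arr.atom_name)  # Angstrom -> nm
    frames = []
    names0: list = []
    lines = path.read_text().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        scale = 1.0
        for tok in comment.split():
            if tok.startswith("units="):
                scale = 0.1 if tok.split("=", 1)[1] in ("A", "angstrom", "Angstrom") else 1.0
        frame = []
        names = []
        for k in range(n):
            idx = i + 2 + k
            if idx >= len(lines):
                raise ParseError(f"{path}:{idx + 1}: truncated frame")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{idx + 1}: expected 'name x y z'")
            names.append(parts[0])
            frame.append([float(p) * scale for p in parts[1:4]])
        if names0 and (len(names) != len(names0)):
            raise ParseError(f"{path}:{i + 1}: atom count differs between frames")
        names0 = names0 or names
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}:1: no frames found")
    return np.asarray(frames, dtype=float), names0


# ---------------------------------------------------------------------------
# configuration

class WallConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lower: float
    upper: float
    k: float = 100.0


class CVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    kind: str
    sigma: float
    params: dict = {}
    groups: dict = {}
    wall: Optional[WallConfig] = None

    def build(self) -> CVDefinition:
        wall = Wall(self.wall.lower, self.wall.upper, self.wall.k) if self.wall else None
        return CVDefinition(name=self.name, kind=self.kind, sigma=self.sigma,
                            params=dict(self.params), groups=dict(self.groups), wall=wall)


class SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str                      # 'double_well' | 'two_basin_2d' | 'bead_peptide'
    params: dict = {}

    def build(self):
        from .bead_model import make_bead_peptide
        from .potentials import make_double_well, make_two_basin_2d
        if self.kind == "double_well":
            return make_double_well(**self.params)
        if self.kind == "two_basin_2d":
            return make_two_basin_2d(**self.params)
        if self.kind == "bead_peptide":
            return make_bead_peptide(**self.params)
        raise ValueError(f"unknown system kind {self.kind!r}")


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_time: float
    hill_height: float = 0.2
    tau_deposit: float = 2.0
    tau_exchange: float = 20.0
    save_stride: float = 2.0
    discard_time: Optional[float] = None
    temperature: float = 300.0
    timestep: float = 0.005
    friction: float = 1.0


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_cvs: List[str] = []
    min_occupancy: int = 5
    fes_threshold_kt: float = 6.0
    cluster_cutoff: float = 3.5      # Angstrom
    contact_cutoff: float = 3.0      # Angstrom
    rmsd_threshold: float = 2.5      # Angstrom
    ligand_weight: float = 3.0
    excluded_labels: List[str] = []


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected with their location."""

    model_config = ConfigDict(extra="forbid")
    system: SystemConfig
    cvs: List[CVConfig]
    schedule: ScheduleConfig
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int
    out_dir: str = "results/run"

    @model_validator(mode="after")
    def _check(self):
        if self.schedule.discard_time is not None and (
            self.schedule.discard_time >= self.schedule.total_time
        ):
            raise ValueError("equilibration discard must be smaller than the total time")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from None


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Hash of the computation-defining fields (the output path is excluded)."""
    payload = config.model_dump_json(exclude={"out_dir"})
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """Per-run provenance: config hash, seed, stage outputs and timings."""

    config_hash: str
    seed: int
    package_version: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {name: sha256}, seconds: float}

    def add_stage(self, name: str, files: dict, seconds: float) -> None:
        self.stages[name] = {"files": files, "seconds": round(seconds, 3)}

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "package_version": self.package_version, "stages": self.stages},
            indent=2, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX

    @staticmethod
    def file_sha256(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
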