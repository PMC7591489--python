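"""Readers and writers for the plain-text formats the analyses consume.

Two-column radial profiles and umbrella time series arrive either as
Gromacs XVG tables (with ``#`` and ``@`` comment conventions) or as CSV;
model parameters come from YAML or TOML config files with ``[ligand]`` and
``[core]`` tables; umbrella manifests are CSV listing one window file per
row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .capping import CoreSpec, LigandSpec
from .electrokinetics import RadialProfile
from .wham import UmbrellaWindow

__all__ = [
    "read_xvg",
    "read_two_column",
    "read_radial_profile",
    "load_config",
    "specs_from_config",
    "read_umbrella_manifest",
    "write_pmf_csv",
    "write_profile_csv",
]


def read_xvg(path: str | Path) -> np.ndarray:
    """Read a numeric XVG table, skipping # and @ comment lines."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line[0] in "#@":
            continue
        rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


def read_two_column(path: str | Path) -> np.ndarray:
    """Read a two-column table from XVG or CSV, auto-detected by content."""
    path = Path(path)
    text = path.read_text()
    if "," in text.splitlines()[0] or path.suffix.lower() == ".csv":
        rows = []
        for row in csv.reader(text.splitlines()):
            if not row or not row[0].strip():
                continue
            try:
                rows.append([float(x) for x in row[:2]])
            except ValueError:
                continue  # header
        return np.asarray(rows)
    return read_xvg(path)[:, :2]


def read_radial_profile(path: str | Path, species: str = "") -> RadialProfile:
    data = read_two_column(path)
    return RadialProfile(data[:, 0], data[:, 1], species=species)


def load_config(path: str | Path) -> dict:
    """Load a YAML or TOML config file into a dict."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib
        return tomllib.loads(path.read_text())
    import yaml
    return yaml.safe_load(path.read_text())


def specs_from_config(config: dict) -> tuple[LigandSpec, CoreSpec]:
    """Build LigandSpec/CoreSpec from a config with [ligand] and [core]
    tables; missing fields use the dataclass defaults."""
    lig = dict(config.get("ligand", {}))
    core = dict(config.get("core", {}))
    return LigandSpec(**lig), CoreSpec(**core)


def read_umbrella_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Read an umbrella manifest CSV with columns
    ``file,center,force_constant,discard``; each referenced file is a
    two-column (time, CV1) series relative to the manifest location."""
    path = Path(path)
    windows = []
    with path.open() as fh:
        for row in csv.DictReader(fh):
            series = read_two_column(path.parent / row["file"])
            windows.append(UmbrellaWindow(
                center=float(row["center"]),
                samples=series[:, 1],
                force_constant=float(row.get("force_constant", 5000.0)),
                equilibration_discard=int(row.get("discard", 0) or 0)))
    if not windows:
        raise ValueError(f"{path}: empty manifest")
    return windows


def write_pmf_csv(pmf, path: str | Path) -> None:
    lines = ["cv1_nm,free_energy_kt"]
    for x, f in zip(pmf.cv1_grid, pmf.free_energy):
        lines.append(f"{x:.6f},{f:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_csv(profile: RadialProfile, path: str | Path) -> None:
    lines = ["r_nm,value"]
    for r, v in zip(profile.r, profile.values):
        lines.append(f"{r:.6f},{v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
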