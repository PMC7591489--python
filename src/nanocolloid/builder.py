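"""Coarse-grained bead-shell nanoparticle builder.

Builds hollow spherical shells of beads arranged as stacked latitudinal
rings, holds them together with an elastic network (each bead bonded to its
six nearest neighbours and its single farthest bead), and assigns discrete
-2 e surface charges until a target net charge is reached. Writers emit PDB
and GRO coordinates, an ITP-style bond section, and JSON metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BeadShell",
    "ChargePlan",
    "build_shell",
    "elastic_network",
    "assign_charges",
    "apply_charge_plan",
    "sigma_grid",
    "sigma_to_net_charge",
    "net_charge_to_sigma",
    "write_gro",
    "write_pdb",
    "write_bonds_itp",
    "write_bonds_csv",
    "write_metadata",
    "read_gro",
]

DEFAULT_BEAD_MASS = 556.0       # u; accounts for bulk internal beads
DEFAULT_BEAD_VDW_RADIUS = 0.264  # nm, CG bead contact radius
DEFAULT_FORCE_CONSTANT = 15000.0  # kJ mol^-1 nm^-2
CHARGE_QUANTUM = -2.0            # e per charged surface bead


@dataclass
class BeadShell:
    """A spherical shell of CG beads with optional bonds and charges."""

    positions: np.ndarray                    # (n, 3) nm
    bead_vdw_radius: float = DEFAULT_BEAD_VDW_RADIUS
    masses: np.ndarray | None = None         # (n,) u
    charges: np.ndarray | None = None        # (n,) e, 0 or -2
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        if self.masses is None:
            self.masses = np.full(n, DEFAULT_BEAD_MASS)
        if self.charges is None:
            self.charges = np.zeros(n)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def shell_radius(self) -> float:
        """Radius of the bead-centre sphere, nm."""
        return float(np.linalg.norm(self.positions, axis=1).mean())

    @property
    def vdw_radius(self) -> float:
        """Radius measured at the van der Waals surface, nm."""
        return self.shell_radius + self.bead_vdw_radius

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class ChargePlan:
    """Which beads carry the -2 e surface charges."""

    target_net_charge: float
    charged_bead_indices: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.charged_bead_indices)) != len(self.charged_bead_indices):
            raise ValueError("charged bead indices must be unique")


def _ring_partition(n_beads: int, n_rings: int) -> np.ndarray:
    """Beads per ring, proportional to ring circumference (sin latitude),
    rounded by largest remainder so the total is exact and no ring is empty."""
    theta = np.pi * (np.arange(n_rings) + 0.5) / n_rings
    weights = np.sin(theta)
    ideal = n_beads * weights / weights.sum()
    counts = np.maximum(np.floor(ideal).astype(int), 1)
    rem = n_beads - counts.sum()
    if rem < 0:
        raise ValueError("impossible ring partition: too many rings")
    order = np.argsort(-(ideal - np.floor(ideal)))
    for i in range(rem):
        counts[order[i % n_rings]] += 1
    if counts.sum() != n_beads:
        raise ValueError("impossible ring partition")
    return counts


def build_shell(n_beads: int = 126, vdw_diameter: float = 3.0,
                bead_vdw_radius: float = DEFAULT_BEAD_VDW_RADIUS,
                n_rings: int | None = None) -> BeadShell:
    """Place ``n_beads`` on stacked latitudinal rings of a sphere.

    The sphere of bead centres has radius ``vdw_diameter/2 - bead_vdw_radius``
    so that the van der Waals surface of the assembly sits at the requested
    diameter. Ring count defaults to round(sqrt(pi n)/2)*2; beads per ring
    follow the ring circumference. Alternate rings are offset in azimuth by
    half a spacing to avoid meridian alignment.
    """
    if n_beads < 12:
        raise ValueError("n_beads must be >= 12")
    if vdw_diameter <= 0:
        raise ValueError("vdw_diameter must be > 0")
    radius = vdw_diameter / 2.0 - bead_vdw_radius
    if radius <= 0:
        raise ValueError("vdw_diameter too small for the bead radius")
    if n_rings is None:
        n_rings = int(round(np.sqrt(np.pi * n_beads) / 2.0)) * 2
    counts = _ring_partition(n_beads, n_rings)
    theta = np.pi * (np.arange(n_rings) + 0.5) / n_rings
    pos = []
    for j, (t, m) in enumerate(zip(theta, counts)):
        phi0 = (np.pi / m) * (j % 2)  # stagger alternate rings
        phi = 2.0 * np.pi * np.arange(m) / m + phi0
        pos.append(np.column_stack([
            radius * np.sin(t) * np.cos(phi),
            radius * np.sin(t) * np.sin(phi),
            np.full(m, radius * np.cos(t)),
        ]))
    return BeadShell(np.vstack(pos), bead_vdw_radius=bead_vdw_radius)


def elastic_network(shell: BeadShell,
                    k: float = DEFAULT_FORCE_CONSTANT) -> BeadShell:
    """Bond every bead to its six nearest neighbours and its farthest bead.

    Rest lengths are the built distances; duplicate (i, j) pairs are merged.
    Returns the same shell with its bond list populated.
    """
    n = shell.n_beads
    if n < 8:
        raise ValueError("need at least 8 beads for the 6-nearest + farthest rule")
    d = np.linalg.norm(shell.positions[:, None, :] - shell.positions[None, :, :],
                       axis=-1)
    np.fill_diagonal(d, np.inf)
    pairs: dict[tuple[int, int], float] = {}
    for i in range(n):
        nearest = np.argsort(d[i])[:6]
        row = d[i].copy()
        row[~np.isfinite(row)] = -np.inf
        partners = list(nearest) + [int(np.argmax(row))]
        for j in partners:
            key = (min(i, int(j)), max(i, int(j)))
            pairs[key] = d[key[0], key[1]]
    shell.bonds = [(i, j, r0, k) for (i, j), r0 in sorted(pairs.items())]
    return shell


def assign_charges(shell: BeadShell, target_net_charge: float,
                   seed: int) -> ChargePlan:
    """Pick distinct beads uniformly at random to carry -2 e each until the
    target net charge (a non-positive even number) is reached exactly."""
    if target_net_charge > 0:
        raise ValueError("target_net_charge must be <= 0")
    if abs(target_net_charge) > 2 * shell.n_beads:
        raise ValueError("target net charge exceeds shell capacity")
    n_charged_f = abs(target_net_charge) / 2.0
    if abs(n_charged_f - round(n_charged_f)) > 1e-9:
        raise ValueError(
            "net charge must be a multiple of the -2 e bead quantum; "
            "round to the nearest even value")
    n_charged = int(round(n_charged_f))
    rng = np.random.default_rng(seed)
    idx = tuple(sorted(rng.choice(shell.n_beads, size=n_charged,
                                  replace=False).tolist())) if n_charged else ()
    return ChargePlan(float(target_net_charge), idx, seed)


def apply_charge_plan(shell: BeadShell, plan: ChargePlan) -> BeadShell:
    """Write the plan's -2 e charges onto the shell (in place)."""
    shell.charges = np.zeros(shell.n_beads)
    shell.charges[list(plan.charged_bead_indices)] = CHARGE_QUANTUM
    return shell


def sigma_grid(n_points: int = 14, lo: float = 0.0, hi: float = 5.0) -> np.ndarray:
    """Equidistant inclusive grid of surface charge densities, e nm^-2."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if lo >= hi:
        raise ValueError("need lo < hi")
    return np.linspace(lo, hi, n_points)


def sigma_to_net_charge(sigma: float, reference_radius: float = 1.30) -> float:
    """Convert sigma to a (negative) net charge, rounded to the -2 e quantum."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    area = 4.0 * np.pi * reference_radius**2
    return -2.0 * round(sigma * area / 2.0)


def net_charge_to_sigma(net_charge: float, reference_radius: float = 1.30) -> float:
    """Magnitude of net charge per reference-sphere area, e nm^-2."""
    return abs(net_charge) / (4.0 * np.pi * reference_radius**2)


# ---------------------------------------------------------------------------
# writers / readers

def write_gro(shell: BeadShell, path: str | Path, name: str = "NP",
              box: float = 10.0) -> None:
    """Write bead coordinates as a GRO file (fixed-width, nm)."""
    lines = [f"{name} bead shell", f"{shell.n_beads:5d}"]
    for i, (x, y, z) in enumerate(shell.positions, start=1):
        lines.append(f"{1:5d}{name:<5s}{'NP':>5s}{i:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path: str | Path) -> np.ndarray:
    """Read bead positions (n, 3) nm back from a GRO file."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    pos = [[float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
           for ln in lines[2:2 + n]]
    return np.asarray(pos)


def write_pdb(shell: BeadShell, path: str | Path, name: str = "NP") -> None:
    """Write bead coordinates as a PDB file (Angstrom)."""
    lines = ["TITLE     bead shell"]
    for i, (x, y, z) in enumerate(shell.positions * 10.0, start=1):
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{name:<4s}{1:5d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bonds_itp(shell: BeadShell, path: str | Path) -> None:
    """Write the elastic network as an ITP-style [ bonds ] section
    (1-based indices, harmonic type 1)."""
    lines = ["[ bonds ]", "; i    j  func   r0(nm)   k(kJ/mol/nm2)"]
    for i, j, r0, k in shell.bonds:
        lines.append(f"{i + 1:5d}{j + 1:5d}{1:5d}{r0:10.4f}{k:12.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bonds_csv(shell: BeadShell, path: str | Path) -> None:
    lines = ["i,j,r0_nm,k_kj_mol_nm2"]
    for i, j, r0, k in shell.bonds:
        lines.append(f"{i},{j},{r0:.6f},{k:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata(shell: BeadShell, path: str | Path,
                   plan: ChargePlan | None = None, **extra) -> None:
    meta = {
        "n_beads": shell.n_beads,
        "shell_radius_nm": shell.shell_radius,
        "vdw_radius_nm": shell.vdw_radius,
        "net_charge_e": shell.net_charge,
        "sigma_e_nm2": net_charge_to_sigma(shell.net_charge),
        "n_bonds": len(shell.bonds),
    }
    if plan is not None:
        meta["seed"] = plan.seed
        meta["charged_bead_indices"] = list(plan.charged_bead_indices)
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
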