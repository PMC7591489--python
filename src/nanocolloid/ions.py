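"""Spatially resolved counterion structure around one or two nanoparticles.

Provides the angular number density of ions around a dimerizing pair (the
halo of counterions accumulating near the contact region), transversal
charge-density slices perpendicular to the inter-particle axis, and
residence-time statistics of counterions near the particle surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Snapshot",
    "AngularDensityProfile",
    "PlanarChargeMap",
    "angular_density",
    "planar_charge_density",
    "residence_times",
    "conic_shell_volume",
]

PLANE_TAGS = ("com", "half_radius", "vdw_surface", "midplane")


@dataclass
class Snapshot:
    """One frame: nanoparticle centre(s) and ion coordinates/charges."""

    np_centers: np.ndarray            # (1 or 2, 3) nm
    np_vdw_radius: float              # nm
    ion_positions: np.ndarray         # (m, 3) nm
    ion_charges: np.ndarray           # (m,) e
    ion_species: list[str] | None = None
    bead_positions: np.ndarray | None = None   # (b, 3) nm
    bead_charges: np.ndarray | None = None     # (b,) e
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.np_centers = np.atleast_2d(np.asarray(self.np_centers, float))
        self.ion_positions = np.asarray(self.ion_positions,
                                        float).reshape(-1, 3)
        self.ion_charges = np.asarray(self.ion_charges, float).ravel()
        if len(self.ion_charges) != len(self.ion_positions):
            raise ValueError("ion charges and positions length mismatch")


@dataclass
class AngularDensityProfile:
    theta_edges: np.ndarray     # degrees over [0, 180]
    density: np.ndarray         # nm^-3, mean over frames
    std: np.ndarray             # nm^-3, over frames
    cutoff: float               # nm from the vdW surface
    counts: np.ndarray          # raw in-shell ion counts per bin (all frames)

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


@dataclass
class PlanarChargeMap:
    plane_tag: str
    cv2_edges: np.ndarray       # nm
    cv3_edges: np.ndarray       # nm
    slab_thickness: float       # nm
    charge_density: np.ndarray  # e nm^-3, (n2, n3), mean over frames

    def integrated_charge(self) -> float:
        """Total charge in the slab, e (density x cell volume summed)."""
        d2 = np.diff(self.cv2_edges)[0]
        d3 = np.diff(self.cv3_edges)[0]
        return float(self.charge_density.sum() * d2 * d3 * self.slab_thickness)


def conic_shell_volume(theta1_deg: float, theta2_deg: float,
                       r1: float, r2: float) -> float:
    """Volume (nm^3) of the conic shell between polar angles theta1..theta2
    and radii r1..r2: (2 pi / 3)(cos t1 - cos t2)(r2^3 - r1^3)."""
    t1, t2 = np.radians(theta1_deg), np.radians(theta2_deg)
    return (2.0 * np.pi / 3.0) * (np.cos(t1) - np.cos(t2)) * (r2**3 - r1**3)


def _dimer_axis(snap: Snapshot, reference_np: int) -> np.ndarray:
    if len(snap.np_centers) < 2:
        raise ValueError("two nanoparticle centres required to define the axis")
    other = 1 - reference_np
    axis = snap.np_centers[other] - snap.np_centers[reference_np]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("coincident nanoparticle centres: axis undefined")
    return axis / norm


def angular_density(frames: list[Snapshot], reference_np: int = 0,
                    bin_width: float = 4.0, cutoff: float = 2.0,
                    species: str | None = None) -> AngularDensityProfile:
    """Number density of ions vs the polar angle theta from the inter-particle
    axis, within ``cutoff`` nm of the reference particle's vdW surface.

    theta is measured at the reference particle centre between the axis
    toward the partner particle and the ion position vector; each theta bin
    defines a conic shell whose analytic volume normalises the counts.
    Mean and standard deviation are taken over frames.
    """
    if not frames:
        raise ValueError("no frames supplied")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    if edges[-1] > 180.0 + 1e-9:
        edges = np.append(edges[edges < 180.0], 180.0)
    n_bins = len(edges) - 1
    r_in = frames[0].np_vdw_radius
    r_out = r_in + cutoff
    volumes = np.array([conic_shell_volume(edges[i], edges[i + 1], r_in, r_out)
                        for i in range(n_bins)])
    per_frame = np.zeros((len(frames), n_bins))
    total_counts = np.zeros(n_bins)
    for fi, snap in enumerate(frames):
        axis = _dimer_axis(snap, reference_np)
        rel = snap.ion_positions - snap.np_centers[reference_np]
        if species is not None and snap.ion_species is not None:
            sel = np.array([s == species for s in snap.ion_species])
            rel = rel[sel]
        dist = np.linalg.norm(rel, axis=1)
        in_shell = (dist >= r_in) & (dist <= r_out)
        rel = rel[in_shell]
        dist = dist[in_shell]
        if len(rel) == 0:
            continue
        cos_t = np.clip(rel @ axis / dist, -1.0, 1.0)
        theta = np.degrees(np.arccos(cos_t))
        idx = np.clip(np.searchsorted(edges, theta, side="right") - 1,
                      0, n_bins - 1)
        cnt = np.bincount(idx, minlength=n_bins)
        total_counts += cnt
        per_frame[fi] = cnt / volumes
    return AngularDensityProfile(edges, per_frame.mean(axis=0),
                                 per_frame.std(axis=0), cutoff, total_counts)


def _plane_position(snap: Snapshot, plane_tag: str, reference_np: int) -> float:
    """Axial coordinate of the slicing plane, measured along the dimer axis
    from the reference particle centre."""
    r = snap.np_vdw_radius
    if plane_tag == "com":
        return 0.0
    if plane_tag == "half_radius":
        return r / 2.0
    if plane_tag == "vdw_surface":
        return r
    if plane_tag == "midplane":
        d = np.linalg.norm(snap.np_centers[1] - snap.np_centers[0])
        return d / 2.0
    raise ValueError(f"unknown plane tag {plane_tag!r}; use one of {PLANE_TAGS}")


def planar_charge_density(frames: list[Snapshot], plane_tag: str,
                          slab_thickness: float = 0.2,
                          grid_step: float = 0.1,
                          half_extent: float = 4.0,
                          reference_np: int = 0) -> PlanarChargeMap:
    """Charge density (e nm^-3) on a plane perpendicular to the dimer axis.

    All charged particles (beads and ions) whose axial coordinate falls
    within half a slab thickness of the plane are binned on a (CV2, CV3)
    grid; the map is averaged over frames.
    """
    edges = np.arange(-half_extent, half_extent + grid_step, grid_step)
    n = len(edges) - 1
    acc = np.zeros((n, n))
    any_in_slab = False
    for snap in frames:
        u = _dimer_axis(snap, reference_np)
        # arbitrary orthonormal in-plane basis (CV2, CV3)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        v2 = np.cross(u, helper)
        v2 /= np.linalg.norm(v2)
        v3 = np.cross(u, v2)
        x0 = _plane_position(snap, plane_tag, reference_np)
        pos = [snap.ion_positions]
        chg = [snap.ion_charges]
        if snap.bead_positions is not None:
            pos.append(np.asarray(snap.bead_positions, float).reshape(-1, 3))
            chg.append(np.asarray(snap.bead_charges, float).ravel())
        pos = np.vstack(pos) - snap.np_centers[reference_np]
        chg = np.concatenate(chg)
        ax = pos @ u
        in_slab = np.abs(ax - x0) <= slab_thickness / 2.0
        if not np.any(in_slab):
            continue
        any_in_slab = True
        c2 = pos[in_slab] @ v2
        c3 = pos[in_slab] @ v3
        hist, _, _ = np.histogram2d(c2, c3, bins=[edges, edges],
                                    weights=chg[in_slab])
        acc += hist
    if not any_in_slab:
        warnings.warn(f"no particles in the {plane_tag!r} slab: empty map",
                      stacklevel=2)
    cell_volume = grid_step * grid_step * slab_thickness
    density = acc / (len(frames) * cell_volume)
    return PlanarChargeMap(plane_tag, edges, edges, slab_thickness, density)


def residence_times(distance_series: np.ndarray, cutoff: float,
                    dt: float = 1.0) -> np.ndarray:
    """Durations of maximal runs with surface distance below ``cutoff``.

    ``distance_series`` is one ion's distance-to-surface time series on a
    uniform time step ``dt``; returns the dwell durations in the same time
    unit.
    """
    inside = np.asarray(distance_series) < cutoff
    if not inside.any():
        return np.array([])
    padded = np.concatenate([[False], inside, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return (ends - starts) * dt
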