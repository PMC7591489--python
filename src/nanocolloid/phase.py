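"""Dispersion-state phase diagrams over (surface charge density, ionic strength).

Assembles rectangular grids of zeta potentials or dimerization free
energies, extracts stability boundaries by marching-squares contouring
(zeta = +/-30 mV, or the dimerization band -1.0 +/- 0.5 kT), locates the
critical ionic strength of a single row, models the linear dependence of
the dimerization free energy on the metal-metal Lennard-Jones well depth
(a hydrophobicity proxy for particle size), and computes the UV-vis
aggregation index Abs650/Absmax from absorbance spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .wham import BAND_CENTER_KT, BAND_HALF_WIDTH_KT

__all__ = [
    "PhaseGrid",
    "PhaseBoundary",
    "AggregationCurve",
    "LinearEpsilonModel",
    "build_grid",
    "extract_boundary",
    "critical_ionic_strength",
    "hydrophobicity_shift",
    "aggregation_index",
]

DEFAULT_IONIC_STRENGTHS = (0.0, 30.0, 70.0, 170.0, 300.0, 500.0)  # mM
DEFAULT_METAL_EPSILON = 1.35  # kT, metal-metal LJ well depth
ZETA_BAND_MV = 30.0


@dataclass
class PhaseGrid:
    """Values of zeta (mV) or dimerization free energy (kT) on a rectangular
    (sigma, ionic strength) design."""

    sigma_axis: np.ndarray            # e nm^-2, increasing
    ionic_strength_axis: np.ndarray   # mM, increasing
    values: np.ndarray                # (n_sigma, n_I)
    quantity: str                     # "zeta" | "delta_g_dim"
    metal_epsilon: float = DEFAULT_METAL_EPSILON

    def __post_init__(self) -> None:
        self.sigma_axis = np.asarray(self.sigma_axis, float)
        self.ionic_strength_axis = np.asarray(self.ionic_strength_axis, float)
        self.values = np.asarray(self.values, float)
        if self.quantity not in ("zeta", "delta_g_dim"):
            raise ValueError("quantity must be 'zeta' or 'delta_g_dim'")
        if np.any(np.diff(self.sigma_axis) <= 0) or \
                np.any(np.diff(self.ionic_strength_axis) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.values.shape != (len(self.sigma_axis),
                                 len(self.ionic_strength_axis)):
            raise ValueError("values shape does not match the axes")


@dataclass
class PhaseBoundary:
    """Iso-contours of the stability criterion in the (sigma, I) plane.

    ``polylines`` maps each contour level to a list of (k, 2) arrays of
    (sigma, I) points. For the free-energy criterion the central -1.0 kT
    level is accompanied by the band edges at -0.5 and -1.5 kT; for the
    zeta criterion the levels are -30 and +30 mV.
    """

    criterion: str
    levels: tuple[float, ...]
    polylines: dict[float, list[np.ndarray]]
    band_half_width: float

    @property
    def is_empty(self) -> bool:
        return all(len(v) == 0 for v in self.polylines.values())


@dataclass
class AggregationCurve:
    ionic_strengths: np.ndarray   # mM
    index: np.ndarray             # Abs650 / Absmax
    critical_i: float | None      # mM; None when no aggregation step found


def build_grid(entries, quantity: str,
               metal_epsilon: float = DEFAULT_METAL_EPSILON) -> PhaseGrid:
    """Assemble (sigma, I, value) triples into a complete rectangular grid.

    Raises listing the missing cells if the design is incomplete, and on
    duplicate cells carrying conflicting values.
    """
    entries = [(float(s), float(i), float(v)) for s, i, v in entries]
    sigmas = np.unique([e[0] for e in entries])
    ions = np.unique([e[1] for e in entries])
    values = np.full((len(sigmas), len(ions)), np.nan)
    for s, i, v in entries:
        si = int(np.searchsorted(sigmas, s))
        ii = int(np.searchsorted(ions, i))
        if not np.isnan(values[si, ii]) and values[si, ii] != v:
            raise ValueError(f"conflicting values for (sigma={s}, I={i})")
        values[si, ii] = v
    if np.isnan(values).any():
        missing = [(float(sigmas[a]), float(ions[b]))
                   for a, b in zip(*np.nonzero(np.isnan(values)))]
        raise ValueError(f"incomplete design; missing cells: {missing}")
    return PhaseGrid(sigmas, ions, values, quantity, metal_epsilon)


def _contours_at(grid: PhaseGrid, level: float) -> list[np.ndarray]:
    """Marching-squares contours at ``level``, mapped from fractional index
    space to (sigma, I) coordinates by linear interpolation."""
    out = []
    idx_s = np.arange(len(grid.sigma_axis))
    idx_i = np.arange(len(grid.ionic_strength_axis))
    for contour in measure.find_contours(grid.values, level):
        sig = np.interp(contour[:, 0], idx_s, grid.sigma_axis)
        ion = np.interp(contour[:, 1], idx_i, grid.ionic_strength_axis)
        out.append(np.column_stack([sig, ion]))
    return out


def extract_boundary(grid: PhaseGrid, criterion: str | None = None) -> PhaseBoundary:
    """Stability boundary of the grid by marching squares with linear edge
    interpolation.

    criterion ``zeta_band_30mV`` contours at -30 and +30 mV; criterion
    ``dg_band_minus1kT`` contours the central -1.0 kT level together with
    the -0.5 and -1.5 kT band edges. Levels outside the data range yield an
    empty boundary with a notice.
    """
    if grid.values.shape[0] < 2 or grid.values.shape[1] < 2:
        raise ValueError("contouring needs >= 2 points per axis")
    if criterion is None:
        criterion = ("zeta_band_30mV" if grid.quantity == "zeta"
                     else "dg_band_minus1kT")
    if criterion == "zeta_band_30mV":
        levels = (-ZETA_BAND_MV, ZETA_BAND_MV)
        half_width = ZETA_BAND_MV
    elif criterion == "dg_band_minus1kT":
        levels = (BAND_CENTER_KT - BAND_HALF_WIDTH_KT, BAND_CENTER_KT,
                  BAND_CENTER_KT + BAND_HALF_WIDTH_KT)
        half_width = BAND_HALF_WIDTH_KT
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    lines: dict[float, list[np.ndarray]] = {}
    vmin, vmax = np.nanmin(grid.values), np.nanmax(grid.values)
    for level in levels:
        if not vmin <= level <= vmax:
            warnings.warn(f"level {level} outside data range "
                          f"[{vmin:.3g}, {vmax:.3g}]: empty contour",
                          stacklevel=2)
            lines[level] = []
        else:
            lines[level] = _contours_at(grid, level)
    return PhaseBoundary(criterion, levels, lines, half_width)


def critical_ionic_strength(ionic_strengths, values, level: float = -1.0):
    """Ionic strength at which ``values`` crosses ``level``, by linear
    interpolation in I.

    Returns a float for a single crossing, a list for multiple crossings,
    and None when the row never crosses the level.
    """
    i_ax = np.asarray(ionic_strengths, float)
    v = np.asarray(values, float)
    crossings = []
    for a in range(len(v) - 1):
        lo, hi = v[a], v[a + 1]
        if (lo - level) * (hi - level) < 0:
            t = (level - lo) / (hi - lo)
            crossings.append(float(i_ax[a] + t * (i_ax[a + 1] - i_ax[a])))
        elif lo == level:
            crossings.append(float(i_ax[a]))
    if v[-1] == level:
        crossings.append(float(i_ax[-1]))
    if not crossings:
        return None
    return crossings[0] if len(crossings) == 1 else crossings


@dataclass(frozen=True)
class LinearEpsilonModel:
    """OLS line through (epsilon, dG_dim) points; predicts the free-energy
    shift induced by changing the metal-metal LJ well depth."""

    slope: float       # kT per kT of epsilon
    intercept: float   # kT
    r_squared: float

    def predict(self, epsilon: float) -> float:
        return self.slope * epsilon + self.intercept

    def shift(self, epsilon: float,
              reference: float = DEFAULT_METAL_EPSILON) -> float:
        return self.predict(epsilon) - self.predict(reference)


def hydrophobicity_shift(points) -> LinearEpsilonModel:
    """Fit dG_dim = slope * epsilon + intercept by ordinary least squares.

    R^2 is reported as NaN when the response is constant (the line is
    flat and the ratio of explained variance is undefined).
    """
    eps = np.array([p[0] for p in points], float)
    dg = np.array([p[1] for p in points], float)
    if len(np.unique(eps)) < 2:
        raise ValueError("need >= 2 distinct epsilon values")
    slope, intercept = np.polyfit(eps, dg, 1)
    pred = slope * eps + intercept
    ss_tot = float(np.sum((dg - dg.mean()) ** 2))
    if ss_tot == 0:
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((dg - pred) ** 2)) / ss_tot
    return LinearEpsilonModel(float(slope), float(intercept), r2)


def _logistic(x, lo, hi, x0, width):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - x0) / width))


def aggregation_index(wavelengths, spectra: dict) -> AggregationCurve:
    """UV-vis aggregation index: Abs at 650 nm over the maximum absorbance,
    per ionic strength.

    ``spectra`` maps ionic strength (mM) to an absorbance array on the
    common ``wavelengths`` grid (nm). The critical ionic strength is the
    midpoint of the largest forward step of the index; with more than six
    salt points a logistic fit refines it (falling back to the step
    midpoint if the fit fails). None is returned when the index never
    rises appreciably.
    """
    wl = np.asarray(wavelengths, float)
    if not wl.min() <= 650.0 <= wl.max():
        raise ValueError("wavelength grid must cover 650 nm")
    i_ax = np.array(sorted(spectra), float)
    index = []
    for i in i_ax:
        spec = np.asarray(spectra[i], float)
        a650 = float(np.interp(650.0, wl, spec))
        amax = float(spec.max())
        index.append(a650 / amax if amax > 0 else 0.0)
    index = np.asarray(index)
    steps = np.diff(index)
    if len(steps) == 0 or steps.max() <= 1e-3:
        return AggregationCurve(i_ax, index, None)
    k = int(np.argmax(steps))
    critical = float(0.5 * (i_ax[k] + i_ax[k + 1]))
    if len(i_ax) > 6:
        from scipy.optimize import curve_fit
        try:
            p0 = [float(index.min()), float(index.max()), critical,
                  max((i_ax[-1] - i_ax[0]) / 20.0, 1.0)]
            popt, _ = curve_fit(_logistic, i_ax, index, p0=p0, maxfev=20000)
            if i_ax[0] <= popt[2] <= i_ax[-1]:
                critical = float(popt[2])
        except RuntimeError:
            pass
    return AggregationCurve(i_ax, index, critical)
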