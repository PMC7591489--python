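"""Shear-plane detection and zeta-potential estimation from radial profiles.

The shear plane is located where the counterion radial distribution starts
deviating from its screened (Debye-Hueckel) behaviour: a Yukawa-like curve
A exp(-B r)/r + C is fitted to the tail of the RDF beyond a set of candidate
inner radii, the first grid point (scanning from the outside in) whose
deviation from the fit reaches a threshold is recorded per fit, and the
median over candidates is the shear radius. The zeta potential is the
Gauss-law electrostatic potential of the spherically averaged charge
distribution evaluated at that radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import EPS_WATER, KE_MV_NM_E

__all__ = [
    "RadialProfile",
    "YukawaFit",
    "DeviationResult",
    "ShearPlaneResult",
    "ZetaResult",
    "fit_yukawa_tail",
    "detect_shear_plane",
    "shear_plane_ensemble",
    "zeta_potential",
    "classify_regime",
    "stability_by_zeta",
]

#: Regime boundaries in surface charge density, e nm^-2.
SIGMA_DEPOLARIZED_MAX = 0.6
SIGMA_HYPERPOLARIZED_MIN = 4.1

#: Colloidal-stability band on the zeta potential, mV (instability inside).
ZETA_STABILITY_BAND_MV = 30.0


@dataclass
class RadialProfile:
    """A radial profile (RDF or density) around the particle centre of mass."""

    r: np.ndarray        # nm, strictly increasing
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.values.shape:
            raise ValueError("r and values must be matching 1-d arrays")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")


@dataclass(frozen=True)
class YukawaFit:
    """Parameters of A exp(-B r)/r + C fitted to a profile tail."""

    A: float
    B: float
    C: float
    r_min_used: float
    rms_residual: float

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.A * np.exp(-self.B * r) / r + self.C


@dataclass(frozen=True)
class DeviationResult:
    """Radial position of the first threshold-sized deviation from a fit."""

    radius: float
    deviated: bool   # False -> no point deviated; radius is the fallback


@dataclass
class ShearPlaneResult:
    per_fit_positions: np.ndarray
    shear_radius: float
    threshold: float
    n_no_deviation: int

    @property
    def is_no_deviation(self) -> bool:
        """True when no candidate fit detected any deviation (pure
        Debye-Hueckel profile)."""
        return self.n_no_deviation == len(self.per_fit_positions)


@dataclass(frozen=True)
class ZetaResult:
    zeta_mv: float
    shear_radius: float
    rel_permittivity: float
    regime: str


def _yukawa(r, a, b, c):
    return a * np.exp(-b * r) / r + c


def fit_yukawa_tail(profile: RadialProfile, r_min: float) -> YukawaFit:
    """Least-squares fit of A exp(-B r)/r + C to the profile beyond r_min.

    Initial guesses come from the log-linearised tail; B is constrained
    non-negative.
    """
    mask = profile.r > r_min
    if mask.sum() < 5:
        raise ValueError(f"need >= 5 points beyond r_min={r_min}")
    r = profile.r[mask]
    y = profile.values[mask]
    c0 = float(y[-max(3, len(y) // 5):].mean())
    z = (y - c0) * r
    pos = z > 1e-12
    if pos.sum() >= 2:
        slope, logint = np.polyfit(r[pos], np.log(z[pos]), 1)
        b0, a0 = max(-slope, 1e-3), float(np.exp(logint))
    else:
        b0, a0 = 1.0, float(z[0]) if len(z) else 1.0
    try:
        popt, _ = curve_fit(_yukawa, r, y, p0=[a0, b0, c0],
                            bounds=([-np.inf, 0.0, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Yukawa tail fit failed beyond r_min={r_min}: {err}") from err
    resid = y - _yukawa(r, *popt)
    return YukawaFit(float(popt[0]), float(popt[1]), float(popt[2]),
                     float(r_min), float(np.sqrt(np.mean(resid**2))))


def detect_shear_plane(profile: RadialProfile, fit: YukawaFit,
                       threshold: float = 0.1,
                       fallback: float | None = None) -> DeviationResult:
    """Scan from the largest radius inward; return the first grid point whose
    absolute deviation from the fit reaches ``threshold``.

    Screened behaviour holds outside the shear plane and breaks inside it,
    so the outermost threshold crossing marks the boundary. If no point
    deviates, the profile is Debye-Hueckel-like throughout and the fallback
    radius (default: the innermost grid point) is returned flagged.
    """
    dev = np.abs(profile.values - fit(profile.r))
    hits = np.nonzero(dev >= threshold)[0]
    if hits.size:
        return DeviationResult(float(profile.r[hits[-1]]), True)
    fb = fallback if fallback is not None else float(profile.r[0])
    return DeviationResult(float(fb), False)


def _lower_median(values: np.ndarray) -> float:
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def shear_plane_ensemble(profile: RadialProfile, r_lo: float = 1.9,
                         r_hi: float = 3.0, n: int = 20,
                         threshold: float = 0.1,
                         fallback: float | None = None) -> ShearPlaneResult:
    """Repeat fit + deviation detection over ``n`` equidistant inner-radius
    candidates in [r_lo, r_hi]; the shear radius is the lower median of the
    detected positions."""
    if profile.r[0] > r_lo or profile.r[-1] < r_hi:
        raise ValueError("profile support must cover [r_lo, r_hi]")
    positions = []
    n_nodev = 0
    n_failed = 0
    for r_min in np.linspace(r_lo, r_hi, n):
        try:
            fit = fit_yukawa_tail(profile, r_min)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        det = detect_shear_plane(profile, fit, threshold, fallback)
        positions.append(det.radius)
        n_nodev += not det.deviated
    if n_failed > n // 2:
        raise RuntimeError(f"{n_failed}/{n} tail fits failed")
    pos = np.asarray(positions)
    return ShearPlaneResult(pos, _lower_median(pos), threshold, n_nodev)


def zeta_potential(charge_profile: RadialProfile, shear_radius: float,
                   rel_permittivity: float = EPS_WATER,
                   central_charge: float = 0.0,
                   tail_tolerance: float = 1e-3) -> float:
    """Electrostatic potential (mV) at ``shear_radius`` by Gauss' law.

    For a spherically symmetric charge density rho(r) (e nm^-3) plus a
    central charge Q0 (the particle beads, e):

        psi(r*) = k_e/eps_r [ (Q0 + Q_ions(<r*))/r* + int_{r*}^inf rho 4 pi r dr ]

    Integrals are trapezoidal on the supplied grid; the density is assumed
    zero beyond the last grid point (a warning fires if it has not decayed).
    """
    r = charge_profile.r
    rho = charge_profile.values
    rstar = float(shear_radius)
    if rstar < r[0] or rstar > r[-1]:
        raise ValueError("shear_radius outside the profile grid")
    if abs(rho[-1] * 4 * np.pi * r[-1]) > tail_tolerance:
        warnings.warn("charge profile not decayed at its last grid point; "
                      "tail truncated", stacklevel=2)
    # refine the grid so r* is a node
    if rstar not in r:
        rho_star = np.interp(rstar, r, rho)
        idx = np.searchsorted(r, rstar)
        r = np.insert(r, idx, rstar)
        rho = np.insert(rho, idx, rho_star)
    else:
        idx = int(np.nonzero(r == rstar)[0][0])
    inner = slice(0, idx + 1)
    outer = slice(idx, None)
    q_enc = central_charge + np.trapezoid(rho[inner] * 4 * np.pi * r[inner]**2,
                                          r[inner])
    tail = np.trapezoid(rho[outer] * 4 * np.pi * r[outer], r[outer])
    return float(KE_MV_NM_E / rel_permittivity * (q_enc / rstar + tail))


def classify_regime(sigma: float) -> str:
    """Electrostatic regime of a charged particle by surface charge density:
    depolarized below ~0.6 e nm^-2 (thermal motion beats attraction), mildly
    polarized up to ~4.1 (Stern-layer screening plateau), hyperpolarized
    above (counterion saturation). Boundary values fall in the middle
    regime."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma < SIGMA_DEPOLARIZED_MAX:
        return "depolarized"
    if sigma <= SIGMA_HYPERPOLARIZED_MIN:
        return "mildly_polarized"
    return "hyperpolarized"


def stability_by_zeta(zeta_mv: float) -> str:
    """Colloidal stability call from the zeta potential: |zeta| must exceed
    30 mV for stability; the closed band [-30, +30] mV is aggregation-prone."""
    if not np.isfinite(zeta_mv):
        raise ValueError("zeta must be finite")
    return "unstable" if abs(zeta_mv) <= ZETA_STABILITY_BAND_MV else "stable"
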