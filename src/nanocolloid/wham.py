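"""Umbrella-sampling analysis: WHAM reconstruction of the dimerization PMF.

The reaction coordinate CV1 is the minimum distance between the van der
Waals surfaces of two interacting nanoparticles. Harmonically restrained
windows along CV1 are unbiased with the weighted histogram analysis method
into a potential of mean force in kT units, referenced to zero over the
separated-state plateau. The dimerization free energy is the PMF minimum at
short range relative to that plateau; a band of -1.0 +/- 0.5 kT marks the
boundary between dispersed and aggregated states (at -1.0 kT the pair has a
1/e chance of escaping the well by thermal motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import T_DEFAULT, kt_kj_mol

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "DimerResult",
    "cv1",
    "window_ladder",
    "wham",
    "dimerization_free_energy",
    "escape_probability",
]

DEFAULT_FORCE_CONSTANT = 5000.0   # kJ mol^-1 nm^-2
DEFAULT_BIN_WIDTH = 0.02          # nm
REFERENCE_WINDOW = (2.5, 3.0)     # nm, separated-state plateau
CROSSOVER = 1.2                   # nm, fine/coarse ladder crossover
BAND_CENTER_KT = -1.0
BAND_HALF_WIDTH_KT = 0.5


@dataclass
class UmbrellaWindow:
    """One harmonically restrained window of CV1 samples."""

    center: float                      # nm
    samples: np.ndarray                # nm
    force_constant: float = DEFAULT_FORCE_CONSTANT  # kJ mol^-1 nm^-2
    equilibration_discard: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")
        if self.equilibration_discard >= len(self.samples):
            raise ValueError("discard leaves no samples")

    @property
    def production_samples(self) -> np.ndarray:
        return self.samples[self.equilibration_discard:]


@dataclass
class PMFProfile:
    """Potential of mean force on a CV1 grid, in kT units."""

    cv1_grid: np.ndarray       # nm, bin centres
    free_energy: np.ndarray    # kT; NaN on unsampled bins
    temperature: float = T_DEFAULT
    reference_window: tuple[float, float] = REFERENCE_WINDOW

    def __post_init__(self) -> None:
        self.cv1_grid = np.asarray(self.cv1_grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)

    def free_energy_kj_mol(self) -> np.ndarray:
        return self.free_energy * kt_kj_mol(self.temperature)


@dataclass(frozen=True)
class DimerResult:
    delta_g_dim: float        # kT
    minimum_location: float   # nm
    classification: str       # dispersed | boundary | aggregated


def cv1(com_distance: float, vdw_radius_1: float = 1.5,
        vdw_radius_2: float = 1.5) -> float:
    """Surface-to-surface separation of two spheres from their
    centre-of-mass distance; negative values indicate overlap."""
    if com_distance < 0:
        raise ValueError("com_distance must be >= 0")
    value = com_distance - vdw_radius_1 - vdw_radius_2
    if value < 0:
        warnings.warn(f"CV1 = {value:.3f} nm < 0: spheres overlap",
                      stacklevel=2)
    return value


def window_ladder(cv_max: float = 3.0, coarse_step: float = 0.1,
                  fine_step: float = 0.05,
                  crossover: float = CROSSOVER) -> np.ndarray:
    """Descending restraint centres: coarse spacing above the crossover,
    fine spacing at and below it, down to contact (0.0)."""
    if coarse_step <= 0 or fine_step <= 0:
        raise ValueError("steps must be > 0")
    if crossover > cv_max:
        raise ValueError("crossover must be <= cv_max")
    n_coarse = int(round((cv_max - crossover) / coarse_step))
    coarse = cv_max - coarse_step * np.arange(n_coarse)  # excludes crossover
    n_fine = int(round(crossover / fine_step)) + 1
    fine = crossover - fine_step * np.arange(n_fine)
    centers = np.concatenate([coarse, fine])
    return np.round(centers, 10)


def wham(windows: list[UmbrellaWindow], bin_width: float = DEFAULT_BIN_WIDTH,
         temperature: float = T_DEFAULT, tol: float = 1e-7,
         max_iter: int = 100000,
         reference_window: tuple[float, float] = REFERENCE_WINDOW,
         min_counts: int = 25) -> PMFProfile:
    """Self-consistent WHAM unbiasing of harmonic umbrella windows.

    Solves  P(x) ~ sum_i h_i(x) / sum_i N_i f_i exp(-beta w_i(x))  with
    w_i(x) = k/2 (x - c_i)^2, iterating the window free-energy shifts f_i
    until they change by less than ``tol`` (kT). The PMF is
    F(x) = -kT ln P(x), shifted so its mean over the occupied bins of the
    reference window is zero (falling back to the outermost 10% of the grid
    when the window is not covered).

    Bins with fewer than ``min_counts`` total samples (the far tails beyond
    the outermost restraint centres) are reported as NaN: their -ln counts
    estimate carries O(1/sqrt(counts)) kT noise and no restraint targets
    them. All bins with a single count still enter the self-consistency
    iteration.
    """
    if not windows:
        raise ValueError("no windows supplied")
    kt = kt_kj_mol(temperature)
    data = [w.production_samples for w in windows]
    lo = min(s.min() for s in data)
    hi = max(s.max() for s in data)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.linspace(lo, hi, 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.array([np.histogram(s, bins=edges)[0] for s in data])  # (W, M)
    counts = hists.sum(axis=0)

    # coverage check: adjacent windows (by centre) must share occupied bins
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            raise ValueError(
                "umbrella coverage gap between windows centred at "
                f"{windows[a].center:.3f} and {windows[b].center:.3f} nm")

    n_i = hists.sum(axis=1).astype(float)               # (W,)
    bias = np.array([0.5 * w.force_constant * (centers - w.center) ** 2
                     for w in windows]) / kt            # (W, M), in kT
    log_boltz = -bias
    log_n = np.log(n_i)[:, None]
    log_f = np.zeros(len(windows))                      # ln f_i
    occupied = counts > 0
    log_counts = np.where(occupied, np.log(np.maximum(counts, 1)), -np.inf)

    from scipy.special import logsumexp

    for _ in range(max_iter):
        # ln P_j  (unnormalised)
        log_denom = logsumexp(log_n + log_f[:, None] + log_boltz, axis=0)
        log_p = log_counts - log_denom
        # update: f_i^-1 = sum_j P_j exp(-beta w_ij)
        new_log_f = -logsumexp(log_p[None, :] + log_boltz, axis=1)
        delta = np.max(np.abs(new_log_f - log_f))
        log_f = new_log_f
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {delta:.2e} kT)")

    reported = counts >= min(min_counts, int(counts.max()))
    free = np.where(reported, -log_p, np.nan)
    ref_mask = reported & (centers >= reference_window[0]) \
        & (centers <= reference_window[1])
    if not np.any(ref_mask):
        warnings.warn("reference window not covered; referencing to the "
                      "outermost 10% of the sampled range", stacklevel=2)
        k = max(1, int(0.1 * reported.sum()))
        ref_idx = np.nonzero(reported)[0][-k:]
        ref_mask = np.zeros_like(reported)
        ref_mask[ref_idx] = True
    free = free - np.nanmean(free[ref_mask])
    return PMFProfile(centers, free, temperature, reference_window)


def dimerization_free_energy(pmf: PMFProfile, crossover: float = CROSSOVER,
                             plateau_std_warn: float = 0.3) -> DimerResult:
    """Dimerization free energy: PMF minimum below the crossover separation,
    relative to the plateau mean. Classification: dispersed above -0.5 kT,
    boundary in [-1.5, -0.5] kT, aggregated below -1.5 kT."""
    lo, hi = pmf.reference_window
    ref = pmf.free_energy[(pmf.cv1_grid >= lo) & (pmf.cv1_grid <= hi)]
    ref = ref[np.isfinite(ref)]
    ref_mean = float(ref.mean()) if ref.size else 0.0
    if ref.size and float(ref.std()) > plateau_std_warn:
        warnings.warn(f"plateau not flat (std {ref.std():.2f} kT)",
                      stacklevel=2)
    close = pmf.free_energy[pmf.cv1_grid < crossover]
    close = close[np.isfinite(close)]
    if close.size == 0:
        raise ValueError("PMF does not cover the short-range region")
    mask = (pmf.cv1_grid < crossover) & np.isfinite(pmf.free_energy)
    i_min = np.nonzero(mask)[0][np.argmin(pmf.free_energy[mask])]
    dg = float(pmf.free_energy[i_min] - ref_mean)
    lo_band = BAND_CENTER_KT - BAND_HALF_WIDTH_KT
    hi_band = BAND_CENTER_KT + BAND_HALF_WIDTH_KT
    if dg > hi_band:
        cls = "dispersed"
    elif dg >= lo_band:
        cls = "boundary"
    else:
        cls = "aggregated"
    return DimerResult(dg, float(pmf.cv1_grid[i_min]), cls)


def escape_probability(delta_g_dim: float) -> float:
    """Boltzmann weight exp(dG_dim) for escaping the dimer well relative to
    the separated plateau, clamped to [0, 1]. At the -1.0 kT stability band
    this is 1/e ~ 0.37."""
    return float(np.clip(np.exp(delta_g_dim), 0.0, 1.0))
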