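"""Seeded generators of synthetic inputs with the statistical structure the
analyses assume: linearized Debye-Hueckel ion clouds with optional Stern
layers, DLVO pair potentials, biased Boltzmann samples from analytic PMFs,
anisotropic counterion halos, and (sigma, I) free-energy surfaces.

Every generator returns the analytic ground truth alongside any stochastic
samples, so downstream tests can compare estimates against the exact curve
that produced the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (E_CHARGE_C, EPS0_SI, EPS_WATER, KB_SI, KE_KCAL_NM_E2,
                        KE_MV_NM_E, N_AVOGADRO, T_DEFAULT, kt_kcal_mol,
                        kt_kj_mol)
from .electrokinetics import RadialProfile
from .ions import Snapshot
from .phase import PhaseGrid
from .wham import PMFProfile, UmbrellaWindow, dimerization_free_energy

__all__ = [
    "DHCloudSpec",
    "DLVOParams",
    "debye_length",
    "dh_potential_mv",
    "dh_counterion_rdf",
    "dh_ion_charge_profile",
    "sample_dh_cloud",
    "dlvo_pmf",
    "sample_umbrella_windows",
    "sample_halo_frames",
    "synthetic_phase_surface",
]

#: Number density of a 1 mM solute, nm^-3.
MM_TO_NM3 = 1e-3 * N_AVOGADRO / 1e24


def debye_length(ionic_strength_mm: float, temperature: float = T_DEFAULT,
                 rel_permittivity: float = EPS_WATER) -> float:
    """Debye screening length kappa^-1 in nm for a 1:1 electrolyte.

    kappa^-1 = sqrt(eps0 eps_r kB T / (2 NA e^2 I)), I in molar units.
    Zero ionic strength returns the infinite-screening-length sentinel
    (numpy inf).
    """
    if ionic_strength_mm < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength_mm == 0:
        return float("inf")
    i_molar = ionic_strength_mm * 1e-3 * 1e3  # mol m^-3
    num = EPS0_SI * rel_permittivity * KB_SI * temperature
    den = 2.0 * N_AVOGADRO * E_CHARGE_C**2 * i_molar
    return float(np.sqrt(num / den) * 1e9)


@dataclass(frozen=True)
class DHCloudSpec:
    """Electrolyte cloud around a charged sphere in the linearized
    (Debye-Hueckel) regime, with an optional Gaussian Stern shell."""

    np_charge: float                 # e (typically negative)
    np_vdw_radius: float = 1.5       # nm
    ionic_strength: float = 70.0     # mM
    rel_permittivity: float = EPS_WATER
    temperature: float = T_DEFAULT
    stern_amplitude: float = 0.0     # peak excess g(r) of the Stern bump
    stern_center: float = 1.7        # nm
    stern_width: float = 0.05        # nm
    box_half_width: float = 6.0      # nm, outer sampling radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.box_half_width <= self.np_vdw_radius:
            raise ValueError("box must enclose the particle")

    @property
    def kappa(self) -> float:
        """Screening constant kappa in nm^-1 (0 at zero ionic strength)."""
        ld = debye_length(self.ionic_strength, self.temperature,
                          self.rel_permittivity)
        return 0.0 if np.isinf(ld) else 1.0 / ld

    @property
    def bulk_density(self) -> float:
        """Bulk number density of each ionic species, nm^-3."""
        return self.ionic_strength * MM_TO_NM3


def dh_potential_mv(r, spec: DHCloudSpec) -> np.ndarray:
    """Linearized Debye-Hueckel potential (mV) of the charged sphere:
    psi(r) = k_e Q exp(kappa (a - r)) / (eps_r r (1 + kappa a))."""
    r = np.asarray(r, dtype=float)
    a = spec.np_vdw_radius
    kap = spec.kappa
    pref = KE_MV_NM_E * spec.np_charge / (spec.rel_permittivity * (1 + kap * a))
    return pref * np.exp(kap * (a - r)) / r


def _kt_mev(temperature: float) -> float:
    """kT in meV, pairing with potentials in mV for unit ion charges."""
    return kt_kcal_mol(temperature) / 23.060548 * 1000.0


def dh_counterion_rdf(r, spec: DHCloudSpec, include_stern: bool = True,
                      linearize: bool = True) -> np.ndarray:
    """Analytic counterion RDF around the charged sphere, plus the optional
    Gaussian Stern bump.

    The default is the linearized Boltzmann excess
    g+(r) = 1 - e psi(r)/kT = 1 + A exp(-kappa r)/r, the regime in which
    the screened tail is exactly of the Yukawa form the shear-plane
    protocol fits; ``linearize=False`` gives the full exponential weight
    exp(-e psi/kT) instead (clipped at the particle surface)."""
    r = np.asarray(r, dtype=float)
    kt_mv = _kt_mev(spec.temperature)
    x = dh_potential_mv(r, spec) / kt_mv
    g = np.maximum(1.0 - x, 0.0) if linearize else np.exp(-x)
    if include_stern and spec.stern_amplitude:
        g = g + spec.stern_amplitude * np.exp(
            -0.5 * ((r - spec.stern_center) / spec.stern_width) ** 2)
    return np.where(r < spec.np_vdw_radius, 0.0, g)


def dh_ion_charge_profile(spec: DHCloudSpec, r_max: float | None = None,
                          n_points: int = 2000) -> RadialProfile:
    """Exact linearized ion charge density (e nm^-3) around the sphere:
    rho(r) = -Q kappa^2 exp(kappa (a - r)) / (4 pi r (1 + kappa a)).

    Integrating this density by Gauss' law reproduces the Yukawa potential;
    the particle's own charge is NOT included (pass it as the central
    charge to :func:`nanocolloid.electrokinetics.zeta_potential`).
    """
    a = spec.np_vdw_radius
    kap = spec.kappa
    if r_max is None:
        r_max = a + (12.0 / kap if kap > 0 else spec.box_half_width)
    r = np.linspace(a, r_max, n_points)
    if kap == 0:
        rho = np.zeros_like(r)
    else:
        rho = -spec.np_charge * kap**2 * np.exp(kap * (a - r)) / (
            4.0 * np.pi * r * (1.0 + kap * a))
    return RadialProfile(r, rho, species="ion_charge")


def _sample_radial(rng: np.random.Generator, n: int, r_lo: float,
                   r_hi: float, weight_fn) -> np.ndarray:
    """Rejection-sample radii in [r_lo, r_hi] from density ~ weight(r) r^2."""
    grid = np.linspace(r_lo, r_hi, 512)
    w = weight_fn(grid) * grid**2
    w_max = float(w.max()) * 1.05
    if w_max <= 0:
        return np.array([])
    out = np.empty(n)
    filled = 0
    attempts = 0
    while filled < n:
        m = max((n - filled) * 2, 64)
        r = rng.uniform(r_lo, r_hi, m)
        u = rng.uniform(0, w_max, m)
        keep = r[u < weight_fn(r) * r**2]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
        attempts += m
        if attempts > 100 * n + 10000 and filled == 0:
            raise RuntimeError("rejection sampling efficiency below 1%")
    return out


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_dh_cloud(spec: DHCloudSpec, n_frames: int = 1,
                    linearize: bool = True
                    ) -> tuple[list[Snapshot], RadialProfile]:
    """Draw ion positions from the Debye-Hueckel Boltzmann densities
    n+-(r) = n0 g+-(r) around the charged sphere (rejection sampling), plus
    the optional Gaussian Stern shell of counterions.

    ``linearize`` selects the linearized weights 1 -+ e psi/kT (clipped at
    zero) matching :func:`dh_counterion_rdf`; otherwise the exponential
    weights are used. Returns the frames and the exact analytic counterion
    RDF used, on the sampling radial support.
    """
    rng = np.random.default_rng(spec.seed)
    a, r_box = spec.np_vdw_radius, spec.box_half_width
    kt_mv = _kt_mev(spec.temperature)
    n0 = spec.bulk_density
    volume = 4.0 / 3.0 * np.pi * (r_box**3 - a**3)

    def g_plus(r):
        x = dh_potential_mv(r, spec) / kt_mv
        return np.maximum(1.0 - x, 0.0) if linearize else np.exp(-x)

    def g_minus(r):
        x = dh_potential_mv(r, spec) / kt_mv
        return np.maximum(1.0 + x, 0.0) if linearize else np.exp(x)

    grid = np.linspace(a, r_box, 1024)
    mean_gp = np.trapezoid(g_plus(grid) * grid**2, grid) * 4 * np.pi / volume
    mean_gm = np.trapezoid(g_minus(grid) * grid**2, grid) * 4 * np.pi / volume
    n_stern = 0
    if spec.stern_amplitude:
        stern_integral = np.trapezoid(
            spec.stern_amplitude * np.exp(
                -0.5 * ((grid - spec.stern_center) / spec.stern_width) ** 2)
            * 4 * np.pi * grid**2, grid)
        n_stern = n0 * stern_integral

    frames = []
    for f in range(n_frames):
        n_plus = rng.poisson(n0 * volume * mean_gp)
        n_minus = rng.poisson(n0 * volume * mean_gm)
        r_plus = _sample_radial(rng, n_plus, a, r_box, g_plus)
        r_minus = _sample_radial(rng, n_minus, a, r_box, g_minus)
        parts = [r_plus[:, None] * _random_directions(rng, n_plus),
                 r_minus[:, None] * _random_directions(rng, n_minus)]
        charges = [np.ones(n_plus), -np.ones(n_minus)]
        species = ["NA"] * n_plus + ["CL"] * n_minus
        if n_stern:
            ns = rng.poisson(n_stern)
            r_st = np.clip(rng.normal(spec.stern_center, spec.stern_width, ns),
                           a, r_box)
            parts.append(r_st[:, None] * _random_directions(rng, ns))
            charges.append(np.ones(ns))
            species += ["NA"] * ns
        frames.append(Snapshot(
            np_centers=np.zeros((1, 3)), np_vdw_radius=a,
            ion_positions=np.vstack(parts) if sum(map(len, parts)) else
            np.empty((0, 3)),
            ion_charges=np.concatenate(charges), ion_species=species,
            frame_id=f))
    r_profile = np.linspace(a, r_box, 512)
    profile = RadialProfile(r_profile,
                            dh_counterion_rdf(r_profile, spec,
                                              linearize=linearize),
                            species="NA")
    return frames, profile


@dataclass(frozen=True)
class DLVOParams:
    """Parameters of the DLVO pair potential between two identical spheres:
    screened-Coulomb (Yukawa) repulsion plus Hamaker van der Waals
    attraction."""

    hamaker: float = 10.0            # kT
    np_radius: float = 1.5           # nm
    np_charge: float = -40.0         # e
    rel_permittivity: float = EPS_WATER
    debye_length_nm: float = 1.0     # nm (inf -> unscreened)
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.hamaker <= 0:
            raise ValueError("hamaker must be > 0")
        if self.debye_length_nm <= 0:
            raise ValueError("debye_length must be > 0")


def _dlvo_electrostatic_kt(h: np.ndarray, p: DLVOParams) -> np.ndarray:
    """Yukawa sphere-sphere repulsion in kT. Charge-normalised convention:
    V(r) = k_e Q^2 / (eps r) * (exp(kappa a)/(1 + kappa a))^2 * exp(-kappa r)
    with r the centre-centre distance 2a + h."""
    a = p.np_radius
    r = 2 * a + h
    kap = 0.0 if np.isinf(p.debye_length_nm) else 1.0 / p.debye_length_nm
    ke_kt = KE_KCAL_NM_E2 / kt_kcal_mol(p.temperature)  # kT nm / e^2
    pref = ke_kt * p.np_charge**2 / p.rel_permittivity
    corr = (np.exp(kap * a) / (1.0 + kap * a)) ** 2
    return pref * corr * np.exp(-kap * r) / r


def _dlvo_vdw_kt(h: np.ndarray, p: DLVOParams) -> np.ndarray:
    """Hamaker sphere-sphere attraction in kT:
    -A/6 [2a^2/(h(h+4a)) + 2a^2/(h+2a)^2 + ln(h(h+4a)/(h+2a)^2)]."""
    a = p.np_radius
    t1 = 2 * a**2 / (h * (h + 4 * a))
    t2 = 2 * a**2 / (h + 2 * a) ** 2
    t3 = np.log(h * (h + 4 * a) / (h + 2 * a) ** 2)
    return -p.hamaker / 6.0 * (t1 + t2 + t3)


def dlvo_pmf(params: DLVOParams, cv1_grid: np.ndarray,
             reference_window: tuple[float, float] = (2.5, 3.0)) -> PMFProfile:
    """Analytic DLVO potential of mean force on the CV1 grid, kT units,
    referenced to zero at the largest separation."""
    h = np.asarray(cv1_grid, dtype=float)
    if np.any(h <= 0):
        raise ValueError("CV1 grid must be strictly positive")
    v = _dlvo_electrostatic_kt(h, params) + _dlvo_vdw_kt(h, params)
    v = v - v[np.argmax(h)]
    return PMFProfile(h, v, params.temperature, reference_window)


def _pmf_callable(pmf) -> callable:
    if callable(pmf):
        return pmf
    grid, fe = pmf.cv1_grid, pmf.free_energy

    def f(x):
        return np.interp(x, grid, fe, left=np.inf, right=fe[-1])
    return f


def sample_umbrella_windows(pmf, ladder: np.ndarray,
                            force_constant: float = 5000.0,
                            n_samples: int = 5000, seed: int = 0,
                            temperature: float = T_DEFAULT,
                            n_sweeps: int = 120,
                            equilibration_discard: int = 0
                            ) -> list[UmbrellaWindow]:
    """Metropolis samples from the biased density exp(-[F(x) + w_i(x)]/kT)
    for each restraint centre in ``ladder``.

    ``pmf`` is a PMFProfile or a callable F(x) in kT. Each window runs
    ``n_samples`` independent walkers for ``n_sweeps`` Metropolis sweeps,
    which after burn-in yields an i.i.d.-like draw from the biased
    Boltzmann density. Aggregate acceptance below 5% raises.
    """
    f = _pmf_callable(pmf)
    kt = kt_kj_mol(temperature)
    rng = np.random.default_rng(seed)
    restraint_width = np.sqrt(kt / force_constant)
    step = restraint_width  # proposal scale matched to the bias width
    windows = []
    for center in np.asarray(ladder, dtype=float):
        def log_target(x):
            return -(np.asarray(f(x), dtype=float)
                     + 0.5 * force_constant * (x - center) ** 2 / kt)
        # start from the biased-density mode (the centre may sit against, or
        # entirely outside, a hard wall of the PMF support)
        for span in (6, 30, 150):
            scan = center + np.linspace(-span, span, span * 40 + 1) \
                * restraint_width
            lp_scan = log_target(scan)
            if np.any(np.isfinite(lp_scan)):
                break
        else:
            raise ValueError(f"PMF not finite anywhere near centre {center}")
        x0 = scan[int(np.nanargmax(np.where(np.isfinite(lp_scan),
                                            lp_scan, -np.inf)))]
        x = x0 + rng.normal(0.0, restraint_width, n_samples)
        lp = log_target(x)
        bad = ~np.isfinite(lp)
        if bad.any():
            x[bad] = x0
            lp[bad] = log_target(np.full(bad.sum(), x0))
        accepted = 0
        w_step = step
        burn_in = n_sweeps // 2
        for sweep in range(n_sweeps):
            prop = x + rng.normal(0.0, w_step, n_samples)
            lp_prop = log_target(prop)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.uniform(size=n_samples)) < lp_prop - lp
            x = np.where(accept, prop, x)
            lp = np.where(accept, lp_prop, lp)
            if sweep < burn_in:
                # adapt during burn-in: steep PMF walls squeeze the biased
                # density far below the restraint width
                if accept.mean() < 0.2:
                    w_step *= 0.5
            else:
                accepted += int(accept.sum())
        rate = accepted / ((n_sweeps - burn_in) * n_samples)
        if rate < 0.05:
            raise RuntimeError(
                f"Metropolis acceptance {rate:.3f} < 5% at centre {center}; "
                "reduce the proposal step")
        windows.append(UmbrellaWindow(center=float(center), samples=x.copy(),
                                      force_constant=force_constant,
                                      equilibration_discard=equilibration_discard))
    return windows


def sample_halo_frames(n_frames: int = 50, baseline_density: float = 1.1,
                       peak_excess: float = 13.9, peak_angle_deg: float = 32.0,
                       concentration: float = 30.0, np_vdw_radius: float = 1.5,
                       cutoff: float = 2.0, com_distance: float = 4.0,
                       seed: int = 0) -> list[Snapshot]:
    """Frames of an anisotropic counterion halo around a nanoparticle dimer.

    Ion positions in the conic shell around the reference particle follow a
    Poisson process with angular intensity
    rho(theta) = baseline + peak_excess * exp(conc (cos(theta - theta0) - 1))
    (a von Mises bump at ``peak_angle_deg``), mimicking the counterion
    accumulation near the contact region of two approaching particles.
    """
    rng = np.random.default_rng(seed)
    r_in, r_out = np_vdw_radius, np_vdw_radius + cutoff
    volume = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
    theta0 = np.radians(peak_angle_deg)

    def intensity(theta):
        return baseline_density + peak_excess * np.exp(
            concentration * (np.cos(theta - theta0) - 1.0))

    rho_max = baseline_density + peak_excess
    centers = np.array([[0.0, 0.0, 0.0], [com_distance, 0.0, 0.0]])
    frames = []
    for fi in range(n_frames):
        n_prop = rng.poisson(rho_max * volume)
        u = rng.uniform(r_in**3, r_out**3, n_prop) ** (1.0 / 3.0)
        dirs = _random_directions(rng, n_prop)
        pos = u[:, None] * dirs
        theta = np.arccos(np.clip(pos[:, 0] / u, -1, 1))  # axis = +x
        keep = rng.uniform(0, rho_max, n_prop) < intensity(theta)
        pos = pos[keep]
        frames.append(Snapshot(np_centers=centers,
                               np_vdw_radius=np_vdw_radius,
                               ion_positions=pos,
                               ion_charges=np.ones(len(pos)),
                               ion_species=["NA"] * len(pos), frame_id=fi))
    return frames


def synthetic_phase_surface(sigma_axis=None, ionic_strength_axis=None,
                            template: DLVOParams | None = None,
                            charge_scale: float = 0.15,
                            h_min: float = 0.3, h_max: float = 3.0,
                            n_h: int = 400,
                            reference_radius: float = 1.30) -> PhaseGrid:
    """Deterministic DLVO-shaped dimerization free-energy surface over the
    (sigma, I) design.

    For each cell the particle charge is sigma * 4 pi R_c^2 scaled by
    ``charge_scale`` (an effective-charge fraction standing in for
    Stern-layer screening), the Debye length follows from I, and the cell
    value is the minimum of the DLVO PMF at short range relative to the
    separated plateau. ``h_min`` is a minimum-approach distance playing the
    role of a Stern/hydration layer that keeps the contact minimum finite.
    """
    if sigma_axis is None:
        sigma_axis = np.linspace(0.0, 5.0, 14)
    if ionic_strength_axis is None:
        ionic_strength_axis = np.array([0.0, 30.0, 70.0, 170.0, 300.0, 500.0])
    if template is None:
        template = DLVOParams()
    sigma_axis = np.asarray(sigma_axis, float)
    ionic_strength_axis = np.asarray(ionic_strength_axis, float)
    area = 4.0 * np.pi * reference_radius**2
    h = np.linspace(h_min, h_max, n_h)
    values = np.zeros((len(sigma_axis), len(ionic_strength_axis)))
    for si, sigma in enumerate(sigma_axis):
        for ii, i_mm in enumerate(ionic_strength_axis):
            ld = debye_length(i_mm, template.temperature,
                              template.rel_permittivity)
            p = DLVOParams(hamaker=template.hamaker,
                           np_radius=template.np_radius,
                           np_charge=-sigma * area * charge_scale,
                           rel_permittivity=template.rel_permittivity,
                           debye_length_nm=ld,
                           temperature=template.temperature)
            pmf = dlvo_pmf(p, h)
            with warnings.catch_warnings():
                # unscreened columns (I = 0) have a 1/r tail, not a flat
                # plateau; referencing to max separation is still exact here
                warnings.simplefilter("ignore", UserWarning)
                values[si, ii] = dimerization_free_energy(pmf).delta_g_dim
    return PhaseGrid(sigma_axis, ionic_strength_axis, values, "delta_g_dim")
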