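# Methods

This note records the models implemented in `nanocolloid`, the defaults
and their rationale, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Capping thermodynamics

The capping free energy of *N* ligands of charge q = −α e on a spherical
metallic core is

ΔG_cap(N) = N ΔG_desolv^lig + N (ΔE_bind − T ΔS_bind) + ΔE_lig/lig(N) + ΔG_polar(N).

The core's own desolvation energy and the apolar part of the re-solvation
energy cancel algebraically and are never evaluated. The two electrostatic
terms are pluggable callables with these defaults:

* **ΔE_lig/lig(N) = k_e q² N(N−1) / (2 R_c)** — the expectation of the
  pairwise vacuum Coulomb sum for N point charges placed uniformly at
  random on a sphere of radius R_c (the mean inverse separation of two
  independent uniform points on a sphere is exactly 1/R). For an
  *organised* (spread-out) layout this is an upper bound; the relative gap
  decays like N^(−1/2) (measured: 27% at N = 10, shrinking monotonically).
  Scales as N² for large N.
* **ΔG_polar(N) = −k_e (Nq)² (1 − 1/ε_w) / (2 R_s)** — Born transfer of
  the enveloping uniformly charged sphere of radius R_s from vacuum into a
  continuum of relative permittivity ε_w; non-positive and quadratic in N.

With both terms active, ΔG_cap is exactly quadratic in N with coefficient
k_e q² [1/(2R_c) − (1 − 1/ε_w)/(2R_s)]. Minimisation is an exhaustive
integer scan over [0, n_max] (default 200) with ties broken toward smaller
N; a *stable* capped state requires an interior minimiser with
ΔG_cap(N*) < 0 — a minimum at the scan edge or a non-negative minimum is
reported as "no stable minimum", the insoluble regime.

Constants and units: k_e = 33.206 kcal mol⁻¹ nm e⁻²; energies in
kcal mol⁻¹; T = 310 K; ε_w = 78.5; ΔS_bind defaults to 0 (ideal-gas
estimates make it negligible at these temperatures; the parameter is
retained).

### The citrate-on-gold preset

`citrate_preset(alpha)` carries the parameterization used throughout the
examples. Its geometry places **both** the charged ligand shell and the
Born sphere at the reference radius R_c = R_s = 1.30 nm (inside the 1.5 nm
van der Waals radius of the 3.0 nm particle: the ligand charges sit at the
binding distance, not at the outer envelope). With coincident radii the
vacuum repulsion and the polar gain nearly cancel, leaving the
water-screened shell energy k_e q² N²/(2Rε_w) − k_e q² N/(2R): the
physically sensible statement that ligand–ligand repulsion on a solvated
particle is dielectrically screened. The per-state desolvation energies

| α | ΔG_desolv^lig (kcal mol⁻¹) |
|---|------|
| 1 | 54.0 |
| 2 | 55.5 |
| 3 | 59.2 |

increase with ligand charge, and ΔE_bind = −40.9 kcal mol⁻¹ is the
quantum-chemical citrate–gold binding affinity with the sign of a bound
state. This parameter set yields N* = 28 at α = 2 (−56 e,
σ = 2.6 e nm⁻²), N* = 33 at α = 3 (−99 e, σ = 4.7 e nm⁻²), no stable
minimum at α = 1, and effective per-ligand affinities
(−ΔG_cap(N*)/N*) of 18.3 and 48.3 kcal mol⁻¹ — bracketing the DFT value
when interpolated in α. `CoreSpec` emits a warning (not an error) when
R_s < R_vdw, since the type-level default remains R_s = R_vdw.

Two area conventions coexist deliberately. σ and ligand density use
4πR_c² = 21.2 nm² (R_c = 1.30 nm), which reproduces the published
(charge, σ) pairs to one-decimal rounding. Surface *coverage* percentages
use a configurable reference area; 19.9 nm² reproduces the published
22.5–26.5% range for the 0.16 nm² modal ligand footprint. The two cannot
be forced to agree and are kept independent.

### Projected ligand area

The footprint of a flexible ligand is estimated by projecting the van der
Waals spheres of each conformer onto a plane for many uniform SO(3)
orientations (quaternion sampling, seeded), rasterising the union of disks
(default 0.02 nm grid), and taking the mode of a Gaussian kernel density
(Silverman bandwidth) over the area samples — the modal rather than mean
area, because the distribution is right-skewed by extended conformers.

## Bead-shell particle models

Particles are hollow shells of CG beads on stacked latitudinal rings. The
ring count is round(√(πn)/2)·2 (20 rings for the reference 126-bead
shell); beads per ring follow the ring circumference with largest-remainder
rounding, and alternate rings are staggered by half a spacing. Bead centres
sit at (vdW diameter)/2 − 0.264 nm so the assembly's van der Waals surface
matches the requested 3.0 nm. The elastic network bonds every bead to its
six nearest neighbours and its single global farthest partner (the
antipode-like bead that braces the shell), rest lengths taken from the
built geometry, k = 15000 kJ mol⁻¹ nm⁻²; duplicates are merged. Surface
charges are assigned by drawing beads uniformly at random (seeded) at
−2 e each until the target net charge is met; targets must therefore be
even. The ring axis is a construction artefact — downstream analyses are
rotation-invariant, which the tests assert on rotated copies.

## Shear plane and ζ-potential

The protocol assumes Debye–Hückel behaviour *outside* the shear plane:
A e^(−Br)/r + C is fitted (nonlinear least squares, log-linearised initial
guesses, B ≥ 0) to the counterion RDF beyond each of 20 equidistant inner
radii in [1.9, 3.0] nm; scanning from the outermost grid point inward, the
first point whose absolute deviation from the fit reaches 0.1 (RDF units)
is recorded, and the lower median over the 20 candidates is the shear
radius. Profiles that never deviate (pure screened clouds) return an
explicit no-deviation sentinel rather than a fabricated radius. The
deviation threshold is applied to the same quantity that was fitted.

ζ is computed by Gauss' law for a spherically averaged charge density
ρ(r) (e nm⁻³) plus the particle's own (central) charge:

ψ(r*) = k_e/ε_r [ (Q₀ + Q_ions(<r*))/r* + ∫_{r*}^∞ ρ(r) 4πr dr ],

trapezoidal on the supplied grid, tail beyond the last point assumed zero
with a truncation warning. k_e = 1439.96 mV nm e⁻¹; the relative
permittivity is an explicit argument (default 78.5) because reported mV
values scale with it. Against the linearized Debye–Hückel cloud the
integral reproduces the Yukawa closed form
ψ(r) = k_e Q e^(κ(a−r))/(ε_r r(1+κa)) to <0.1%.

Regime thresholds: σ < 0.6 e nm⁻² depolarized, 0.6–4.1 mildly polarized
(Stern-layer screening plateau), >4.1 hyperpolarized; boundaries belong to
the middle regime. |ζ| ≤ 30 mV (closed band) is aggregation-prone.

## Umbrella sampling and WHAM

CV1 = centre distance − both vdW radii. The production ladder descends
from 3.0 nm in 0.1 nm steps to the 1.2 nm crossover and in 0.05 nm steps
to contact (43 centres); k = 5000 kJ mol⁻¹ nm⁻². WHAM iterates the
standard self-consistency equations in log space (logsumexp) until the
window shifts move by <10⁻⁷ kT; bin width defaults to 0.02 nm. The PMF is
reported in kT (T = 310 K) and referenced to zero mean over the
[2.5, 3.0] nm plateau. Bins with fewer than 25 total samples — the far
tails beyond the outermost restraint centres, whose −ln(counts) estimate
carries O(counts^(−1/2)) kT noise — are reported as NaN while still
entering the iteration. Adjacent windows must share at least one occupied
bin or the reconstruction aborts naming the gap.

ΔG_dim is the PMF minimum below the crossover relative to the plateau;
classification: dispersed above −0.5 kT, boundary within −1.0 ± 0.5 kT,
aggregated below −1.5 kT. The escape probability e^(ΔG_dim) (clamped to
[0, 1]) is 1/e at the band centre. A plateau standard deviation above
0.3 kT triggers a flatness warning.

## Ion structure

Angular densities use the polar angle between the inter-particle axis and
the ion position vector from the reference particle centre, counted in
4° bins over the conic shell between the vdW surface and 2.0 nm beyond
it; bin volumes are analytic, (2π/3)(cos θ₁ − cos θ₂)(r₂³ − r₁³), and
error bars are standard deviations over frames. Transversal charge maps
bin all charges (beads and ions) within a 0.2 nm slab perpendicular to the
axis at one of four planes (particle centre, half radius, vdW surface,
dimer midplane) on a 0.1 nm grid. Residence times are maximal run lengths
of the surface-distance series below a cutoff; the first and last runs of
a finite series are censored and should be dropped for unbiased means.

## Phase diagrams

Grids are strict rectangular designs (missing cells are an error listing
them). Boundaries come from marching squares with linear edge
interpolation on the bilinear surface; the free-energy criterion reports
the −1.0 kT centre with the −0.5 and −1.5 kT band edges as separate
polylines, the ζ criterion the ±30 mV pair. Critical ionic strengths are
linear interpolations of a grid row at the −1.0 kT level; multiple
crossings are all returned. The hydrophobicity model is an ordinary
least-squares line ΔG_dim(ε), with shift(ε) = prediction(ε) −
prediction(1.35 kT); R² is NaN for a constant response. The UV-vis
aggregation index is Abs(650 nm)/max Abs per salt concentration; the
critical concentration is the midpoint of the largest forward step,
refined by a logistic fit when more than six concentrations are available.

## Synthetic data: what it does and does not emulate

All generators are seeded and return the analytic ground truth alongside
the samples, so tests compare estimates against the exact generating
curve, never against another estimate.

* **Debye–Hückel clouds** draw ion positions by rejection sampling from
  the *linearized* Boltzmann densities n±(r) = n₀(1 ∓ eψ_DH/kT, clipped
  at 0) around the charged sphere, with an optional Gaussian Stern shell
  of counterions. Linearization is the default because the shear-plane
  protocol's Yukawa fit is exact in that regime; the full exponential
  weight is available (`linearize=False`) but produces RDFs that no
  Yukawa curve fits when e|ψ| ≫ kT. The generator does not emulate ion–ion
  correlations, finite ion size, or polarizable water — passing tests
  validate the *protocol*, not the CG force field.
* **DLVO surfaces** combine the screened-Coulomb sphere–sphere repulsion
  k_e Q² e^(−κr) (e^(κa)/(1+κa))²/(ε_r r) with the Hamaker sphere–sphere
  attraction (A_H = 10 kT default). The (σ, I) phase-surface generator
  evaluates ΔG_dim on h ∈ [0.3, 3.0] nm — a Stern/hydration minimum-approach
  distance that keeps the contact minimum finite — and scales the bare
  charge by an effective-charge fraction 0.15 standing in for Stern-layer
  screening. These two numbers shape the synthetic surface only; they are
  not fitted to any published map, and the package makes no claim that the
  synthetic surface reproduces published absolute free energies — only its
  monotonicities (more charge → shallower well, more salt → deeper well)
  and its topology (a single stability boundary) are asserted.
* **Umbrella windows** are sampled by vectorised Metropolis chains (one
  independent walker per requested sample, 120 sweeps, proposal scale
  matched to the restraint width and halved during burn-in while
  acceptance is below 20%); production acceptance under 5% aborts.
  Initialisation scans for the biased-density mode so restraint centres
  pressed against a hard support wall remain usable.
* **Counterion halos** are Poisson point processes in the conic shell with
  a von Mises angular intensity peaked at 32°, emulating the accumulation
  of counterions near a dimer's contact region.

## Problem sizes

The default test and reproduction runs use 43 umbrella windows with
5×10⁴ samples each for production-depth WHAM checks (about half a minute
per profile), 3–5×10³ samples per window for quick round trips, 40–60
frame ensembles for ion-structure statistics, and 14 × 6 (σ, I) designs
for phase surfaces — sizes at which every stochastic check holds with
comfortable margin under a fixed seed.

## Known limitations

* The capping model is mean-field: no discrete adlayer packing, no
  pH→α speciation (α is an input), no curvature correction to ΔE_bind.
* The ζ chain assumes spherical symmetry; anisotropic double layers
  (dimer geometries) are handled only by the ion-structure analyses.
* WHAM error bars are not implemented (no autocorrelation analysis);
  window samples are assumed decorrelated.
* The DLVO generator's effective-charge scaling is a stand-in for the
  Stern screening physics, adequate for monotonicity and topology tests
  but not for absolute free energies.
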