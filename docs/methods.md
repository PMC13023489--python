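# Methods

## Scope and model

`dcbsim` models paclitaxel transport during and after drug-coated balloon
(DCB) angioplasty as transient diffusion of a scalar concentration
φ (kg/m³) on an axisymmetric (r, z) domain:

    ∂φ/∂t − ∇·(D(x) ∇φ) = 0

Convection and cellular uptake are deliberately zero: the dilation is too
short for luminal flow to matter inside the wall, and binding kinetics are
outside scope. The structural mechanics of dilation are not simulated;
instead the *post-dilation* configuration is built parametrically, with the
balloon shell in perfect contact with the innermost tissue surface.

### Geometry

An idealised straight vessel of length L with lumen radius R, wall
thickness W, and (for stenotic presets) a concentric annular plaque whose
thickness follows a cosine taper from `s·R` at the throat (stenosis rate
`s`, diameter-reduction convention) to zero at the shoulders — smooth
shoulders avoid flux singularities at the plaque ends. The balloon is a
0.10 mm shell (the one printed device dimension) conforming to the contact
surface.

Defaults are documented *fixtures*, not published values (the bench
geometry behind the calibration data is not printed anywhere): R = 1.5 mm,
W = 1.0 mm, L = 20 mm, plaque half-length 5 mm, balloon length 15 mm. All
are overridable (`VesselDims`), and presets `exvivo`/`s10`/`s30`/`s50`
carry stenosis rates 0/0.10/0.30/0.50.

### Discretisation

Cell-centred finite volumes on a global rectilinear (r, z) grid; cells are
labelled balloon/plaque/wall/void by their centres (staircase
representation of the curved interfaces). The radial grid is anchored at
multiples of the spacing so grid-aligned interfaces (lumen, outer wall)
mesh exactly; cell volumes are the exact annular volumes `2π·r̄·Δr·Δz`, so
summed wall volume telescopes to the closed form and region volumes change
< 0.5 % under 2× refinement on every preset.

Face transmissibility is `A·D_f/d` with the harmonic mean of region
diffusivities on unlike-region faces (optional per-interface override).
Time stepping is backward Euler with a cached sparse LU factorisation per
step size; the system matrix is an M-matrix, so the step is
unconditionally stable and positivity-preserving, and zero-flux closure
makes it conservative to direct-solver round-off (~1e-14 relative per
step). Verified against a dense matrix-exponential solution of the same
semi-discrete system (≤ 0.1 % after 10 steps) and against the classical
erfc solution of the two-slab contact problem (≤ 2 % near the interface at
refined resolution).

Default steps: 1 s during transfer (a 60–120 s process), 600 s during
retention (an 8-week process); both configurable, and results are stable
over six orders of magnitude in dt.

### Transfer stage and the meaning of Γ

During inflation a single effective coefficient Γ (the balloon-to-vessel
*transfer coefficient*) governs the coating, the tissue and the contact
interface: the inflation-phase equation carries one diffusivity, and the
calibrated quantity is precisely this joint coefficient. (An alternative
reading — Γ only on the contact faces with the free-tissue D inside the
wall — was evaluated; it uniformly lowers uptake and fits the measured
percentages strictly worse, and it makes Γ a pure face property with no
continuum meaning.)

Calibration minimises the **total error** Σₖ 100·|simₖ−expₖ|/expₖ against
the measured uptake pair (8.17 % @ 60 s, 14.63 % @ 120 s), accepting below
5 %. Because uptake is strictly increasing in Γ, each timepoint has at most
one matching Γ; the search brackets those roots (Brent), compares total
error across them, and polishes with a bounded scalar minimisation. When no
measurement is reachable inside the bracket the caller chooses: raise with
the achievable ranges, clip to the boundary, or widen the bracket
decade-by-decade (`on_unreachable`), the last mirroring the practice of
trying successively larger coefficient series until the acceptance rule can
be evaluated.

Two facts discovered during development deserve emphasis:

* **The measured 60→120 s uptake ratio (1.79) exceeds the √2 bound** that
  any resolved pure-diffusion model yields at early times (uptake ∝ √t).
  At fine resolution the best achievable total error is therefore ~15–21 %,
  for any Γ and any fixture of this class.
* **On the coarse 0.05 mm desk mesh the discrete interface resistance makes
  uptake nearly linear in t**, which happens to match the measured ratio;
  calibration then achieves a total error of ~3 % at Γ* ≈ 7.8e-12 m²/s.
  The calibrated Γ* is thus an *effective, mesh-resolution-tied* parameter
  (as any transfer coefficient fitted through a numerical model is); it
  compensates for both the unprinted bench geometry and the chosen
  resolution, and should only be used with the mesh spacing it was fitted
  at. The reference value 1.28e-12 m²/s remains the default
  `TransportParams.gamma_transfer`.

### Retention stage: prescribed washout

After withdrawal the balloon region is dropped and D = 1e-12 m²/s applies
throughout plaque and wall. Luminal washout is prescribed, not
mechanistic: daily endpoints M(24 h) = 0.30·M(0) and
M(d+1) = 0.70·M(d), with exponential interpolation inside each day
(continuous, monotone; the daily endpoints are what the data support —
"mass at the previous day's end" is the adopted reading).

A controller removes exactly the scheduled step loss after each diffusion
step. **Feasibility forces a depth-ordered design**: a sink acting only on
the first tissue cell layer (or any fixed shallow zone) cannot sustain
30 %/day once drug has penetrated beyond ≈ √(D/λ) ≈ 0.5 mm — diffusion
cannot resupply the surface fast enough, independent of the time step (dt
halving to 0.07 s was tried) and largely of the mesh. The controller
therefore takes each step's loss from the tissue *nearest* the former
plaque–balloon contact surface, proportional to local concentration within
the marginal shell, consuming deeper shells only as needed: the closest
feasible realisation of surface-localised washout. All loss is seeded at
the plaque–balloon surface (on the plain tube, the vessel–balloon surface);
the outer wall and axial ends are zero-flux.

Consequences worth knowing:

* the ledger tracks the schedule to machine precision (the t5/t6 checks are
  exact by construction *and* verified independently from the per-step
  ledger, whose closure — removed + remaining = initial — holds to ~1e-15);
* the spatial coefficient of variation falls steeply while the initial
  surface-concentrated dose redistributes (days 0–2) and then plateaus:
  the removal front keeps the near-lumen tissue depleted, so CV does **not**
  decrease monotonically through week 1, although it ends the week far
  below its starting value. A strictly monotone CV is incompatible with
  exact schedule tracking for every surface-biased removal we tried
  (single-layer, k-layer, exponential-kernel weighting with 0.1–1 mm decay
  lengths).

### Dosimetry

φ converts to tissue mass concentration as c[μg/g] = φ·10⁶/ρ with
ρ = 1000 kg/m³ (soft-tissue convention, configurable). Safety: spatial
*maximum* at the 24 h checkpoint strictly below 85.40 μg/g (conservative
choice; the mean is also reported). Efficacy: last checkpoint whose spatial
*mean* is ≥ 0.047 μg/g, as weeks within the 8-week horizon. Optimal
dilation time: among safe candidates, maximise effective duration, ties to
the shortest time (least barotrauma). With the conservative maximum
criterion the coarse fixtures flag longer dilations as unsafe at 24 h;
a 20 s dilation on the 10 % fixture is safe (peak ≈ 62 μg/g) and its mean
concentration falls below 10 μg/g within a week, consistent with published
low-dose comparisons.

## Synthetic data

`make_fixture` provides the four geometry presets; `gen_measurements` runs
the forward transfer model at a known Γ and applies unit-mean lognormal
noise with configurable CV (default 0.02 — a tight bench assay; percentages
are positive and errors plausibly proportional) and a fixed seed.
Generated measurements inherit the forward model's monotonicity in time.
What passing recovery tests show: the calibration inverts the *forward
model* uniquely and stably (noiseless recovery to <0.1 %, 2 %-noise
recovery within 10 % in ≥9/10 seeds). What they do not show: anything about
assay chemistry, coating mechanics, or geometric mismatch between fixture
and bench — those enter only through the effective Γ.

## Problem sizes and runtimes

Default desk-scale meshes use 0.05 mm spacing (8.8k–15k cells per fixture;
the balloon shell keeps ≥ 2 cells across). A full calibration is ~40
forward runs (~10 s total); an 8-week retention run is 8064 implicit steps
(~15 s). The analytic-oracle and convergence tests run on 1-D slab meshes
at 1–2.5 μm spacing where the diffusion boundary layer is resolved.

## Known limitations

* No convection, binding, metabolism, or vessel recoil; homogeneous
  isotropic tissue.
* Concentric plaque only; fixture dimensions stand in for unpublished bench
  geometry, so absolute uptake percentages carry that uncertainty.
* The calibrated Γ* is tied to the mesh spacing used to fit it.
* The washout schedule is extrapolated far beyond its empirical support
  after ~1 week (30 %/day forever implies sub-nanogram masses by week 8).
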