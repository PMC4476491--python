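# Methods

## Scope and coordinate conventions

`hemotrace` reconstructs the point of origin (PO) and region of origin (RO)
of a blood impact spatter pattern on a single **vertical** wall. Interfaces
use forensic reporting units — stain positions in cm, ellipse axes in mm,
volumes in µl, angles in degrees — and everything internal is SI, converted
only at the I/O boundary.

A wall frame is a point on the wall plane, an inward unit normal `n`, a
vertical in-plane unit vector `u`, and the lateral axis `s = u × n`
(right-handed; `s` is the right-hand direction of an observer inside the
room facing the wall). The directional angle γ is measured **clockwise from
the upward vertical** as seen by that observer; published BPA software
varies on this, so the sign convention is configurable
(`gamma_clockwise`). The in-plane travel direction is
`d = cos γ·u + sin γ·s`, the impact velocity direction
`v̂ = cos α·d − sin α·n`, and the backward launch ray is `−v̂`.

## Stain → droplet inversion

* **Impact angle**: `α = arcsin(W_max/L_max)`. Widths exceeding lengths are
  rejected as mismeasured ellipses.
* **Drying ratio**: the theoretical water-budget model
  `κ(Hct) = Hct(1 − w_r) + (1 − Hct)(1 − w_p)` with plasma water fraction
  `w_p = 0.91` and red-cell water fraction `w_r = 0.70` (slope 0.21,
  intercept 0.09; κ(0.44) = 18.24 %). Measured dried volumes depend on the
  scanning device, so a `calibrated-linear` mode takes fitted
  (slope, intercept) coefficients plus a scalar device factor `c_dev`
  (default 1.0, multiplicative on the measured dried volume). The shipped
  `NFI_AREASCAN3D` preset scales the theoretical line to pass through the
  one published anchor point for that scanner, κ(0.44) = 15.6 %; the actual
  calibration line of that device is not public, so the preset is a declared
  stand-in, not a measured fit. Calibration slopes from volume-pair tables
  are fitted through the origin (a zero-volume droplet leaves zero residue).
* **Diameter**: `D₀ = (6V₀/π)^(1/3)`; 1 µl = 1 mm³.
* **Impact speed**: the spreading interpolation
  `ξ(v) = Re^{1/5}√P/(A+√P)` with `P = We·Re^{−2/5}`, `A = 1.24`, is
  inverted with `W_max = ξ(v)·D₀` by Brent root-finding over
  v ∈ [0.01, 100] m/s (relative tolerance 1e-9). ξ is strictly increasing in
  v, so the root is unique; widths outside the attainable range raise a
  no-solution error that marks the stain unusable for velocity inference.
  The stain dimension fed to the law is the ellipse **width** — the
  cross-travel extent, least distorted by obliquity — with no further
  obliquity correction.

Blood property defaults (ρ = 1060 kg/m³, η = 4.8 mPa·s, σ = 0.060 N/m,
Hct = 0.44) are literature values for whole blood; blood is shear-thinning
and lab values vary, so all are configurable in the `[blood]` TOML section.

## Flight model

The equation of motion is

    a = −g ẑ − (3/4)(ρ_air/ρ_blood)(C_D(Re_rel)/D)|v_rel| v_rel,

with `v_rel = v − wind`. The drag coefficient is Schiller–Naumann,
`C_D = (24/Re)(1 + 0.15 Re^0.687)`, valid through the droplet Reynolds range
(~1–10³); above Re = 1000 it is held at its Re = 1000 value for continuity.
The Stokes limit enters only through the finite product `C_D·Re → 24`, so
the right-hand side is regular at `v_rel = 0`. Neglected: buoyancy
(ρ_air/ρ_blood ≈ 0.1 %), added mass, droplet deformation and in-flight
evaporation — all second-order for sub-centimetre drops over ≤ 3 m.

Integration is classical fixed-step RK4, default `dt = 1e-4 s`,
deterministic across platforms (no adaptive-step branching). Backward
reconstruction steps the *same* ODE with negative dt, which makes
forward/backward integration mutually inverse to integrator tolerance and
correctly inflates the speed along the backward path (drag decelerated the
forward flight). Backward paths stop when their depth from the wall exceeds
`max_depth_m` (default 3 m) or the height leaves [0, `z_max_m`]; z = 0 is
the floor and paths are clipped, not reflected. RK4 integrates the
straight-line (zero force) and pure-gravity (constant force) models to
round-off, so all three models share one integrator.

## Origin estimation

The PO is the minimizer of Σᵢ dᵢ(p)², where dᵢ is the shortest distance from
p to trajectory i (a sum of absolute distances is available behind
`loss="sum_abs"`). Straight trajectories use the exact point-to-line
distance, and for straight bundles with the squared loss the normal
equations solve the problem exactly, so the closed-form solution is returned
directly. Curved bundles start from that straight-line solution and refine
with Nelder–Mead to 0.01 cm; distances to sampled paths are minima over the
polyline segments (one sample per integration step ⇒ sub-millimetre segment
length, far below measurement error). Near-parallel bundles are detected by
the condition number of the straight-line normal matrix (> 1e8) and rejected
rather than silently solved.

The per-stain distance is a 3D radial scalar; the SD over stains uses the
sample (n−1) denominator, and `RO radius = 2·SD` exactly. Note that adding a
trajectory passing exactly through the PO can *increase* this RO radius (a
zero joins a set of roughly equal distances and widens their sample spread);
that is a property of the SD-based definition, not a solver artifact.

Accuracy statistics over repeated patterns with known truth: per-axis mean
deviation of the PO (signed), its per-axis variance, the mean per-pattern SD
⟨SD⟩, and a 95 %-level maximum deviation `|Δ̄| + 2⟨SD⟩` per axis.

Downward-directed stains (γ more than 90° from vertical) are excluded by
default before estimation — their height back-projection is very
inaccurate — and the γ window is configurable to study including them.

## Synthetic patterns

The forward simulator emulates the reference measurement geometry: a point
source at (100, 150, 63.7) cm, one metre from a vertical wall. Defaults that
the reference experiment does not pin down were chosen once as plausible
impact-spatter values and are fully configurable: droplet diameters
log-normal with median 1 mm and geometric SD 1.3; launch speeds uniform on
2–8 m/s; azimuths within ±30° of the wall normal; elevations 10–60° above
horizontal. 250 droplets are launched per pattern so that, after the
upward-γ selection filter, roughly 18–36 analyst-grade stains remain —
matching the ~30 stains per pattern an expert selects in practice. Droplets
that hit the floor first, time out, or graze the wall parallel to its plane
are dropped and counted.

Each wall crossing is bisected onto the wall plane, and the stain
observables are produced by the *same* physics the inverse pipeline inverts
(`W = D₀·ξ(v_imp)`, `L = W/sin α`, `V_dry = κ·V₀`), giving exact round-trip
identities in the noise-free case. Optional features emulate real-data
effects: an isotropic launch-position jitter (the breakup region of a real
impact is not a point; default 0) and multiplicative Gaussian measurement
noise on W, L and V_dry (default off). One RNG stream per pattern, seeded
explicitly, makes every pattern independently bit-reproducible.

What passing the synthetic checks does **not** show: the simulator shares
its spreading law, drying model and drag correlation with the inverse
pipeline, so recovery tests validate the inversion machinery and the
trajectory physics, not those empirical relations themselves; real stains
add ellipse-fitting error, surface wetting variability, non-point breakup
and hematocrit uncertainty that the noise-free defaults do not contain.

## Numerical and test-scale choices

The ensemble checks use 8 simulated patterns of 250 droplets analysed with
all three models — the same pattern count as the reference experiment —
which keeps the whole suite under ~2 minutes on one core while giving ≥ 18
trajectories per estimate. The crosswind drift experiment releases a droplet
from rest at 1.4 m in a 0.5 m/s uniform wind and integrates to touchdown
(interpolated through the floor crossing); 5 mm droplets drift ≈ 1 cm while
0.1 mm droplets drift ≈ 2.7 m, reproducing the known size sensitivity.

Known limitations: single planar vertical target; uniform (not turbulent or
spatially varying) wind; no outlier rejection (stain selection is the
analyst's input); no sheet/ligament breakup physics; no probabilistic origin
region — the RO is a descriptive 2·SD sphere, not a posterior.
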