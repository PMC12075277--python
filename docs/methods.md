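# Methods

## Forward model

A biphasic cartilage layer indented by a rigid sphere (radius R) under a
step creep load F is modelled with drained Poisson's ratio ν = 0, the
contract of the curve-fit: at ν = 0 the equilibrium contact modulus E
equals the aggregate modulus, and the consolidation diffusivity is
D = E·k with k the hydraulic permeability (m⁴/(N·s)).

* Equilibrium: semi-infinite Hertz, δ_eq = (3F/(4E√R))^(2/3),
  a_eq = √(R·δ_eq).
* Instantaneous response: the undrained solid is incompressible
  (effective ν = 1/2 at fixed shear modulus), doubling the effective
  contact modulus, hence δ₀/δ_eq = 2^(−2/3). This is a model consequence,
  not a tunable.
* Transient: δ(t) = δ_eq − (δ_eq − δ₀)·g(τ) with τ = E·k·t/a_eq² and the
  two-exponential spherical poroelastic master function
  g(τ) = 1.304·e^(−√τ) − 0.304·e^(−0.254τ), which satisfies g(0) = 1
  exactly and g → 0 monotonically. The master curve is a plain function
  and acts as a swappable strategy should a different transient be
  preferred.
* Load application is idealized as a perfect step at t = 0; deformation
  is referenced to the preload-equilibrium state. The 100 µN preload is
  2 % of the creep load and its own Hertzian deformation (< 8 % of δ_eq)
  is not modelled.
* Finite thickness: disabled by default (semi-infinite contact).
  An optional bonded-layer stiffening polynomial
  χ(a/h) = 1 + 1.133(a/h) + 1.283(a/h)² + 0.769(a/h)³ + 0.0975(a/h)⁴
  can be applied to the Hertz force, in which case δ_eq solves the
  corrected force balance by bracketing. Thickness is always used for the
  thin-layer validity flag regardless of this switch.

Units: computation in SI; interfaces in bench units (µN, µm, mm, s, MPa),
permeability in m⁴/(N·s). Converters live in `cartmap.units` and are
round-trip exercised throughout the suite.

## Curve fitting

Ordinary (unweighted) least squares on raw deformation in µm — instrument
noise is assumed homoscedastic — over (ln E, ln k), which enforces
positivity without bounds; Levenberg–Marquardt with fixed tolerances
(ftol = xtol = 1e−12, ≤ 200 function evaluations), fully deterministic.
The initializer inverts Hertz at the mean of the last 10 % of samples for
E and maps the half-creep crossing time through g(τ) = 0.5 (τ_half ≈ 0.258)
for k; flat or degenerate curves fall back to configured defaults
(0.5 MPa, 5×10⁻¹⁵ m⁴/(N·s)) with a logged warning. Curves whose
deformation *decreases* by more than 5 µm (far beyond noise) are rejected
as non-physical rather than repaired.

Validity gates, evaluated on every fit:

* r² ≥ 0.70, computed over the **entire** creep-phase curve (the
  equilibrium plateau alone is always well fit; the whole-curve criterion
  is what protects the transient-borne permeability);
* a_eq/h ≤ 0.55, using the **equilibrium** contact radius — the largest
  during creep, hence the conservative choice.

Permeability is valid only when both pass; the equilibrium modulus is
reported whenever the optimizer converges. In practice the gates reproduce
the expected field behavior: stiff, degenerate regions creep only a few
micrometres, the noise-dominated whole-curve r² drops below 0.70, and
their permeability is dropped while their modulus is kept.

## Gravimetry

φʷ = (W_wet − W_dry)/(W_wet − W_PBS) · ρ_PBS/ρ_w and
WC = (W_wet − W_dry)/W_wet × 100. The PBS/water density ratio defaults to
1.005 (near-unity; configurable). Samples with wet weight below 0.5 mg are
flagged (a 0.1 mg-division balance resolves their submerged weighing
poorly) but not rejected.

## Regional statistics

Summaries are mean ± SEM (sd/√n, undefined at n = 1) per
(group, bone, region) cell. Group comparison machinery is pairwise Welch
t-tests with Bonferroni adjustment (p → min(1, m·p)) — deliberately **not**
a linear mixed-effects model; donor correlation is not modelled and the
output columns are named accordingly. The ligament analysis pools each
donor's volar-half regions (VR, VC, VU; the pooling rule is configurable)
into one value per donor, pairs it with that donor's VLC stiffness, and
reports the Pearson r with the exact two-sided t-transform p-value
(t = r√((n−2)/(1−r²)), n−2 df). Permeability enters correlations only
through gate-valid fits.

## Synthetic cohort

The generator emulates the study design: 3 groups × 6 donors × 2 bones ×
6 regions, per-donor random intercepts shared across a donor's regions,
creep curves from the forward model plus i.i.d. Gaussian noise
(σ = 0.5 µm), gravimetric weights inverted from target porosity, and
per-donor VLC stiffness. Distribution choices: truncated normal for
modulus, thickness and porosity; log-normal for permeability and wet
weight. A single seed fans out to per-donor substreams keyed by
(seed, group, donor), so growing the cohort never reshuffles existing
donors, and a truth table of every generating parameter is emitted.

Key defaults and their rationale:

* **Cell means** follow the study's regional pattern — advanced-stage
  thinning and stiffening concentrated in the volar-ulnar metacarpal
  (0.25 mm, 0.83 MPa) and volar trapezium (VC 0.24 mm, 1.13 MPa) — with
  unlisted cells filled so each group's 12-cell modulus/porosity average
  equals its overall mean (0.45/0.41/0.66 MPa; 0.76/0.80/0.82).
* **Healthy modulus dispersion** (donor intercept 0.02 MPa, residual
  0.02 MPa) is calibrated to the instrument's healthy deformation window:
  δ_eq maps 50–80 µm to E ∈ [0.23, 0.47] MPa, so healthy spreads must be
  modest for most deformations to land in-window. The advanced group is
  far more heterogeneous (residual 0.15 MPa plus a 0.25 MPa donor-level
  volar-trapezium component), reflecting mixed cartilage/eburnated-bone
  surfaces.
* **Permeability** (log-normal, median 6×10⁻¹⁵ m⁴/(N·s)) is chosen so
  characteristic creep times sit well inside the 600-s hold, consistent
  with a protocol benchmarked to reach equilibrium; magnitudes are
  order-of-magnitude choices surfaced in the spec object.
* **Ligament coupling**: for each donor, a standard normal z₁ scales the
  volar-trapezium modulus offset and stiffness is drawn as
  μ + σ(ρ·z₁ + √(1−ρ²)·z₂), imposing the target donor-level correlation
  (default ρ = −0.8 in the advanced group, 0 elsewhere). The observed
  correlation is attenuated by donor intercepts and residual region noise
  (expected |r| ≈ 0.75 at the defaults). A companion positive coupling of
  stiffness to volar permeability is *not* imposed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: balance quantization (weights are continuous),
instrument drift or correlated noise (noise is i.i.d. Gaussian), partial
eburnation within a region (each region is one homogeneous material),
preload-phase deformation, and any systematic deviation of real cartilage
from the two-exponential transient.

## Numerical choices and degenerate inputs

Truncated-normal draws redraw up to 1000 times then clip with a logged
warning; thickness is floored at 0.05 mm and modulus at 0.05 MPa; porosity
lives in (0.30, 0.97); the implied water mass fraction is kept below
0.985·φ/ρ-ratio so the back-computed PBS weight stays physical. Master
curve inversions use bracketed root-finding (xtol 1e−14). Gate thresholds
are inclusive (r² = 0.70 and a/h = 0.55 both pass). Single-time forward
evaluations pad the curve container to its two-sample minimum.

The endpoint property "δ(600 s) within 1 % of δ_eq" holds on the
physiological band E ∈ [0.2, 2] MPa × k ∈ [5×10⁻¹⁵, 10⁻¹⁴] m⁴/(N·s); at
much lower E·k the diffusion time a²/(E·k) simply exceeds the 600-s hold
and no transient of this time scale can equilibrate — such parameters are
outside the band the protocol was designed for, though the fitter still
recovers them (the recovery tests deliberately span k down to 10⁻¹⁶).

## Problem sizes

The default cohort is 216 regions (3×6×2×6) at 2 Hz sampling (1201 points
per 600-s curve); a full pipeline run fits all 216 curves in a few
seconds. Statistical property checks use 20–200 donors per group
(distribution-level checks) and 40–100 seeds (correlation sign-recovery),
sizes at which the Monte-Carlo error of each checked fraction is a few
percent.

## Known limitations

* The transient master curve is a documented stand-in for the unprinted
  fitting model of the underlying experimental literature; absolute
  permeabilities inherit its time normalization.
* The thin-layer gate flags invalid geometry but the default model does
  not correct for it; enabling the bonded-layer polynomial changes δ_eq
  and is therefore off by default for reproducibility.
* Welch-plus-Bonferroni is not a substitute for mixed-effects inference
  when donors contribute many correlated regions.
* r² on raw deformation is assumed; fitting transformed deformation would
  shift the gate's effective strictness.
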