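# Methods

`coromech` implements a triaxial (circumferential–axial–radial) analysis of
passive and active coronary-artery wall mechanics: constitutive laws, the
reduction of inflation–extension measurements to mean-wall stresses,
constrained global estimation of the material constants, and a two-layer
residual-stress model of the transmural stress distribution.

## Constitutive model

The passive wall follows the Fung exponential pseudo-strain-energy

```
W_p = (C1/2) (e^Q − 1),
Q   = a1 Eθ² + a2 Ez² + a3 Er² + 2a4 EθEz + 2a5 EzEr + 2a6 ErEθ,
```

with Green strains `E_i = (λ_i² − 1)/2` and no shear terms.  Maximal
smooth-muscle activation (60 mM K⁺) is described by an error-function
energy

```
W_a = C2 (erf(Q′) − 1),     Q′ = λθ/b1 + λz/b2 + λr/b3 − b′.
```

`C1`, `C2` carry stress units (kPa internally; mmHg only at the pressure
I/O boundary, 1 mmHg = 0.1333224 kPa); `a1–a6`, `b1–b3`, `b′` are
dimensionless.  The `b_i` set the width of the active length–tension curve
along each axis and `b′` its position; the original formulation's `b4–b6`
enter only through `b′ = b4/b1 + b5/b2 + b6/b3` and are not individually
identifiable, so only `b′` is stored.  A planar (2D) variant with the
radial term removed (`b3=None`) is provided for model comparison.  The
active energy is evaluated as `−C2·erfc(Q′)` to stay accurate in the
saturated tail.

Constitutive (direct-partial) 1st Piola–Kirchhoff stresses are
`T_i = λ_i ∂W_p/∂E_i + ∂W_a/∂λ_i`, with the three strains treated as
independent arguments.  Each active component is bounded by
`2C2/(b_i√π)`, attained exactly where `Q′ = 0`; this closed form anchors
the sensitivity analysis (rescaling `b3` rescales the radial peak as
`1/b3` and leaves the circumferential peak unchanged; rescaling `b1` or
`b2` only moves the peaks in stretch).

### Convexity of Q

Two diagnostics are reported, never silently enforced: strict
positive-definiteness of the symmetric matrix `[[a1,a4,a6],[a4,a2,a5],
[a6,a5,a3]]` (leading principal minors), and the inequality printed in the
source literature for this family, `a4²+a5²+a6²−a1a2−a2a3−a1a3 > 0`, which
is the reverse of a positive-definiteness surrogate.  The published
constant sets satisfy one, the other, or neither, so the fitting default
enforces positivity only (`constraint_mode='none'`); either convexity mode
can be switched on and is then handled by rejection-resampling at GA
initialization plus a static penalty (1e9 per unit violation) during
evolution.

## Mean-wall stress reduction and theory closure

One protocol record is (transmural pressure P, loaded outer diameter,
axial force F) at fixed axial stretch and activation state.  With the
no-load wall area `A0` and the zero-stress mid-wall circumferential length
`l0`, the reduction computes `r_i = √(r_o² − A0/(πλz))`, `h = r_o − r_i`,
the mid-wall stretch `λθ = π(r_i+r_o)/l0`, and the experimental 1st PK
triple

```
Tθ = P r_i/(λθ h),   Tz = (1/λz)[F/(π(r_o²−r_i²)) + P r_i²/(h(r_o+r_i))],
Tr = −r_i P/((r_o+r_i) λr).
```

These follow from the radial equilibrium of the loaded thick-walled
cylinder; in particular the mean radial Cauchy stress is
`⟨σ_r⟩ = −P r_i/(r_i+r_o)` regardless of material.  For an incompressible
material the energy determines only the stress *differences*
`σθ−σr` and `σz−σr`; the theory side of the fit therefore closes them with
the same mean radial equilibrium:

```
σθ = Dθ (r_i+r_o)/(2 r_o),   σr = σθ − Dθ,   σz = Dz + σr,   T_i = σ_i/λ_i.
```

This closure makes theory and reduction exactly consistent: a dataset
generated from a constant set is fitted by that same set with zero
residual, and the reduced radial-to-circumferential 1st PK ratio
`(r_o+r_i)λr/(λθ h)` evaluates to ≈5 for whole-wall geometry — the ratio
reported for these vessels.  A direct-partial radial stress cannot do
either (its radial component does not respond to the reaction pressure),
which is why the closure, not the direct partial, enters the objective.

## Parameter estimation

The constants are estimated sequentially: the seven passive constants
against the Ca²⁺-free points (sum of squared 1st PK differences in all
three directions, kPa²), then the five active constants against the
K⁺-constricted (total) points with the passive set fixed.  An optional
joint least-squares refinement over all twelve constants exists but is off
by default.

A bounded trust-region local least squares (Levenberg–Marquardt role)
started from the geometric mid-point of the bounds provides a
deterministic warm start; a real-coded genetic algorithm then searches
globally.  GA defaults (all configurable): population 120, 300
generations, tournament size 3, blend crossover with probability 0.8,
Gaussian mutation with per-parameter scale 0.1×(bound width) decaying
linearly to 0.01, elitism 2, seed recorded in every output.  Half of the
initial population is jittered around the warm start, half drawn uniformly
in the bounds; populations are scored in single vectorized numpy calls.
The GA winner is polished by a final local pass.  Bounds: `(1e-4, 50)` for
`C1, a1–a6`; `(1e-3, 200)` for `C2`; `(1e-3, 20)` for `b1–b3, b′` —
covering the published ranges with margin.  Goodness of fit is the
per-component `R² = 1 − SSres/SStot` with `SStot` about the experimental
mean.

The estimation layer is also exposed as scikit-learn estimators
(`PassiveStressRegressor`, `ActiveStressRegressor`) whose `X` rows are
`(λθ, λz, r_i, r_o)` and whose `y` rows are `(Tθ, Tz, Tr)`; they compose
with sklearn model selection and pipelines.

## Synthetic data generator

The generator emulates the measurement protocol: pressures 20–200 mmHg in
steps of 20, axial stretches 1.3 and 1.5, passive and maximally
constricted states (40 records).  For each record it solves the mean-wall
equilibrium `Tθ_theory(λθ) = P r_i/(λθ h)` for the loaded outer radius —
taking the largest root in the admissible stretch bracket (1.01, 2.5),
i.e. the stable distension branch, since the soft toe of the exponential
admits a spurious low-stretch crossing — and inverts the axial formula for
the transducer force.  Reducing a generated record therefore returns the
theoretical stress triple to machine precision.

Noise is multiplicative Gaussian with configurable CV, applied
independently to the measured diameter and force (the experimental error
pathway), never to derived stresses.  The real vessels' `A0` and `l0` are
not published; the defaults are plausible porcine-RCA values chosen once:
`A0 = 1.4 mm²`, `l0 = 8.4 mm` for the dissected intima–media (IM) layer
(loaded `r_i ≈ 2 mm`, `h ≈ 0.09 mm`) and `A0 = 2.9 mm²`, `l0 = 7.2 mm`
for the entire wall (`h/r_i ≈ 0.1`).  With the IM Heart-1 constants the
circumferential stretch spans ≈1.19–1.71 over the protocol; the published
figures start near 1.1, a region the fitted exponential's soft toe makes
unreachable at 20 mmHg with any fixed geometry — the generated sweep is
compressed toward its upper end.

What passing the recovery tests shows — and does not show.  On noiseless
data the sequential protocol recovers the generating constants to machine
precision, which validates the estimation machinery, not its robustness.
At 2% diameter/force noise the picture changes qualitatively: a 2%
diameter error displaces points *along* the steep exponential, and even
the true constants score `R² ≈ 0–0.7` against such data; the fitted curves
recover the truth curves only to `R² ≈ 0.83–0.98`.  Real video-caliper
diameter measurements are good to a few tenths of a percent, and the
`R² > 0.9` of the published fits implies errors well below 1%; the 2%
noise condition should be read as a stress test far beyond the
experimental regime, and results under it as a noise-physics ceiling, not
an optimizer deficiency.

## Two-layer transmural model

The wall is two concentric incompressible layers — IM (carrying the active
stress) and a passive adventitia — each with an independent stress-free
(cut-open) configuration: inner/outer radii and opening angle `Φ`
(`Φ = 0` means no residual strain; convention `k = π/(π−Φ)`, `λθ = k r/R`,
radial map `r = √(r_in² + (R²−R_in²)/(k λz))`).  Whether the source's
layers were contiguous or independently cut in the stress-free state
cannot be determined from the main text; independent per-layer stress-free
states with deformed-configuration continuity are used, which makes the
stretches — hence `σθ` — discontinuous at the interface while the radial
traction stays continuous.

Radial equilibrium `dσ_r/dr = (σθ−σr)/r` with `σ_r(r_i) = −P`,
`σ_r(r_o) = 0` is solved by shooting on the deformed inner radius.  The
stress difference is purely kinematic pointwise, so the integration is a
cumulative trapezoid quadrature on per-layer grids (default 200
points/layer; interface `σθ` changes by <1e-7 on grid doubling), and the
outer-boundary residual is bracketed on a coarse scan and driven to zero
by Brent's method (relative tolerance 1e-14 on `r_i`; boundary residuals
≈1e-14 kPa; equilibrium residual on a refined grid ≈2e-5 kPa/mm).

The layer-specific stress-free geometry of the original preparations is
unpublished, so scenario geometry is synthetic and *calibrated*: template
layers (IM passive = IM-table mean; adventitia passive = whole-wall-table
mean as a surrogate, no adventitia-specific table being published; IM
active = the joint fit of all six IM layers, `C2=28.92, b1=0.43, b2=1.62,
b3=4.38, b′=4.87`) have their stress-free thicknesses rescaled until the
solved loaded wall matches printed targets — thickness 0.22 mm with the IM
half of it at 80 mmHg and `λz = 1.3`, 0.44 mm at 160 mmHg for pressure
overload — to within 0.5%.  Template radii and opening angles
(`Φ_IM = 1.6 rad > Φ_adv = 0.8 rad`) were chosen once so the calibrated
solution reproduces the printed qualitative structure: the IM layer
carries most of the circumferential load at `λθ ≈ 1.37` while the
adventitia stays near-slack (`λθ ≈ 1.12`), `σθ` drops discontinuously at
the interface, and `|σ_r|` decreases monotonically from `P` to zero.
Under this geometry, activation lowers the IM mean `σθ` by ≈6% (the
published analysis reports ≈15% with its own geometry) while `σ_r` changes
by well under 1 kPa, and pressure overload roughly doubles the inner-wall
`|σ_r|/σθ` ratio.  Absolute stress magnitudes are geometry-dependent and
are treated as qualitative, not numeric, targets.

For comparison with the earlier planar active model, a 2D counterpart is
constructed from published widths `b1 = 0.12, b2 = 0.18` with its
unpublished `C2` and offset least-squares matched to the 3D law's
circumferential active stress over the physiological sweep (`λθ ∈
[1.1, 1.5]`, `λz = 1.3`).  The circumferential interface difference
between 2D and 3D solutions is small (≈2–3%) and flat in pressure, as
reported; the radial difference depends on the unpublished reference
geometry and is reproduced only as a nonzero, hand-checkable metric.  The
uniform-circumferential-stress thickness search (wall thickens with
pressure so the thickness-averaged `σθ` is conserved) recovers the
baseline thickness identically and yields 0.442 mm at 160 mmHg — the
near-twofold thickening the overload scenario assumes.

## Published tables as fixtures

The subject-level material constants of both preparations ship as CSV
fixtures at printed precision, along with the printed Mean/SD rows.
Summary statistics are recomputed with the sample (n−1) SD; agreement with
a printed cell is defined a priori as one unit in the last printed digit,
since rounded subject cells pin the true summary only to ±0.5 ulp and the
printed summary adds its own rounding.  All 36 mean cells and all
whole-wall SD cells reproduce under this criterion.  The IM-table active
SD cells reproduce only under the population (n) convention, and the
IM-table passive SD cells for `a1–a6` match neither convention — that SD
row is internally inconsistent with its own subject rows (likely computed
from unrounded fits); the discrepancy is reported, not patched.

## Numerical choices and limitations

* `e^Q` overflow guard at `Q > 700` raises a diverged-energy error in the
  scalar API; the vectorized objective substitutes a large finite penalty
  (1e12) so optimizers never see NaN.
* Axial length at no-load is taken equal to that at zero stress (stated
  assumption of the protocol); `λθ` is evaluated at mid-wall.
* Shear stresses, viscoelasticity, preconditioning transients,
  perivascular tethering, growth/remodelling and fiber-level
  microstructure are out of scope.
* The mean-wall fit homogenizes the wall; layer-specific heterogeneity
  enters only through the two-layer model's separate constants.
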