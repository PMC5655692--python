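# coromech

Triaxial passive and active wall mechanics of coronary arteries:
constitutive modelling, material-constant estimation from
inflation–extension tests, and a two-layer residual-stress model of the
transmural stress distribution.

## Who this is for

Vascular-biomechanics researchers who characterize arterial tissue with
pressure–diameter–axial-force protocols (pressures stepped over the
physiological range at fixed axial stretches, in a relaxed Ca²⁺-free state
and under maximal K⁺-induced smooth-muscle constriction) and want a
tested, scriptable pipeline from raw records to fitted strain-energy
constants and transmural Cauchy-stress profiles.

## The model

Passive behaviour follows the Fung exponential pseudo-strain-energy in the
three normal directions (circumferential θ, axial z, radial r):

```
W_passive = (C1/2)(e^Q − 1)
Q = a1 Eθ² + a2 Ez² + a3 Er² + 2a4 EθEz + 2a5 EzEr + 2a6 ErEθ
```

with Green strains `E_i = (λ_i² − 1)/2` and incompressibility
`λθ λz λr = 1`.  Smooth-muscle activation adds an error-function energy

```
W_active = C2 (erf(Q′) − 1),    Q′ = λθ/b1 + λz/b2 + λr/b3 − b′
```

whose 1st Piola–Kirchhoff stress components are bounded by `2C2/(b_i√π)`.
Constants are estimated by minimizing the summed squared differences
between theoretical and experimental 1st PK stresses — passive constants
first, then active constants with the passive set fixed — using a bounded
local least-squares warm start refined by a seeded genetic algorithm under
positivity (and optional convexity) constraints.  A two-layer thick-wall
cylinder with layer-specific opening-angle residual strain then yields the
transmural distribution of circumferential and radial Cauchy stresses,
solved by shooting on the deformed inner radius.  Details, conventions and
numerical choices are in `docs/methods.md`.

## Worked example

Generate a synthetic dataset from published intima–media constants, fit
both strain-energy functions, and solve the transmural stress profile:

```python
import numpy as np
import coromech as cm
from coromech.experimental import points_by_state
from coromech.fitting import FitConfig, fit_passive, fit_active

truth = cm.default_ground_truth("IM", "Heart 1")
records = cm.generate_dataset(truth, cm.ProtocolSpec(noise_cv=0.0, seed=0))
points = points_by_state(cm.reduce_dataset(records, truth.geometry))

cfg = FitConfig(seed=0)
passive = fit_passive(points["passive"], cfg)
active = fit_active(points["total"], passive.constants, cfg)
print("passive:", np.round(passive.constants.as_array(), 3))
print("objective (kPa^2): %.3g" % passive.objective,
      " R2:", {k: round(v, 4) for k, v in passive.r2.items()})
print("active: ", np.round(active.constants.as_array(), 3))

im0, ad0 = cm.coronary_layer_templates()
im, ad = cm.calibrate_geometry(0.22, 0.5, 80.0, 1.3, [im0, ad0],
                               activation="active")
prof = cm.solve_wall([im, ad], 80.0, 1.3, "active")
ii = prof.interface_index
print("r_i = %.3f mm, h = %.3f mm" % (prof.r_i, prof.thickness))
```

Output:

```
passive: [6.29 2.79 1.64 5.49 2.5  3.2  2.11]
objective (kPa^2): 1.18e-23  R2: {'T_theta': 1.0, 'T_z': 1.0, 'T_r': 1.0}
active:  [49.8   0.55  1.13  4.66  4.79]
r_i = 1.431 mm, h = 0.220 mm
```

The fit recovers the generating constants `(C1, a1…a6)` and
`(C2, b1–b3, b′)` exactly (the noiseless protocol is self-consistent, so
the objective reaches machine zero and every per-component R² is 1).  The
two-layer solve calibrates the stress-free geometry to a 0.22 mm loaded
wall at 80 mmHg: circumferential Cauchy stress is high in the
intima–media layer (≈120–131 kPa), drops discontinuously to ≈14 kPa in
the adventitia, while radial Cauchy stress rises continuously from
−10.67 kPa (= −P) at the lumen to zero at the outer surface.

The same steps are available from the shell:

```sh
coromech simulate --truth "IM:Heart 1" --seed 0 --out run/meas.csv
coromech fit --measurements run/meas.csv --seed 0 --out run/
coromech report run/
```

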