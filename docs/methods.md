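# Methods

`cellstrand` simulates a confluent monolayer of carcinoma-like cells
chemotaxing from a seeding reservoir into a microfluidic channel, and
measures when and how single cells or clusters dissociate ("rupture")
from the invading strand.  This note records the model, the numerical
choices, the calibration of free constants, and what the scaled-down
study conditions can and cannot show.

## Model

Each cell `i` is a smooth indicator field `phi_i(r)` on a shared 2-D
grid, 1 inside the cell and 0 outside, with the interface tracked at the
1/2 level set.  The walls of the device are a static field `phi_wall`
with the same interface profile.  Fields evolve by an overdamped
advection–relaxation law

```
d(phi_i)/dt + P_i . grad(phi_i) + d(phi_i)/dt|_adh = -(1/gamma) dH/d(phi_i)
```

with the Hamiltonian

```
H = sum_i int [ alpha/4 phi_i^2(phi_i-1)^2 + K/2 |grad phi_i|^2 ]   (interfacial)
  + sum_i lam (1 - int phi_i^2 / pi R^2)^2                          (area)
  + sum_{i>j} int g phi_i^2 phi_j^2 + sum_i int g_wall phi_i^2 phi_wall^2   (exclusion)
```

and the adhesive advection

```
d(phi_i)/dt|_adh = sum_{j!=i} omega f(grad phi_j) . grad phi_i
                 + kappa f(grad phi_wall) . grad phi_i ,
f(z) = z / (1 + eps |z|^2).
```

The polarity `P_i = p_i (cos theta_i, sin theta_i)` is the velocity the
cell would have absent all interactions.  The angle of a chemotactically
guided cell is an Ornstein–Uhlenbeck process relaxing toward the
gradient direction `theta0 = pi/2` at rate `k_theta` with rotational
diffusion `D_r`; followers have `k_theta = 0`.  The angle lives on the
unwrapped line: wrapping to `(-pi, pi]` would change the stationary law
`theta - theta0 ~ N(0, D_r/k_theta)`.

Three phenotypic states differ only in polarity magnitude: followers
(`p0`), guided cells (`2 p0`, chemotaxis on), and leaders (`3 p0`).
Cells in the seeding reservoir are followers; a cell within one radius
of the channel mouth or inside the channel becomes guided; a guided cell
newly arriving at the invading front draws once from the
contact-inhibited lottery `P_leader = max(1 - n_i/n_c, 0)`, where `n_i`
is its cell–cell contact node count.  Transitions are permanent.
"Front" means: in the channel with no other channel cell more than
`R/2` above it within `|dx| < R`.  Whether a cell that leaves and
returns to the front redraws was an open choice; we draw once per
arrival event.

## Parameters

Internal units are micrometres and hours; rates quoted per minute are
converted at config load.

| parameter | default | units | origin |
|---|---|---|---|
| p0 | 13.3 | um/h | typical single-cell speed; guided = 2 p0, leader = 3 p0 |
| k_theta | 0.84 (=0.014/min) | 1/h | default chemotaxis strength (1.4 x reference) |
| D_r | 1.344 (=0.0224/min) | 1/h | fixed by CI = exp(-D_r/2k_theta) ~ 0.45 |
| R | 6.9 | um | fixed by Pe = p0/(R D_r) ~ 1.43 |
| alpha, K | 40, 9.32 | E/um^2, E | interface width d = 2 ln9 sqrt(2K/alpha) ~ 3 um |
| lam | 2000 | E | holds cell area within a few % of pi R^2 under squeezing |
| g, g_wall | 120, 80 | E/um^2 | overlap suppressed to ~1% of self-interaction |
| gamma | 1 | E h/um^4 | sets the relaxation clock; other constants scale to it |
| omega (omega0) | 100 | um^2/h | cell-cell adhesion reference, see calibration |
| kappa | 100 | um^2/h | cell-wall adhesion |
| eps | 1.0 | um^2 | saturation of f; |f| <= 1/(2 sqrt(eps)) |
| n_c | 256 at h_ref=0.4 um | nodes | leader lottery scale, rescaled ∝ 1/h |

The width-dependent adhesion profile multiplies `omega0` by 0.7 (6 and
10 um channels), 0.8 (20 um) and 1.0 (50 um): effective cell–cell
adhesion is weaker in narrow confinement.

**Calibration.**  The interfacial/exclusion/adhesion constants are free
constants of this implementation.  They were fixed, once, against the
model's qualitative reference behaviors: (i) an isolated cell is stable
and near-circular (contour circularity > 0.95) at area `pi R^2`; (ii) a
cell pair stays bound under a polarity mismatch of order `p0` but is
torn apart by a sustained leader-scale pull; (iii) a confluent monolayer
invades channels of every width within the 18 h observation window and
predominantly sheds single cells; (iv) the closed confluent reservoir is
solid-like (jammed) at the low end of the Peclet sweep and fluid-like at
the default Pe = 1.43.  These are the study conditions; they are not
revisited per experiment.

## Numerics

* Grid: node-centered, spacing `h` (production 1.0 um), `h <= d/2`
  enforced.  Domain edges are wall material inside `phi_wall`; the
  jamming box is periodic in x.
* Operators: second-order central differences (one-sided at walled
  edges); five-point Laplacian with mirror closure.  The gradient energy
  in `H` is quadratured with *forward* differences so that the analytic
  functional derivative is the exact discrete gradient of the discrete
  `H` on periodic grids — the perturbation oracle then holds to rounding
  even on rough fields.
* Integrator: synchronous explicit Heun (trapezoid) steps.  Forward
  Euler at the production step size advects an isolated cell ~10% slower
  than its polarity (an O(dt) bias); Heun removes this at under twice
  the per-step cost.  Euler remains available.
* Step size: `dt = 0.5 min(gamma h^2/4K, h/v_max, 2 gamma/(3 alpha +
  2 max(g, g_wall) + 8 lam/pi R^2))` with `v_max` the leader speed plus
  the saturated adhesion advection `(omega+kappa)/(2 sqrt(eps))`.  The
  reaction bound matters: without it, configurations with weak adhesion
  (larger advective bound) destabilize through the double-well term.
* Performance: the right-hand side is evaluated by a fused numba kernel
  over per-cell support bounding boxes (fields below 1e-6 are treated as
  zero outside the boxes); a pure-numpy reference path is kept and the
  two are cross-checked in the tests to 1e-6 relative.
* Phase fields overshoot [0, 1] transiently by up to ~0.05-0.3 near
  hard multi-body squeezes; the double-well restores them and the
  maximum excursion is reported per run.
* Polarity noise: Euler–Maruyama; one master seed spawns independent
  per-replicate streams (seeding jitter, leader lottery, one stream per
  cell), so replicate k is a pure function of (config, seed, k).

## Analysis

* Contact graph: edge where `int phi_i^2 phi_j^2 d2r` exceeds 10% of
  `h^2` times the peak nodewise overlap of two equilibrated adhering
  cells (calibrated once per parameter set and cached).
* Rupture: a connected component with no seeding-region cell, disjoint
  from the bulk component, persisting two consecutive analysis frames
  (3 simulated minutes apart); the event time is the detecting frame
  minus half an interval.  The persistence requirement suppresses
  interface-noise flicker; the dissociation criterion is declared, not
  inferred from data.
* Survival: Kaplan–Meier product-limit via lifelines (exponential
  Greenwood 95% band); replicates reaching 18 h unruptured are
  right-censored.
* Jamming: time-and-ensemble MSD of unwrapped trajectories; ordinary
  least squares on lags `t > 3/D_r` (not through the origin);
  `Deff = slope/(4 D0)`, `D0 = p0^2/(2 D_r)`; solid iff `Deff < 0.012`
  (boundary value classified fluid).

## Scaled-down study conditions

Ensembles run on one CPU, so the full-scale geometry (hundreds of
cells, 300 replicates per condition) is replaced by: invasion devices
with a 56 x 20 um reservoir (8 cells; 80 x 20 um and 11 cells for the
50-um channel, so several cells can advance abreast), 22 um channels,
`h = 1` um, 30 replicates per width; a 44 x 34 um periodic jamming box
with 9 cells at area fraction 0.90, 2 h equilibration, 12 h of recorded
motion, 8 pooled replicates per Pe for the transition sweep (3 per
point on the coarse phase-diagram grid).  These reproduce the
qualitative phenomena — single-cell-dominated rupture in all widths,
slower rupture under stronger adhesion, a sharp solid-to-fluid rise of
`Deff` across the Pe sweep, no invasion at the two lowest Pe — but not
quantities that need large supplies of cells: mean cluster sizes stay
near 1 because at most a few cells occupy the channel when the first
dissociation occurs, and the large (>10 cell) clusters seen in wide
channels at full scale cannot form.  Two further desk-scale artifacts
are documented under limitations: 10-um channels shed single-file
*pairs* unusually often, and near the default Pe the measured `Deff`
sits close to the 0.012 classification threshold, so threshold-based
statements at that corner of the phase diagram are at the resolution
limit of the estimator.

## Known limitations

* **Wall adhesion does not gate narrow-channel entry at this
  resolution.**  With a 3 um interface on a 1 um grid, entry into 6-um
  channels is controlled by wall hardness (`g_wall`) and tension versus
  propulsion; the advective `kappa` term sticks cells to walls (and at
  large `kappa` pins them) but its funneling assistance at the mouth is
  eroded by wall exclusion.  The regime where entry requires `kappa > 0`
  evidently needs a much finer interface relative to the channel and a
  large cell supply.  The no-wall-adhesion control experiment is still
  implemented and run; its outcome at desk scale differs from the
  full-scale expectation, and the corresponding test documents this
  honestly rather than masking it.
* **Mean cluster size is not monotone in channel width at desk scale.**
  In 10-um channels two elongated cells squeezed single-file form one
  strongly coupled plug that often detaches as a pair, while the short
  strands that desk-scale reservoirs support keep 20- and 50-um cluster
  sizes near 1; at full scale the width trend is carried by long
  many-cell strands that cannot form here.
* **The jamming classification is marginal at high adhesion and default
  Pe.**  The measured `Deff` at (omega0..2 omega0, Pe = 1.43) falls
  within estimator noise of the 0.012 threshold, and at strong adhesion
  with near-zero motility a slow adhesion-driven compaction creep
  inflates `Deff` relative to the tiny free-cell normalization `D0`.
  Phase-diagram containment statements that hinge on classifying these
  marginal points are therefore unreliable at this scale.
* The reservoir is not refilled; long invasions can starve the channel.
* No cell division or death; no polarity coupling between neighbors;
  2-D only (channel height is not modeled).
* `n_c` is tied to grid resolution through the contact-node count; the
  1/h rescaling preserves physical contact length but the reference
  spacing (0.4 um) is itself a calibration choice.
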