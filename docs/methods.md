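# Methods

This note records the model, its parameters, the numerical choices, and
the design decisions behind `mothmpc`, in enough detail to reproduce or
deliberately change any of them.

## The two-body flight model

The moth is reduced to two rigid ellipsoids in the vertical plane. Body 1
(head-thorax, mass m1, pitch inertia I1) carries the reference point
(x, y) at its centre with its long axis at angle θ; a pin joint sits L1
tail-ward of the centre, and body 2 (abdomen, m2, I2) extends L2 from the
joint along its own axis angle φ. Both angles are measured
counter-clockwise from +x and are never wrapped during integration.
Abdominal flexion β = φ − θ − π is zero for a straight body; at the goal
attitude θ = π/2 the straight body hangs vertically, abdomen down.

Forces and torques:

* **Gravity** on both mass centres.
* **Damped torsional spring** at the joint: potential ½κβ_w² and Rayleigh
  dissipation ½η(φ̇−θ̇)², where β_w is β wrapped to (−π, π]. Wrapping
  means a full abdominal revolution returns the joint to its rest state;
  see "Wrapped spring" below.
* **Aerodynamic drag**: quadratic blunt-body drag −½ρ_a C_d A_i |v_i| v_i
  on each mass centre, with A_i = π b_i² the ellipsoid cross-section. The
  drag law is a pluggable function (`drag_law=` argument throughout), so a
  different formulation can be swapped in without touching the integrator.
* **Applied efforts**, constant within a control window: a force of
  magnitude F at angle α relative to the body-1 axis, applied at the wing
  hinge — the body-fixed point offset L3 along the axis (shifted
  treatments only) and h_wing dorsal of it — plus a wing torque τ_wing on
  θ and a joint torque τ_abdo applied +/− across the joint (on φ / on θ).

The equations of motion were derived by hand from the Euler–Lagrange
form; the hand derivation is guarded by a test oracle that assembles the
same equations purely from finite differences of the scalar energies (see
`tests/_oracles.py`), agreeing to better than 1e-6 relative on random
states across all treatments.

### Why the wing-hinge offset and the wrapped spring

The published account of this system reports that configurations lacking
both a wing torque and a force-origin offset are dynamically unstable,
with the abdomen of the underactuated variants rotating without bound,
while the fully actuated variants fly 10 s stably. Neither behaviour is
possible if the mean wing force acts exactly at the head-thorax centre:
that model is a passively stable hanging pendulum, and with the measured
κ an unwrapped spring would stop any abdominal wind-up after at most
τ_max/κ ≈ 4.3 rad. Two closures restore the reported phenomenology, and
both are physically grounded:

* the stroke-averaged wing force acts at the **wing hinge**, dorsal of
  the body axis (h_wing). Hovering then carries a constant pitch moment
  F·h_wing that must be actively cancelled — by τ_wing (fa), partly by
  the L3 lever (fs/us), or by cranking the abdomen as a reaction wheel
  (ua);
* the spring acts on the **wrapped** flexion angle, so sustained
  abdominal rotation is mechanically possible once the hinge moment
  exceeds the maximum spring torque κπ.

The default constants place the system exactly in the narrow regime these
numbers jointly admit: hover moment F_hover·h_wing ≈ 8.2 mN·m lies
between κπ ≈ 7.2 mN·m (below which a statically cocked abdomen would
absorb the moment) and τ_wing max = 10 mN·m (above which even the fully
actuated variant could not hold pitch). Both closures are parameters
(`h_wing`, `wrap_spring`) and can be switched off to recover the
centre-applied, unwrapped-spring model.

## Parameters (defaults.toml)

All defaults live in the versioned `defaults.toml`; code never hard-codes
them. The mechanical constants κ = 0.0023 kg·m²·rad⁻¹s⁻², the effort
ranges (F ≤ 0.443 N, |τ| ≤ 0.01 N·m, α over the full circle) and the
controller schedule (20 ms windows, 25% advance, 2500 realizations, 10 s)
are fixed measured/printed quantities. The remaining constants are chosen
once for mutual consistency with them:

| parameter | default | rationale |
|---|---|---|
| m1, m2 | 13.5, 16.5 g | total weight ≈ ⅔ F_max so hovering sits high in the force range yet climbing stays possible; abdomen 55% of body mass |
| L1, L2 | 12, 13 mm | body length 2(L1+L2) = 50 mm |
| I1, I2 | 0.456, 0.64 µkg·m² | uniform ellipsoid I = m(a²+b²)/5 |
| b1, b2 | 5 mm | drag cross-sections A = πb² |
| L3 | 6 mm | force-origin shift of fs/us, half of L1 |
| h_wing | 28 mm | places the hover moment inside the (κπ, τ_max) window above |
| η | 3e-4 N·m·s/rad | moderately damped abdominal mode; larger values inflate parasitic joint work, much smaller ones underdamp it |
| C_d, ρ_a, µ_a | 1.0, 1.204, 1.81e-5 | blunt body in standard air |
| weights w1..w6 | 1e6, 1e6, 400, 400, 400, 1 | inverse-square tolerances (1 mm, 1 mm, 0.05 rad, 0.05 m/s, 0.05 m/s, 1 rad/s); position penalized hardest, θ more than θ̇ |

Torque draws are magnitudes up to τ_max with an independent random sign
(`signed_torques`), the planar analogue of the (F, α)
magnitude-plus-direction force draw; strictly non-negative draws act as a
one-sided ratchet that destabilizes every treatment within seconds and
are available only as an option.

## Controller

Each window draws n effort sets, propagates all of them simultaneously
from the same initial state, evaluates λ at the window end against the
goal at t0 + 20 ms (even though only 25% of the winner is traversed), and
selects the argmin with ties broken toward the lowest draw index. Windows
use independent RNG substreams seeded by (seed, window_index), so any
window is reproducible in isolation and results are a pure function of
configuration and seed. The initial condition is at rest at the goal
(x = 0, y = y_goal(0) = 0, θ = π/2, straight body).

The goal is y_goal(t) = Σ A_i sin(2π f_i t) with the eleven frequencies
at prime multiples of 0.1 Hz (0.2 … 3.7 Hz) and amplitudes decaying as
1/f from 10 mm, keeping the per-component velocity amplitude flat;
x_goal = 0 and θ_goal = π/2 always.

## Numerics

* Batch rollouts use a vectorized fixed-step classical RK4 on the 0.5 ms
  output grid — the whole batch advances in lock-step, which is what
  makes thousands of 20 ms rollouts per window affordable. The advance
  point (25% of 20 ms = 5 ms) is exactly grid sample 10.
* `integrate_window` is the adaptive reference (RK45, rtol 1e-6,
  atol 1e-9 by default, dense output on the same grid). RK4-vs-adaptive
  agreement is tested; conservation tests run the reference at rtol 1e-9,
  where energy drift is below 1e-6 relative per simulated second.
* Work is accumulated per 0.5 ms step over the traversed 25% advance
  segment (a `segment="full"` option integrates the whole window
  instead). Cost of transport divides by the path length of the same
  segment; windows moving less than 1e-9 m are flagged undefined and
  excluded from medians.
* Box counting rasterizes the linearly interpolated track onto a
  1024-pixel isotropic grid (2% padding) and fits log N against
  log(1/ε) over the dyadic ladder ε = 2 … 256 px.
* The stiffness estimator evaluates the FFT ratio at the discrete bin
  nearest the drive frequency with a rectangular window; 15 s records at
  1000 Hz put all five standard drive frequencies on or next to a bin
  centre, so leakage is negligible for on-bin drives. The printed
  "x-intercept" of the κ̂-vs-frequency quadratic is implemented as the
  polynomial's value at zero frequency (a literal axis crossing would be
  a frequency, not a stiffness); the literal roots are also exposed.

## Statistics

Treatment groups are compared on one median per full simulation run (the
run is the unit of replication, avoiding pseudo-replication across
windows): Kruskal–Wallis omnibus with effect size
η² = (χ² − k + 1)/(n − k), Dunn's pairwise z-tests with tie correction,
a standard Bonferroni rule (reject when p < α/m, the divisor exposed
because other conventions exist), and compact-letter-display groupings.
The incidence χ² is Pearson's without continuity correction — the form
that reproduces the published statistic — and the rank-sum test uses the
exact null when both samples are tie-free and small, the tie-corrected
normal approximation otherwise.

## What the synthetic generators emulate — and what they do not

`trackstats.generate_track` produces smooth, optionally noisy 100 fps
planar paths (straight, circular, sinusoidal, smoothed random walk) with
known geometry. It emulates the sampling and smoothness of head tracks
from overhead video, not moth behaviour: no flights toward a flower, no
landing/takeoff, no tracking dropouts. `springfit.synth_trial` generates
exact linear spring–damper–inertia torque responses to a sinusoidal
angle drive plus white torque noise; real preparations add actuator
compliance, nonlinearity at large sweeps, and coloured noise. Passing
tests therefore certify the estimators and statistics on their stated
models, not the biology.

## Scaled-down study sizes

The full published experiment (40 replicate 10 s simulations per
treatment at 2500 realizations/window) is far beyond a desktop run. The
package's acceptance workflow uses 5 replicates × 1.5 s × 300
realizations per treatment for the four-treatment comparison and a single
2 s run for the instability check; these sizes give stable medians and
decisive rank-sum orderings for the tracking error while completing in
minutes.

## Known limitations

* The cost-of-transport ordering between fully and underactuated variants
  does not reproduce at these scaled-down sizes: the underactuated
  controller evades the expensive abdominal reaction-wheel work by
  letting pitch sag (which the position-dominant loss tolerates), so its
  measured cost stays near the force-only floor F/(m₁g) while the fully
  actuated variant pays for pitch-holding torque work. Its force-term
  cost alone is genuinely higher than the fully actuated one's, so the
  energetic handicap of underactuation is present but masked by this
  overhead at small batch sizes.
* During abdominal spin episodes the pitch angle temporarily sags by more
  than 1 rad; spin and sag co-occur because every spring wrap transmits a
  torque transient to the head-thorax.
* 2-D only: no roll/yaw, no wing aerodynamics model, no sensory delay or
  state-estimation noise; the controller is clairvoyant within a window.
* Greedy one-window lookahead: no terminal cost or multi-window planning.
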