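# Default model constants for the two-body hawkmoth simulator.
# All quantities SI (kg, m, s, N, rad) unless noted.
#
# Morphometrics and mechanics are chosen for mutual consistency with the
# fixed effort ranges below: total weight is ~2/3 of the maximum sampled
# aerodynamic force (hovering sits high in the force range but leaves climb
# authority), abdomen 55% of body mass, body length 2 (L1 + L2) = 0.05 m,
# inertias from the uniform-ellipsoid formula I = m (a^2 + b^2) / 5. The
# wing-hinge height h_wing places the mean flight force dorsal of the body
# axis; with these constants the hover pitch moment F * h_wing exceeds the
# maximum wrapped-spring torque kappa * pi but stays within the wing-torque
# range, so pitch is open-loop unstable yet controllable - the regime the
# torque and stiffness constants jointly define.
schema = 1

[moth]
m1 = 0.0135        # head-thorax mass, kg
m2 = 0.0165        # abdomen mass, kg
I1 = 4.56e-7       # head-thorax pitch moment of inertia, kg m^2
I2 = 6.4e-7        # abdomen pitch moment of inertia, kg m^2
L1 = 0.012         # head-thorax semi-axis (reference point to joint), m
L2 = 0.013         # abdomen semi-axis (joint to abdomen centre), m
L3 = 0.006         # force-origin offset along the head-thorax axis, m
b1 = 0.005         # head-thorax semi-minor axis, m (drag cross-section)
b2 = 0.005         # abdomen semi-minor axis, m (drag cross-section)
h_wing = 0.028     # dorsal height of the wing-hinge force origin, m
kappa = 0.0023     # torsional spring constant, kg m^2 rad^-1 s^-2
eta = 3.0e-4       # torsional damping coefficient, kg m^2 rad^-1 s^-1
Cd = 1.0           # blunt-body drag coefficient, dimensionless
mu_a = 1.81e-5     # dynamic viscosity of air, Pa s
rho_a = 1.204      # air density, kg m^-3
g = 9.81           # gravitational acceleration, m s^-2
wrap_spring = true # spring acts on the wrapped flexion angle

[treatment]
actuation = "fa"           # one of fa | fs | ua | us
abdomen = "regular"        # regular | reduced
mass_scale = 0.1           # abdomen mass multiplier for the reduced abdomen
scale_inertia = true       # also scale I2 for the reduced abdomen

[efforts]
F_max = 0.443              # maximum aerodynamic force magnitude, N
alpha_min = 0.0            # force direction lower bound, rad
alpha_max = 6.283185307179586  # force direction upper bound (2 pi), rad
tau_abdo_max = 0.01        # maximum abdominal joint torque magnitude, N m
tau_wing_max = 0.01        # maximum wing torque magnitude, N m
signed_torques = true      # torque draws carry a random sign

[control]
window = 0.020             # control-window duration, s
advance_fraction = 0.25    # fraction of the selected path traversed
n_realizations = 2500      # Monte-Carlo draws per window
total_time = 10.0          # simulated duration, s
output_step = 0.0005       # dense-output grid step, s
seed = 0
# Loss weights w1..w6 on (x, y, theta, xdot, ydot, thetadot) deviations.
# Inverse-square tolerances: 1 mm in position, 0.05 m/s in velocity,
# 0.05 rad in theta, 1 rad/s in thetadot; position is penalized hardest.
weights = [1.0e6, 1.0e6, 400.0, 400.0, 400.0, 1.0]

[goal]
# Vertically oscillating target: eleven sines at prime multiples of 0.1 Hz
# with 1/f amplitude decay (constant per-component velocity amplitude).
frequencies = [0.2, 0.3, 0.5, 0.7, 1.1, 1.3, 1.7, 1.9, 2.3, 2.9, 3.7]
amplitudes = [0.01, 0.0066666667, 0.004, 0.0028571429, 0.0018181818, 0.0015384615, 0.0011764706, 0.0010526316, 0.0008695652, 0.0006896552, 0.0005405405]
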