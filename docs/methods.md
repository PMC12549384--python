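# Methods

## The suction-pressure model

During suction filling the lower punch is pulled down a height h_ppd while
the die sits under the feed frame. The cavity of cross-section A_die and
height h₀ + h(t) (h₀ is the punch position on entry — 0 for a conventional
fill cam, the 4.7 mm pre-pull for a stearate cam) expands at the punch
velocity v(t). Treating the in-die air as an ideal, isothermal gas and the
powder bed above the die as a Darcy porous layer of height L and
permeability K, the mass balance d(pV)/dt = R·T·dn/dt with Darcy inflow
dn/dt = K·A_die·ρ_air/(η_air·L·M_air)·(p_atm − p) reduces, after dividing
by A_die, to a single scalar ODE:

    dp/dt = [c·(p_atm − p) − p·v(t)] / (h₀ + h(t)),
    c     = R·T·K·ρ_air / (η_air·L·M_air)   [m/s].

Assumptions: ideal gas; isothermal; constant bed height over the die; no
powder enters the die during pull-down; no leakage through the punch–die
gap; ρ_air fixed at its ambient value (air enters through the bed), which
is what makes c a constant. With the ideal-gas-consistent density
ρ_air = p_atm·M_air/(R·T) the constant collapses to c = K·p_atm/(η_air·L),
removing one free parameter.

For constant v the ODE has the fixed point p* = c·p_atm/(c + v), i.e. a
stationary suction pressure Δp* = p_atm·v/(c + v): Darcy inflow balances
cavity expansion. Two analytic limits anchor the tests: K = 0 (sealed bed)
conserves p·(h₀ + h) (Boyle's law for the trapped pocket), and c → ∞
(perfectly permeable bed) gives Δp → 0.

### Numerics

The equation is stiff near t = 0 for conventional cams, where the cavity
height → 0 and the local rate constant (c + v)/(h₀ + h) diverges.
Integration therefore starts at t_start = 10⁻⁶ s with p = p_atm (the same
offset is applied to stearate cams for uniformity) and uses the implicit
Radau IIA method of order 5 (`scipy.integrate.solve_ivp`, analytic
Jacobian), default tolerances rtol = 10⁻⁶, atol = 10⁻⁸. The output grid is
300 points evenly spanning [t_start, filling time]. Against a reference
solution at 10⁻¹²/10⁻¹⁴ the relative error in peak Δp stays below 0.1%
over every material × machine × cam × turret-speed scenario (the
acceptance script measures ~10⁻⁵ %). Because the ODE is linear in p, an
independent fixed-step oracle uses the closed-form backward-Euler update
at dt = 10⁻⁶ s — explicit one-step methods are unstable during the initial
transient of conventional-cam scenarios — and agrees with Radau within
0.5% in peak Δp. A small numerical subtlety: starting at t_start means the
sealed-bed invariant is p·(h₀+h) = p_atm·(h₀+h(t_start)), which differs
from p_atm·h₀ by ~4×10⁻⁶ relative; tests check the exact conserved form.

Solutions are post-checked against 0 ≤ Δp ≤ p_atm and clipped only within
solver tolerance of those bounds. Reported rise times (first time Δp
reaches 90% of its peak) are linearly interpolated between output samples;
on the conventional rotary cam the buildup is effectively instantaneous
(µs scale), so rise-time comparisons between materials are meaningful only
for buffered (stearate) or accelerating (simulator) scenarios.

## Kinematics

On the rotary press the punch is guided by the turret down a linear cam
slope: the pull-down sector θ_ppd gives t_ppd = θ_ppd/(360·n_t) and
v = h_ppd/t_ppd, constant. θ_ppd is not a published machine constant; the
package defaults to 72° and treats it as configuration — every kinematic
quantity is linear in it, so results should always be read alongside the
assumed angle.

On the compaction simulator the punch starts at rest, accelerates to a
stationary velocity and decelerates to stop exactly at the filling height.
The profile is piecewise second-degree polynomial: quadratic ramps with
v = 0 at the endpoints, continuous at the plateau, with a shared shape
parameter solved in closed form so the displacement integrates exactly to
h_ppd — hence the full-stroke average velocity equals h_ppd/t_ppd, the
rotary linear velocity, by construction. Defaults (acceleration and
deceleration each 30% of the stroke, stationary velocity 1.4× the mean)
were chosen once to reproduce the qualitative machine behavior: pull-down
time matching the rotary press, stationary velocity well above the rotary
value. Requested profiles whose plateau velocity would force a ramp
negative are rejected as infeasible rather than silently reshaped.

Report analysis mirrors what one does with real instrumentation exports:
the stationary window is the maximal contiguous run of samples at ≥ 95% of
the per-report maximum velocity (the threshold is configuration; "stationary"
has no instrument definition), mean and sd are taken over that window, and
acceleration/deceleration are OLS slopes of v(t) on the segments before and
after it. Windows shorter than 3 samples are errors; missing ramp segments
are flagged rather than fabricated. Per-report means are pooled with the
inverse-variance weighted mean μ_w = Σ(μᵢ/σᵢ²)/Σ(1/σᵢ²) and weighted sd
σ_w = (Σ1/σᵢ²)^(−1/2). Note the 95% window necessarily includes the flat
tails of the ramps, biasing the recovered plateau low by ~0.2% for the
default profile shape — well inside the pooling uncertainty at ten reports.

## Materials and filling yield

Material constants (particle sizes, bulk/tapped/particle density,
permeability at 1 kPa normal stress) are stored in the units practitioners
print them in (µm, g/cm³, m²) and converted to SI where physics is
computed. The packaged table carries the three study blends: DCP
(free flowing, K = 5.20×10⁻¹² m²), MCC (easy flowing, 4.62×10⁻¹²) and LAC
(cohesive, 5.61×10⁻¹³). The rheometer permeability protocol applies two
volume flows (0.4 and 0.6 L/min) to the same bed; the bed permeability is
the mean of the two per-flow Darcy estimates, the simplest unbiased
aggregation. ffc is computed per pre-shear level; no flow-function
regression across levels is attempted.

The filling yield ϕ = m_t/(π·r_die²·h_d·ρ_b) uses bulk density as the
reference because the actual in-die density is unknown; ϕ > 1 flags
overfilling (in-die densification). Weight dispersion is reported as
percent relative standard deviation, the pharmacopoeial convention, and
since ϕ is linear in weight, the RSD of ϕ equals the RSD of the weights.

## Air properties

The reference values of the air constants are not published with the
study, so the package defaults to standard ambient air: T = 293.15 K,
p_atm = 101325 Pa, M_air = 0.02896 kg/mol, η_air = 1.8×10⁻⁵ Pa·s,
R = 8.314 J/(mol·K), ρ_air ideal-gas consistent (≈ 1.20 kg/m³; enforced
within 1%). All are overridable per scenario.

## Synthetic data

No raw instrumentation reports or tablet weights are published, so the
generator produces both with known ground truth. Punch reports are the
scenario's velocity profile sampled at 2000 Hz with white Gaussian
velocity noise (default sd 1% of the plateau) and a noiseless displacement
trace; autocorrelated noise and sensor quantization are deliberately not
modelled, so recovery tests demonstrate estimator correctness, not
robustness to real instrument artifacts. Tablet weights are Gaussian about
μ_ϕ × theoretical mass with fractional sd 1.5% (the weight-variation level
of a well-behaved material), where the ground-truth mean yield

    μ_ϕ = base_yield · (1 − s_dp·e^(−Δp_max/Δp_ref)) · (1 − s_sup·e^(−n_pass/n_ref))

saturates in the peak suction pressure (Δp_ref = 2000 Pa) and in the
number of paddle passes during the fill (n_ref = 1;
n_pass = paddle speed × filling time × spokes, 12 spokes on the rotary
press, 6 on the simulator). The exponential-saturation links are a
synthetic construct chosen for controllability, not a fitted yield model:
they echo the observed phenomenology (yield limited by suction for
low-permeability powders and by paddle supply at low paddle speeds) and
let every analysis stage be checked against known parameters. Passing
recovery tests therefore shows the pipeline is self-consistent at realistic
noise levels; it says nothing about bridging, jamming or feed-frame
residence-time effects, which have no stated model. All draws derive from
`numpy` generators seeded by (seed, stream, cell) integer tuples, so
datasets are byte-reproducible.

## Problem sizes

The full experimental design is 5 turret × 7 paddle speeds per
(machine, cam, material) block, n = 20 tablets per rotary cell and 10 per
simulator cell, and 10 reports per simulated turret speed — the analysis
scripts and tests generate these sizes directly, and the convergence sweep
covers all 24 material × machine × cam × {20, 60} min⁻¹ scenarios. The
fixed-step oracle is exercised on a representative five-scenario subset at
n_t = 60 min⁻¹, where a 10⁻⁶ s step means ~2×10⁵ updates per scenario.

## Known limitations

The ODE is a deliberately idealized single-physics model: it takes
permeability as the only material property, so it cannot discriminate
materials of similar K but different cohesion (DCP vs MCC), and it ignores
feed-frame geometry, powder ingress, punch–die leakage and thermal
effects. Rise times on conventional rotary cams are below the output-grid
resolution and should be read as "instantaneous". The stearate cam's 4.7 mm
pre-pull and the 6/11 mm bed heights are specific to the studied machines;
other tooling requires overriding the defaults.
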