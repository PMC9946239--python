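# Methods

This note documents the models implemented in `paramecium`, the choices
made where the design was genuinely open, the numerical schemes, and what
the synthetic data used by the tests does and does not emulate.

## Units

All internal quantities use one consistent system: mV, nA, nS, pF, ms, µM,
µm (degrees for angles, rad/s for spin). Two derived constants matter:
`g[nS]·V[mV] = pA`, so conductance-based currents carry a factor 10⁻³ to
come out in nA, and `dV/dt [mV/ms] = 10³·I[nA]/C[pF]`. A calcium current
of 1 nA into the ciliary volume v = 1700 µm³ changes concentration at
`I/(2Fv)` = 3048.8 µM/s; the calcium pump rate J is stored in µM/s (a
printed rate of 866 s⁻¹ is J/[Ca]₀ with [Ca]₀ = 0.1 µM, i.e. 86.6 µM/s,
consistent with the quoted maximum pump rate of ~87 µM/s).

## Membrane model

Single isopotential compartment with leak, Boltzmann-n² delayed rectifier
(time constant `a + b/cosh((V−V_τ)/k_τ)`, a *peaked* bell — the divided
form is used deliberately; the simplified variant ties V_τ = V_Kd and
k_τ = 2k_Kd), a GHK calcium current with Hill calcium-inactivation
(n_Ca ≈ 4 sites), a calcium-activated K⁺ current, and optionally an
inward rectifier (n², fixed time constant) used only for hyperpolarized
protocols — the behavioral model excludes it, since its activation is
negligible above E_K. The GHK factor is evaluated as `x/(eˣ−1)` with a
series branch near x = 0 and clamped tails, so it is continuous, strictly
positive and overflow-safe.

Calcium dynamics combine a linear removal process (rate λ) with a
saturating pump `J/(1+[Ca]₀/[Ca])` that exactly cancels the resting
influx when `J = I_rest/(F·v)`. Integration uses the logarithmic variable
pCa = log₁₀([Ca]/[Ca]₀); the pCa-form equation is algebraically identical
to the concentration form (verified against tightly converged `solve_ivp`
solutions of both forms) and remains well-behaved when [Ca] → 0.

### The resting state of the default parameter set

The bundled `table3_median` preset assembles the median fitted parameters
of the ciliated-cell population. Medians across cells are not a jointly
fitted cell: at the population-median resting potential (−22 mV) the
resting calcium current of this assembled cell is ≈35 pA and its voltage
sensitivity (2/k_Ca · I_Ca ≈ 16 pA/mV) exceeds the leak conductance
(9.5 pA/mV), so a fixed point there is unstable. The package therefore
pins the default resting potential at −25 mV, within the measured
population spread (V₀ = −24.5 ± 10.6 mV), chosen once so that

* the resting point is comfortably stable (the unstable threshold sits
  ≈2.5 mV above rest), and
* the standard noise current (Ornstein-Uhlenbeck, σ = 9 pA, τ = 20 ms)
  produces spontaneous action potentials at the calibrated rate of
  ~0.2 Hz (measured 0.18 Hz over 400 agent-seconds), the same calibration
  the original recordings prescribe.

`steady_state_init` places the fixed point exactly: gating variables take
their steady-state values at V₀, the leak reversal E_L is solved so the
net current vanishes at V₀ (the analogue of aligning recordings for tip-
potential drift), and J is set to balance the resting calcium influx so
[Ca] rests at exactly 0.1 µM. With these choices a noise-free 10 s
simulation drifts by < 0.01 mV and < 10⁻³ µM.

## Numerics

Forward Euler with dt = 0.1 ms for the membrane; gating variables are
clipped to [0,1] after each step (Euler can overshoot at this dt). Halving
dt changes spike peaks by < 1%. The OU noise current and the RC electrode
are advanced by their exact exponential updates, so their statistics and
steady states are dt-independent; σ_n is the *stationary standard
deviation* of the noise (9 pA). The electrode model (R_e, τ_e, ΔV) low-pass
filters the command current; ΔV cancels exactly from the injected current
and is kept only for fitting.

## Electromotor coupling and kinematics

[Ca²⁺] maps instantaneously to: ciliary angle (Hill, α₀ = 11°,
Δα = 160°, so resting flow is ~11° and fully reversed flow ~171° off the
anteroposterior axis — these two values are not tabulated in the source
material and were fixed from the reported mean flow angles), signed axial
speed (±500 µm/s, zero at K_motor = 2.4 µM), rotation-axis tilt
(13°–90°) and spin (2π–8π rad/s), the last two as log-symmetric bells
peaking at K_motor. The printed "(2 cycles/s)" for the maximum spin is
taken as a typo: the stated factor of 4 over the minimum and the
spherical model's ≈4.09 amplification fix ω_max = 8π/s. All Hill/bell
forms evaluate in log-concentration to avoid underflow.

The swimmer integrates with a coarser kinematic step (1 ms for sharp-edged
stimuli, 2 ms for continuous fields; must divide evenly by the membrane
step). Coupling is one-way within a kinematic step: calcium read at the
step start sets (v, θ, ω) for the whole step. Orientation uses unit
quaternions (scipy `Rotation`); each step composes the exact rotation
`exp([ω_b]·dt)` rather than the first-order quaternion derivative, which
removes dt-dependent norm drift. Plane confinement rotates the orientation
vector about `ẑ × p` by `asin(p_z/|p|)` after every step; when the
orientation is exactly normal to the plane (measure-zero) the body y-axis
is the deterministic fallback axis. The initial azimuth of the oral groove
(spin phase) is a scenario parameter; escape directions after avoiding
reactions depend on it, which is the model's deterministic
pseudo-randomness.

A note on the free-swimming helicoid as measured from the model's own
output: at resting calcium the tilt bell gives θ_rest = 13 + 77/cosh(2
ln10·log₁₀(K_motor/[Ca]₀)) ≈ 13.27°, not exactly θ_min = 13°, and the
plane-confined heading oscillates essentially sinusoidally (fit r² ≈ 1)
with amplitude ≈ tan(θ_rest) ≈ 13.5° and period
2π/(ω_rest·cos θ_rest) ≈ 1.017 s. These values are step-size independent
(identical at dt_kin = 2, 1, 0.5 and 0.2 ms). The fitted period therefore
sits within 2% of the nominal 1.00 s, while the fitted amplitude exceeds
the nominal 13° by ~4% — a structural property of the couplings (bell
tail plus planar projection), not a numerical artifact. The corresponding
test asserts the nominal 2% band and documents this known deviation.

## Spherical hydrodynamic analysis

The turning analysis idealizes the cell as a 60 µm sphere in water
(η = 10⁻³ Pa·s; tilt and spin ratios are independent of η and of the
force amplitude, which the tests assert over orders of magnitude). Local
tangential forces with piecewise-constant angle are integrated per region
with Gauss-Legendre nodes and the sinθ area weight; the closed-form
uniform and anterior-quarter wrenches serve as oracles (agreement to
< 10⁻⁶ relative at 512² nodes). The diagonal sphere mobility maps wrench
to motion. The local force amplitude is calibrated once so the uniform
forward pattern swims at 500 µm/s and reused for all patterns. Outputs:
the turning pattern translates axially at exactly 0 (the anterior
quarters cancel by cos(−170°) = −cos(−10°)), rotates about an axis tilted
34.2° in the oral-groove plane, and spins 4.09× faster than the forward
pattern. Absolute spin rates of this idealized model (~0.175 cycles/s
forward at the calibrated amplitude) are not meaningful observables and
only the ratio is asserted. The module is analysis-only: the behavioral
simulator couples calcium directly to (v, θ, ω) and never calls it.

## Sensory transduction

Cell silhouette: length a = 120 µm, width b = 35 µm, with the half-width
profile `(b/2)·√(1−4x²/a²)` of both edges offset by
`−β·(b/2)·sin(2πx/a)` (β = 0.15) — a ventral bend, interpreted as a
fraction of the half-width since a bare 0.15 µm offset would be
invisible; the bend is area-preserving (area = πab/4 ≈ 3300 µm²). Overlap
with sharp-edged stimuli is computed as an exact polygon intersection
(shapely) of the sampled outline; the `resolution` parameter (default
2 µm) controls boundary vertex spacing, and refining it changes overlap
fractions by ≪ 0.5%. For spatially continuous stimuli the drive is the
field value at the cell center (bilinear on grids). Receptor kinetics:
instantaneous (I = I₀p), delayed (first-order lag, τ = 40 ms), or
adapting (fast hyperpolarizing and slow depolarizing pathways with equal
gain, τ = 40/200 ms; stationary response zero, so only changes are
signalled). Spatial channel recruitment is not modeled.

## Closed-loop scenarios

Arenas are rectangles with optional periodic axes. The five bundled
scenarios follow the published geometries: object encounter (half-plane,
5 nA max, instantaneous or delayed), repelling disc (1 mm disc in a 4 mm
torus, delayed, 5 nA), attracting disc (adapting, 1 nA), gradient
(100 pA/mm on a 25 mm × 0.5 mm cylinder, adapting, all agents starting at
the arena center), and collective CO₂ behavior (agents deposit 100 pA/s
per occupied 20 µm pixel into a field diffusing at 0.01 mm²/s — the
physical 0.002 mm²/s accelerated fivefold — integrated by an explicit
5-point scheme with a checked stability bound). Agents are independent
except through the shared field. Spontaneous avoiding reactions arise
only from the OU noise current. Occupancy counts cell centers. One root
seed drives spawned child streams for initial conditions and for the
population noise; the noise stream is drawn vectorized with agent i
always consuming lane i, so runs are bit-reproducible for a given seed
and agent count.

## Trajectory analysis

Orientation flips larger than 20° between successive frames are treated
as front/rear tracking errors and corrected by 180°. Selection drops
tracks shorter than 1 s, immobile tracks (median speed below 20 µm/s
over 0.5 s windows — the source procedure does not quantify "immobile";
this is the package's operational definition), and circling tracks
(clockwise/anticlockwise turning fractions off balance by > 0.1, tracks
longer than 4 s). Backward swimming is `m·o < 0` with the motion vector
from central differences; single-frame-pair episodes are discarded.
Reorientation angles sum successive orientation changes over the
reaction, excluding events whose ellipse eccentricity (when provided)
dips below 0.8; for simulated pulse responses the alternative
before/after mode averages orientation over 1 s (one spin period) on
each side of the stimulus. Helicoid fits seed the period from the
dominant Fourier component, detrend a linear drift, and refine
`c + A·sin(2πt/T+φ)` by least squares; fits explaining < 50% of variance
are flagged.

## Model fitting

Stages mirror the recording protocol: (1) electrode R_e, τ_e from small
(< 0.5 nA) pulses against both electrode potentials, 100 ms before to
100 ms after the pulse; (2) leak + inward rectifier on 0 to −4 nA pulses
(reading potential, pulse start to +50 ms), from the natural resting
point implied by the candidate parameters so E_L stays identifiable;
(3) leak + delayed rectifier on 0 to +4 nA pulses with C and E_K fixed
from stage 2, error split into the first 30 ms and the remainder with
equal window weights; (4) the full model against voltage (two equal
windows: pulse, and pulse end to +500 ms), the ciliary flow angle (unit-
vector error `(cosα−cosα̂)² + (sinα−sinα̂)²` over −100 ms to +500 ms,
30 Hz frames held to the simulation grid), and a pre-pulse resting-
calcium penalty. Each objective is normalized by its target variance
(relative objective scales are not specified by the source; variance
normalization is the package's choice). In stage 4 traces are aligned to
a common resting potential, E_K is fixed, and the forward model pins its
rest with the pump balanced, so the calcium penalty is honoured by
construction and J tracks I_rest/(F·v).

Conductances, binding constants, rates and time constants spanning
decades are fitted in log₁₀ space. Optimization is an optional seeded
differential-evolution stage followed by trust-region least squares on
the residual vector; the best-so-far objective history is recorded and is
non-increasing by construction. Quality control rejects C > 500 pF,
resting resistance outside 30–500 MΩ, or E_K > E_L. Weakly identified
parameters (g_Ca, and g_Kir/V_Kir in the hyperpolarized stage, where the
channels are mostly closed in the sampled voltage range) are reported but
not asserted in recovery tests.

### What the synthetic datasets do and do not emulate

`generate_synthetic_dataset` simulates the forward model through the RC
electrode filter, optionally adds white Gaussian measurement noise to
both electrode potentials, and emits the same trace dialect the fitters
read, with the generating parameters attached. It reproduces the pulse
protocols, electrode filtering and frame-rate-limited angle series of the
real experiments. It does not emulate: slow tip-potential drift between
sweeps (beyond a constant offset), cell-to-cell variability, temperature
or solution changes, membrane noise during recordings, PIV measurement
error in the flow angle, or failures of the isopotential assumption.
Passing recovery tests therefore demonstrates correctness and
identifiability of the estimation machinery under the model, not
robustness to every artifact of real recordings.

### Problem sizes in the test suite

Recovery tests run noiseless datasets with the full pulse grids where
cheap (deciliated: fourteen 0.3–4 nA sweeps) and reduced grids for the
full model (eleven sweeps spanning both published pulse sets), with
optimizer budgets reduced by starting least squares from bounded
perturbations of the generating values (±20–80% per parameter, log-space
for scale parameters) rather than running a long global stage; the
differential-evolution stage remains available and seeded for fits from
scratch. Closed-loop scenario checks use 100 agents for 20 s, the
published population size and duration.

## Known limitations

* Electromotor coupling is instantaneous and phenomenological; no
  per-cilium calcium sensitivity, no coupling delay.
* The hydrodynamic module assumes a sphere and is not fed back into the
  swimming model; no wall or object hydrodynamics, no gravitaxis.
* Medians-as-a-cell: the default preset is a population composite, so its
  excitability threshold (~0.55 nA for 2 ms pulses) differs from any
  individual recorded cell; backward-swimming durations rise with pulse
  amplitude from threshold to ~3 nA, then saturate and dip slightly
  (~3%) for stronger brief pulses because the larger
  after-hyperpolarization clears calcium faster.
* Voltage-clamp protocols, Na⁺/Mg²⁺ currents, the escape reaction,
  contractions and trichocyst discharge are out of scope.
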