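# Methods

## Flight model

The glider is a point mass with quasi-steady aerodynamics in a horizontally
homogeneous, time-invariant shear wind blowing from north to south
(velocity (0, −W(z))). States are airspeed U, air-relative pitch γ and yaw ψ
(from the +x/East axis, positive toward +y/North), and position (x, y, z);
controls are the lift coefficient C_L and roll angle φ. Lift and drag are
L = ½ C_L ρ S U², D = ½ C_D ρ S U² with the parabolic polar
C_D = C_D0 + C_L²/(π e Λ).

The yaw equation is written with the airspeed U on the left-hand side,
m U ψ̇ cos γ = L sin φ + m σ ż cos ψ: this is the dimensionally and
Galilean-consistent form (the ground-speed variant would break the
energy-rate identity Ė = m g ż + m U U̇ = ½ m σ U² sin 2γ sin ψ − D U that
the whole coefficient framework rests on, and the minimum-wind validation
value only reproduces under the airspeed form). That identity is enforced in
tests to 1e-10 relative at 1000 random states.

### Glider parameters

The classical wandering-albatross parameter set used across the
dynamic-soaring optimization literature:

| parameter | value | unit | note |
|---|---|---|---|
| m | 8.5 | kg | |
| S | 0.65 | m² | wing area |
| Λ | 18.21 | – | aspect ratio b²/S, b = 3.44 m |
| C_D0 | 0.033 | – | |
| e | 0.92 | – | span efficiency → k = 1/(π e Λ) ≈ 0.019 |
| ρ | 1.225 | kg/m³ | |
| C_L ≤ 1.5, n ≤ 3, z ≥ 0.5 m | | | operational limits |

The span efficiency deserves a note. A pure lifting-line polar (e = 1,
k = 0.0175) yields a minimum soarable wind of 8.24 m/s in the validation
configuration; the classical polar C_D = 0.033 + 0.019 C_L² (best glide
ratio ≈ 20) yields 8.58 m/s with a 7.02-s period, matching the published
validation values (8.57 m/s, 7.00 s) to 0.2%. We therefore ship e = 0.92 as
the default; it is configuration, not a constant.

### Wind profiles

Logarithmic: W(z) = W_ref log(z/h₀)/log(h_ref/h₀) with h_ref = 10 m and
h₀ = 0.03 m (open sea); shear σ(z) = W_ref/(log(h_ref/h₀) z); mean shear
σ̄ = W_ref/(h_ref−h₀), the exact height average of σ over [h₀, h_ref].
Sigmoid: W(z) = W_ref/(1+e^(−z/h_ref)) with h_ref = 1 m by default, for
wave-shadow conditions; σ̄ is not defined for it. Raw profile operations
raise below their domain; only integration utilities clamp (W → 0, σ → σ(h₀)
below h₀), so analysis code can never silently extrapolate.

## Trajectory optimization

Hermite–Simpson direct collocation on N intervals (default N = 50 uniform;
non-uniform grids supported). Decision variables: states and controls at the
N+1 nodes, the period T ∈ [2, 20] s, and W_ref ∈ [2, 20] m/s in minimum-wind
mode. Constraints: 6N defect equalities; cycle closure in U, γ, ψ, z
(positions deliberately free); optionally the direction constraint
implemented as Δx cos θ − Δy sin θ = 0 plus forward progress
Δx sin θ + Δy cos θ ≥ 1 m (equivalent to tan θ = Δx/Δy with the correct
quadrant); load factor n = L/(m g) ≤ 3 at every node; bounds z ≥ z_min,
0 ≤ C_L ≤ 1.5, |φ| ≤ 80°, |ψ| ≤ 180°, |γ| ≤ 75° (technical bounds; the
pitch/roll bounds do not bind at the validated minimum-wind optima, though
the roll bound does bind in strong wind).

The NLP is solved with SLSQP using analytic objective and constraint
Jacobians (hand-derived, verified against finite differences to ~1e-9) and
diagonal variable/constraint scaling. The problem is non-convex, so each
solve runs a small multistart (default 5) of parameterized climbing-diving
seed cycles — sinusoidal γ and ψ at plausible amplitudes, T₀ = 6 s, mean yaw
aimed so the seed's displacement matches the requested direction — with
seeded perturbations; sweeps additionally warm-start each wind level from
the previous solution. Feasibility is declared at a scaled constraint
violation ≤ 1e-6; solutions are post-verified by replaying the optimal
controls (piecewise linear, the Hermite–Simpson convention) through an
independent RK4 integration (≤ 1% RMS at the nodes) and by cycle energy
closure (|E(T) − E(0)| ≤ 1e-3 of mean |E|).

`minimum_wind_speed` treats W_ref as a decision variable; an optional
cross-check bisects fixed-wind feasibility to 0.05 m/s. "Infeasible from all
starts" in fixed-wind mode is reported as below-minimum-soarable wind.

Numerical sizes used in the shipped tests and acceptance script: N = 50 for
the minimum-wind validation runs, N = 40 for the directional bounds and the
trade-off sweep (the objective moves by < 0.5% between N = 25 and N = 50).

### A note on the sweep trends

Over the feasible wind range η̄ is strictly decreasing in σ̄ for all travel
directions. ε̄ rises steeply from the feasibility bound but peaks near
W_ref ≈ 13–14 m/s and then declines by 1–3% toward 20 m/s at every travel
direction; cold multistarts with varied amplitudes, turn directions and
periods and warm continuation all converge to the same optima, and widening
the roll bound does not change the shape, so we report this plateau-and-dip
as a genuine property of the model optimum rather than forcing a monotone
reading. The dominance-interval counts (how often η exceeds ε within a
cycle) are local-optimum sensitive and are reported as warnings, not
asserted.

## Track pipeline

Implements the ground-speed-sinusoid wind estimation for 1-Hz positions:
local equirectangular projection about the track centroid (warning above a
2° span); 300-s segments; per-sample ground velocity and bearing
θ_V ∈ [0°, 360°); OLS fit V_h = V̄_h + a sin θ_V + b cos θ_V;
W₀ = √(a²+b²) (identically half the fitted max−min), tailwind bearing
θ_W = atan2(a, b) stored as the blowing-toward direction; calibration
W_ref = 1.80 W₀ − 1.42 (segments with W_ref ≤ 0 discarded);
σ̄ = W_ref/9.97 1/s. Air-relative yaw per sample from the wind triangle,
U_h² = V_h² + W_ref² − 2 V_h W_ref cos(θ_V−θ_W) and
ψ = asin(V_h/U_h sin(θ_V−θ_W)), principal branch (samples whose true angle
lies beyond ±90° are retained with the clamped branch and counted in
diagnostics). Pitch is never observed at 1 Hz and is imputed with the linear
map γ = l(θ)ψ − m(θ), l = 0.00309 θ + 0.02, m = 0.00427 θ − 0.47 — all three
angles in degrees (the map's units are ambiguous in its source; degrees keep
l(θ)'s θ ∈ [60, 120] self-consistent, and a radian variant is switchable).
θ = |θ_V − θ_W| folded to [0°, 180°] is computed per sample and the
crosswind filter 60–120° applied per sample; the calibration is applied
before the filter. Segment quality gates (config-exposed, logged per
rejection): ≥ 150 valid samples of 300, circular bearing span ≥ 90°, fit
RMS ≤ 5 m/s.

Trend analysis: Gaussian linear mixed model, coefficient ~ σ̄ with a random
intercept per individual (REML, statsmodels); on a singular or
non-converging random-effects fit, or a single individual, it falls back to
pooled OLS with a logged `model` flag.

## Synthetic cohort generator

The kinematic source emulates a 4-individual campaign: per individual, five
constant-wind blocks with W_ref from 8 to 20 m/s, random wind bearing and a
travel direction drawn from 70–110°, 1500 s per block (2.1 h, 25 windows per
bird), 1-m i.i.d. Gaussian position jitter. The ground-track bearing
meanders with a cycle-scale sinusoid (8-s period; amplitude 75° at 8 m/s
shrinking to 45° at 20 m/s — strong shear affords straighter cycles — with a
per-individual amplitude factor ~N(1, 0.05) injecting the heterogeneity the
mixed model exercises) plus a slow 25°/100-s course wander, and the ground
speed follows the tailwind-component law the estimator assumes,
V_h = 16 + W_felt cos(θ_V−θ_W).

Two deliberate idealizations: (i) the felt wind is the calibration inverse
(W_ref+1.42)/1.80 — the published calibration constants cannot be re-derived
without the original tracking data, so the emulator presents data for which
that correction is exact, and recovery error then measures the estimator
itself (exact at zero noise; ≤ ~6% per window at 1-m noise); (ii) position
noise is i.i.d. (no GPS autocorrelation). Passing tests therefore show the
pipeline is unbiased and correctly signed on data satisfying its own
assumptions — not that the calibration is correct for real albatross tracks.
The trade-off trend signs recovered from the cohort (η̄ down, ε̄ up with σ̄)
arise from wind-triangle geometry (stronger wind drift lowers the apparent
|ψ|), not from the injected meander schedule alone.

The `optimized` source replays a tiled max-net-speed collocation solution
rotated into the requested wind frame. It is model-faithful but the
published calibration does not transfer to it: ideal cycles have a strong
airspeed–heading correlation that inflates the ground-speed sinusoid
(W_ref ≈ 16.8 estimated at a true 10 m/s), and their ground-bearing span
(~82°) sits below the default coverage gate. It is therefore used for
geometry, determinism and rank-correlation checks, with the kinematic source
as the default for recovery and trend tests.

## Known limitations

* The optimizer finds local optima; multistart and continuation make results
  reproducible under a fixed seed but carry no global-optimality guarantee.
* Single-cycle periodicity is assumed; wind regimes whose optimal behavior
  is a two-cycle pattern (sigmoid profile, near-upwind travel) are out of
  scope and would appear as infeasibility or a one-cycle compromise.
* No flapping thrust: winds below the feasibility bound are reported
  infeasible although real birds soar there by mixing in flapping.
* The γ imputation map is calibrated at W_ref = 10 m/s and inherits that
  regime; imputed η̄ magnitudes are systematically higher than
  trajectory-level truth (rank correlation ≈ 0.9, no level agreement
  expected or asserted).
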