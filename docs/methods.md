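# Methods

## Model

The package implements the minimal mass-action oscillator for biofilm
metabolism: three concentrations (mmol l⁻¹) on an hourly time scale,

    dGp/dt = k1·G_E·Gp − k4·Gp − k2·A·Gp
    dA/dt  = −k3·A + k5·Gi
    dGi/dt = k4·Gp − k5·Gi

with a single bilinear term (`k2·A·Gp`). `Gp` is peripheral glutamate, a
proxy for the periphery's amino-acid/protein pool — hence the
self-amplifying uptake `k1·G_E·Gp` (more transporters, more uptake). `Gi`
is interior glutamate, fed by diffusive transfer `k4·Gp`; `A` is ammonia,
produced from interior glutamate at rate `k5·Gi` (glutamate dehydrogenase)
and lost to the surroundings at rate `k3·A`. The loop `Gp → Gi → A ⊣ Gp` is
a delayed negative feedback; together with the weak linear positive
feedback of `Gp` on itself it sustains a limit cycle. Biomass is a passive
readout, `dB/dt = b·A·Gp·B` (cells l⁻¹).

Modelling assumptions worth keeping in mind: `G_E` is constant (excess
supply); ammonia made in the periphery is lost instantly (so `k2·A·Gp` does
not appear in the `A` balance); diffusion is irreversible; growth kinetics
are trilinear rather than saturating. A variant flag replaces `k4·Gp` by
`k4·Gi·Gp` in both equations where it appears (self-amplified import); all
closed forms below refer to the baseline variant unless noted.

## Parameters

| name | default | unit | meaning |
|------|---------|------|---------|
| k1   | 0.3426  | (mmol l⁻¹ h)⁻¹ | glutamate uptake by the periphery |
| k2   | 5.3     | (mmol l⁻¹ h)⁻¹ | biomass formation (A + Gp consumption) |
| k3   | 4       | h⁻¹  | ammonia loss to the surroundings |
| k4   | 2       | h⁻¹  | periphery → interior glutamate transfer |
| k5   | 2.3     | h⁻¹  | ammonia production from interior glutamate |
| G_E  | 30      | mmol l⁻¹ | external glutamate concentration |
| b    | 0.1     | ((mmol l⁻¹)² h)⁻¹ | biomass conversion factor |

`k3 ≈ 2·k4` reflects the roughly twofold higher diffusivity of ammonia over
glutamate. The defaults are the published reference parameterization of
this oscillator for biofilms and are used verbatim; in particular k1 is
kept at 0.3426 even though the published bifurcation thresholds (5.88,
24.41 mmol l⁻¹) correspond to k1 rounded to 0.34 — the package computes
5.8377 and 24.2265 from the defaults and documents a 1% comparison
tolerance rather than altering k1.

## Steady states, stability, bifurcations

With `k = k1·G_E − k4`, the non-trivial steady state is

    Gp_ss = k·k3/(k2·k4),  A_ss = k/k2,  Gi_ss = k·k3/(k2·k5)

— linear in `G_E` and positive iff `k > 0`. Below that transcritical
threshold (`G_E = k4/k1`) the origin is the attractor; the non-physical
branch is still returned, flagged, so diagram scans can follow it through
the crossing. The NTSS Jacobian has characteristic polynomial
`λ³ + (k3+k5)λ² + k3·k5·λ + k·k3·k5`; the Routh–Hurwitz boundary gives the
Hopf condition `k = k3 + k5`, i.e. `G_E = (k3+k4+k5)/k1`, with onset
frequency `ω = √(k3·k5)`. Eigenvalues are always computed from exactly
assembled characteristic-polynomial coefficients (trace, principal minors,
determinant) rather than from a generic eigensolver, which keeps the
node/focus distinction stable near the real↔complex transition; a complex
part or a zero real part is only declared beyond a 1e−9 relative tolerance,
and boundary cases are classified "degenerate" instead of being forced into
a generic class.

`hopf_point_numeric` generalizes the threshold to any rate constant by
bracketing the zero of the complex-pair real part at the NTSS (Brent's
method, parameter tolerance 1e−8 relative); it reproduces the closed form
for `G_E` and yields e.g. k5 = 4.278 h⁻¹ and k3 = 5.978 h⁻¹ for the
defaults.

Diagram scans vary exactly one parameter over a sorted grid (≥ 10 points).
Per grid point the branch comes from the closed form and the oscillation
envelope from simulation. The discarded transient adapts to the leading
oscillatory decay/growth rate — about six e-folding times of |Re λ|,
clipped to [10 h, 150 h] — because near the Hopf point relaxation is
critically slowed and a fixed window either leaks transient into the
envelope or truncates the emerging cycle; 25 h (≳ 10 cycles) of signal are
always retained. Envelope runs start from a 5% perturbation of the NTSS
(when positive) so the measured width reflects the attractor rather than
the approach from an arbitrary distant state. Integration failures at a
grid point are recorded in the output and the scan continues. k1 is not
offered as a preset scan axis in the CLI because it acts only through
`k1·G_E`; the library engine accepts it.

## QSSA reduction

Eliminating fast `Gi` (overexpressed glutamate dehydrogenase, large k5)
slaves it to `Gi = (k4/k5)·Gp` and leaves a two-variable system whose
non-trivial state coincides with `(Gp_ss, A_ss)` and whose eigenvalues are
`−k3/2 ± √(k3²/4 − k·k3)`. Three regimes follow: (a) `k < 0` saddle,
(b) `0 < k < k3/4` stable node, (c) `k > k3/4` stable focus. Because a
two-variable mass-action system with at most bilinear terms cannot sustain
a limit cycle, case (c) — damped oscillations — is the strongest behaviour
the reduced model allows: the positive feedback of `Gp` explains
oscillation, but the third variable's delay is what inflates it into a
limit cycle. The analogous elimination of `A` (slave `A = (k5/k3)·Gi`) is
provided mechanically. Regime boundaries within 1e−9 (relative, on the
discriminant) are reported "degenerate".

## Simulation and cycle statistics

`simulate` wraps LSODA (adaptive stiff/non-stiff) with the analytic
Jacobian, rtol 1e−8 / atol 1e−10, dense output on a fixed grid (default
25 h in 0.025 h steps). Tiny negative excursions (≥ −1e−9) are clipped to
zero; larger ones, solver failures, and divergence beyond 1e6 mmol l⁻¹
(used to cut off unphysical parameter draws during calibration) raise an
error carrying the failing time. Default initial conditions are
(1, 1, 1) mmol l⁻¹; limit-cycle statistics are attractor properties and
IC-independent, which the tests verify.

Oscillation summaries discard a transient (default 10 h), detect strict
local maxima of ammonia on the grid, refine each peak time with a parabola
through the three bracketing samples (sub-grid accuracy; plateau ties take
the leftmost sample), and report the mean inter-maximum interval as the
period. Amplitudes are peak-to-trough (max − min) per variable over the
retained window — the only definition consistent with a `Gp` swing of
~14.9 mmol l⁻¹ around a ~3.1 mmol l⁻¹ mean. Averages (including the `A·Gp`
product) are trapezoid means between the first and last detected ammonia
maximum, i.e. over an integer number of periods. Runs with fewer than
3 maxima or ammonia amplitude below 1e−6 are reported non-oscillatory, with
whole-window means as a fallback.

**Average equality.** Dividing the `Gp` equation by `Gp` and integrating
over one period shows `⟨A⟩ = A_ss`; the linear equations likewise give
`⟨Gi⟩ = Gi_ss`, `⟨Gp⟩ = Gp_ss`, and combining them, `⟨A·Gp⟩ = A_ss·Gp_ss`.
The tests verify all four to 0.1% on a 60 h run with a 30 h transient (the
spectral decay rate of ~0.5 h⁻¹ toward the cycle leaves a ~0.1% bias after
only 10 h, so the long window is needed for this sharp a check). A direct
consequence: on the attractor, biomass grows exponentially at rate
`b·A_ss·Gp_ss` between consecutive ammonia maxima, so the doubling time is
`ln 2/(b·A_ss·Gp_ss) = 1.4207 h` at the defaults. The doubling-time
estimator takes the first four ammonia maxima after the transient
(requiring at least five in the window), averages the per-interval
exponential rates `ln(B(t_{i+1})/B(t_i))/Δt`, and is exact for any purely
exponential biomass curve.

**Known period discrepancy.** The published description of this
parameterization quotes an oscillation period of about 126 min. The
attractor period computed here is 140.0 min (stable to <0.02% between 50 h
and 200 h, identical under tolerance halving, and confirmed with an
independent integrator). The printed amplitudes (3.0 / 7.1 / 14.9 mmol l⁻¹)
do match the attractor, so the parameters themselves are not in doubt; the
first inter-peak interval from (1, 1, 1) is 125 min and the near-Hopf
eigenfrequency gives 2π/√(k3·k5) = 124 min, so the shorter quoted period
evidently reflects the early transient rather than the converged cycle.
The package reports what it computes; the CLI `reproduce` report marks the
period row as failing its documented tolerance.

Growth-curve comparison against the hypothetical steady-state growth
`B0·exp(b·A_ss·Gp_ss·t)` is provided as a utility with caller-supplied
`B0`: the published baseline for that comparison mixes two incompatible
initial values, so no fixed default is meaningful.

## Synthetic observations

The generator emulates microfluidics-style fluorescence time series:
simulate, subsample on an exact grid multiple of the integration step
(default 0.1 h, ~17 samples per period), add independent zero-mean Gaussian
noise per observation, clip at zero (reporting the clipped fraction).
Additive Gaussian noise is the simplest defensible observation model for a
fluorescence proxy; it ignores photobleaching, shot-noise scaling with
intensity, and missing frames, so recovery results bound what is achievable
under idealized noise, not microscope reality. One root seed spawns one
substream per variable in the fixed (Gp, A, Gi) order, making datasets
bit-reproducible and independent of which variables are observed.

## Calibration

`TrajectoryCalibration` minimizes the summed squared residuals between the
observations and a simulation started from the first observation (the
initial state is not fitted by default, keeping small-n problems
well-posed; it can be overridden). Concentrations are fitted directly, not
log-transformed — they span only about one order of magnitude. Box bounds
are mandatory (default 0.1–10× the caller's starting values) and k1 and
G_E may never be simultaneously free, since only their product enters the
dynamics.

Optimization is multi-start bounded least squares (trust-region
reflective). Starting points are log-uniform draws within the bounds (rate
constants live on a ratio scale). Each restart solves a progression of
problems on growing prefixes of the record — 10%, 30%, 60%, then 100% of
the observation times, warm-started in sequence. The short first window
covers the initial transient but less than one oscillation period, so its
fit landscape lacks the phase-mismatch local minima that trap full-window
fits of oscillatory data; the full-window stage then sharpens the estimate.
The restart with the smallest full-record residual sum of squares wins.
Infeasible parameter draws (diverging integrations) return large constant
residuals so the optimizer steps away instead of aborting. Standard errors
come from the Gauss–Newton covariance `σ²(JᵀJ)⁻¹` with `σ² = RSS/(n−p)`.

At the reference conditions (σ = 0.1 mmol l⁻¹ noise, 0.1 h sampling for
25 h, three free parameters k1/k2/k5, six restarts) the median recovery
error across ten seeded replicates is ~1% per parameter, with worst cases
around 4%; the residual error is dominated by the noisy first observation
being used as the initial state.

## Problem sizes used by the tests

Unit and property checks run on 25–60 h simulations at the 0.025 h output
step; the long 200 h runs quoted above were development-time verification
only. The recovery experiment uses 10 replicates × 6 restarts (≈3 min);
diagram scans in tests use 10–15 grid points. Property tests over random
parameter sets use 20–200 seeded draws (hypothesis where convenient,
seeded numpy elsewhere).

## Limitations

- No spatial structure: the two compartments are well-mixed pools; no PDE
  or delay-equation variants.
- No stochastic kinetics; noise enters only as observation noise.
- Sensitivities are local (steady-state elasticities); no variance-based
  global analysis, and none for period/amplitude.
- The limit cycle itself is characterized by simulation, not continuation;
  no Floquet analysis.
- Calibration is least squares with box bounds — no posterior inference,
  and identifiability handling is limited to the k1/G_E product rule.
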