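# biofilmosc

Kinetic analysis of metabolic oscillations in *Bacillus subtilis* biofilms,
built around the smallest mass-action reaction system that exhibits a Hopf
bifurcation.

Growing *B. subtilis* biofilms divide labour between two compartments: the
periphery takes up glutamate from the medium, while the interior monopolizes
the production of ammonia, which the periphery needs for biomass synthesis.
This coupling produces oscillations in growth with a period of roughly two
hours. `biofilmosc` implements a three-variable caricature of that loop —
peripheral glutamate `Gp`, ammonia `A` and interior glutamate `Gi`
(mmol l⁻¹, time in hours):

```
dGp/dt = k1·G_E·Gp − k4·Gp − k2·A·Gp
dA/dt  = −k3·A + k5·Gi
dGi/dt = k4·Gp − k5·Gi
```

`G_E` is the (constant) external glutamate concentration, `k1` the
self-amplifying uptake constant, `k4` the periphery→interior transfer rate,
`k5` the glutamate-dehydrogenase (ammonia production) rate, `k3` the ammonia
loss rate, and `k2` the bilinear consumption of ammonia and glutamate for
biomass, which grows trilinearly as `dB/dt = b·A·Gp·B`. An optional variant
replaces the transfer term by the self-amplified form `k4·Gi·Gp`.

The package provides, on top of this model:

- **dynamics** — stiff-capable simulation (LSODA, analytic Jacobian),
  limit-cycle period/amplitude/average extraction, biomass growth and the
  ammonia-maxima doubling-time estimator;
- **steady states & stability** — closed-form trivial (TSS) and non-trivial
  (NTSS) states, exact Jacobians, eigenvalue classification;
- **bifurcation analysis** — closed-form transcritical (`G_E = k4/k1`) and
  Hopf (`G_E = (k3+k4+k5)/k1`) thresholds, numeric Hopf detection in any
  rate constant, one-parameter branch/envelope diagram scans;
- **QSSA reduction** — adiabatic elimination of `Gi` (or `A`), with the
  proof-backed classification saddle / stable node / stable focus and the
  no-limit-cycle property of the reduced system;
- **sensitivity analysis** — symbolic steady-state sensitivities, scaled
  and unscaled, with a finite-difference oracle;
- **synthetic data & calibration** — seeded noisy observation generator and
  multi-start trajectory-matching least squares
  (`TrajectoryCalibration(...).fit()` → results object with `summary()`).

## Worked example

```python
from biofilmosc import (ParameterSet, simulate, summarize_oscillation,
                        steady_states, transcritical_point, hopf_point,
                        analytic_sensitivities)

p = ParameterSet()                    # reference parameterization
tss, ntss = steady_states(p)
print(ntss.concentrations)            # [3.12377358 1.56188679 2.71632486]
print(ntss.classification)            # unstable-focus  (beyond the Hopf point)

traj = simulate(p, (1, 1, 1), t_end=60.0)
s = summarize_oscillation(traj, transient=30.0)
print(f"{s.period:.4f} h")            # 2.3335 h  (140.0 min)
print(s.amplitudes)                   # {'Gp': 14.899, 'A': 2.967, 'Gi': 6.785}
print(s.cycle_averages)               # {'Gp': 3.1239, 'A': 1.5618, 'Gi': 2.7161}

print(transcritical_point(p))         # 5.8377  mmol/l
print(hopf_point(p))                  # 24.2265 mmol/l
print(analytic_sensitivities(p).max_scaled())  # (1.2416, 'Gp_ss', 'k1')
```

The steady state is unstable at the reference supply level, so the system
settles on a limit cycle: peak-to-trough swings of ~14.9 mmol l⁻¹ in
peripheral glutamate against a mean of only ~3.1. The cycle averages equal
the unstable steady-state values — a Lotka–Volterra-type equality that this
package verifies numerically and exploits for the growth rate: biomass on
the cycle doubles every `ln 2/(b·A_ss·Gp_ss) ≈ 1.42 h` despite the periodic
stalls in growth.

Parameter recovery from noisy synthetic observations:

```python
from biofilmosc import SyntheticConfig, generate, fit

ds = generate(SyntheticConfig(params=p, noise_sigma=0.1, seed=0))
res = fit(ds.observed, ("k1", "k2", "k5"), p, n_restarts=6, seed=1000)
print(res.summary(truth=p))
# k1 0.33704 (1.6% off), k2 5.0851 (4.1%), k5 2.2592 (1.8%)
```

The same pipeline is scriptable from a shell:

```sh
biofilmosc simulate --out traj.csv             # 1001-row time course CSV
biofilmosc summarize --data traj.csv
biofilmosc bifurcate --param G_E --min 3 --max 30 --n 15 --out scan.csv
biofilmosc synth --seed 1 --sigma 0.1 --out obs.csv
biofilmosc fit --data obs.csv --free k1,k2,k5
biofilmosc reproduce --outdir repro/           # headline analyses + report
```

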