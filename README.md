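# homeostat

Feedback circuits of tissue-size homeostasis: biphasic control, mutant
invasion, and evolutionary stability.

## The problem

Tissues hold their cell mass `Z` at a set point through feedback: cells
sense a signal `y` (a hormone level, a metabolite, a secreted factor) and
adjust proliferation and removal, `dZ/dt = Z·(λ₊(y) − λ₋(y))`. This
package asks what happens when single cells *mis-sense* the signal — a
clone that reads `y` as `k·y` after a receptor or sensor mutation — and
why so many real circuits (beta cells and glucose, neurons and glutamate,
T cells and IL-2) make the signal *toxic at both extremes*.

The answer it implements and tests:

- **Monophasic** control (growth rate crosses zero once in `y`) is
  globally stable but evolutionarily fragile: any clone that mis-senses
  the signal upward has positive growth at the set point, sweeps the
  tissue, and drags the signal to a pathological level.
- **Biphasic** control (growth negative at both low and high `y` —
  glucotoxicity-style) eliminates any strong mis-senser: the rare mutant
  reads the normal signal as a toxic one and dies. The price is a second,
  unstable fixed point `y_UST` beyond which the tissue collapses. The
  dimensionless gap `δ = (y_UST − y_ST)/y_ST` measures how much
  perturbation the circuit tolerates.
- Selection on strong mutants is **frequency dependent**: rare (somatic)
  clones are purged, but a germline mutant spawns a whole tissue that
  holds the signal where *it* senses the set point.
- Over a lifetime, a compartmentalised tissue (e.g. pancreatic islets,
  `N` cells each) stays mutant-free with probability

      ζ(t) = exp(−N·τ⁻¹·δ·μ₀·(1 − 1/ν)·t),

  where `τ⁻¹` is the per-cell division rate, `μ₀` the per-division
  probability of an advantageous mis-sensing mutation, `ν = λ₊/λ₋` the
  mutant's fitness ratio and `(1 − 1/ν)` its large-`N` Moran fixation
  probability. Narrowing δ buys evolutionary stability at the cost of
  dynamic stability and response time (`λ₊ − λ₋ = τ⁻¹(ν−1)/ν`) — a
  three-way tradeoff.

The package is for systems-biology modellers who want these circuits as
tested, composable pieces: ODE circuit models with fixed-point and basin
analysis, mutant-invasion simulations, a seeded Moran simulator as the
stochastic oracle for ζ(t), and the two worked applications (beta
cells/glucose with GCK Hill sensing; stem-cell renewal control).

## Worked example

```python
from homeostat import presets, simulate, find_fixed_points, delta_metric
from homeostat.mutant_invasion import advantageous_window

bi = presets.biphasic()                 # λ₊ = 4.8/(1+(7/y)⁵), λ₋ = 6/(1+(8/y)⁵)+0.1
fps = find_fixed_points(bi)             # zeroes of λ plus the coupling Z·y = 25
for p in fps:
    print(f"y* = {p.y:.3f}  Z* = {p.Z:.3f}  {p.stability}")
print(f"delta = {delta_metric(fps):.3f}")
print(f"advantageous window: k in (1, {advantageous_window(bi)[1]:.3f})")

traj = simulate(bi, 5.0, 5.0)           # integrate from a generic interior state
print(f"outcome: {traj.outcome}  final: Z = {traj.populations['Z'][-1]:.3f}, "
      f"y = {traj.signal[-1]:.3f}")
```

prints

```
y* = 4.058  Z* = 6.161  stable
y* = 8.262  Z* = 3.026  unstable
delta = 1.036
advantageous window: k in (1, 2.036)
outcome: steady  final: Z = 6.161, y = 4.058
```

The circuit settles at its set point (y ≈ 4.06, Z ≈ 6.16); only mutants
mis-sensing the signal by less than about two-fold can invade — a 4-fold
mutant senses 16 (past `y_UST` ≈ 8.26), lands on the toxic branch and is
eliminated. `homeostat --help` exposes the same runs from the shell
(`run`, `fixed-points`, `zeta`, `moran`, `betacell`, `stemcell`,
`ensemble`, `list-fixtures`), all driven by TOML scenario files; bundled
examples live under `homeostat/fixtures/`.

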