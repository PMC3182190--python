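# compsyn — learning with a network of competing synapses

`compsyn` simulates a game-theory-inspired model of synaptic plasticity in
which binary synapses — each either **strong** or **weak** — compete on a
one-dimensional chain through the activity of the neurons they flank. It is
aimed at computational neuroscientists studying how multiple synaptic
timescales shape system-level learning and forgetting, e.g. in motor
adaptation.

## The model

Each neuron fires with probability `α` if its other adjacent synapse is
strong, `β` if weak. When a synapse is considered for an update, the
outcome is anti-Hebbian: with mixed-type neighbours, it is potentiated if
only the strong-adjacent neuron fires and depressed if only the
weak-adjacent one fires; otherwise nothing happens. In the mean-field
(effective) description the strong fraction `x` obeys

    dx/dt = 2x(1−x) [ (1−x)A − xB ],   A = α(1−β),  B = β(1−α),

with a stable fixed point `x* = A/(A+B)` and exponential relaxation time
`τ = 1/(2x*(1−x*)(A+B))`. A signal `s` biases the parameters as
`(α, β) → (α+s, β−s)`, shifting the fixed point; learning and forgetting
are relaxations toward the shifted and default fixed points, each governed
by the `τ` of its end state. The package provides:

- `compsyn.core` — plasticity-rule enumeration, drift, fixed points, `τ`;
- `compsyn.lattice` — seeded Monte-Carlo simulation of the microscopic
  chain (the stochastic model the mean field approximates);
- `compsyn.signals` / `compsyn.protocols` — de-adaptation (signal → no
  signal), downscaling (signal → half signal) and anterograde-interference
  (signal → reversed signal) protocols with saturation-based timescale
  measurement;
- `compsyn.phasemaps` — ln timescale-ratio maps over the (default,
  signal-strength) plane, by analytic and numeric routes.

## Worked example

```python
from compsyn import (PlasticityParams, build_protocol, run_protocol,
                     relaxation_time, stable_fixed_point)

default = PlasticityParams(0.2, 0.8)        # widely separated timescales
print(stable_fixed_point(default))          # 0.058823529411764566
print(relaxation_time(default))             # 13.28125000000005

result = run_protocol(default, build_protocol("deadaptation", 0.1))
print(result.t_learn)                       # 68.32000000000001
print(result.t_second)                      # 105.98
print(result.ratio)                         # 1.5512295081967211
print(result.analytic_ratio)                # 2.0196659482758688
```

The system starts at the default fixed point (only ≈ 5.9 % of synapses
strong), learns a signal `s = 0.1` in `t_learn ≈ 68` sweeps, and takes
`t_second ≈ 106` sweeps to forget it once the signal is removed — forgetting
is ≈ 1.55× slower than learning, because the default state's relaxation
time (τ ≈ 13.3) exceeds the signal-on state's (τ(0.3, 0.7) ≈ 6.6). The
`analytic_ratio` is the pure time-constant ratio 13.28/6.58 ≈ 2.02;
measured saturation times differ from it by logarithmic factors but rank
the parameter plane the same way.

The same computations are available from the shell:

```sh
compsyn protocol --out out/dead --set a=0.2 --set protocol=deadaptation --set signal=0.1
compsyn phasemap --out out/map --set method=both --set protocol=deadaptation
compsyn lattice  --out out/chain --seed 7 --set alpha=0.6 --set beta=0.4
```

Every run writes its fully resolved configuration next to the outputs;
identical configurations (and seeds) reproduce byte-identical files.

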