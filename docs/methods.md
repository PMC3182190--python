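# Methods

## Model

A one-dimensional periodic chain of `N` binary synapses, each either
**strong** or **weak**, connects binary threshold neurons. Synapses sharing
a neuron are neighbours, so each synapse has exactly two. When a synapse is
a candidate for an update, each of its two flanking neurons fires
independently with a probability set by the type of its *other* adjacent
synapse — `alpha` if that synapse is strong, `beta` if weak; the candidate
synapse itself is ignored ("ignoring the common denominator" shared by the
two neurons). The joint activation outcome is classified by polarity:

- **potentiation** — the neighbours are of mixed type and only the
  strong-adjacent neuron fires (probability `A = alpha (1 - beta)` per
  mixed configuration); the candidate becomes strong;
- **depression** — mixed type and only the weak-adjacent neuron fires
  (probability `B = beta (1 - alpha)`); the candidate becomes weak;
- **no change** — everything else, including all same-type neighbour
  configurations.

The rule has an anti-Hebbian flavour: change is driven by asymmetric
(one-fires, one-silent) activity. The all-strong and all-weak states are
absorbing: no mixed pair ever arises again.

These single-update rules are the single source of truth in the code: the
mean-field quantities below are assembled by enumerating the 2×2 activation
table (`neighbor_outcome_probs`), and the closed forms carried alongside
are *derived* expressions that the test suite checks against the
enumeration to 1e-12 on a parameter grid.

## Mean-field (effective) description

Replacing the chain by a single strong fraction `x`, uniform over the
lattice and free of correlations, and averaging the update rules over
neighbour configurations drawn independently with strong-probability `x`
(mixed weight `2x(1-x)`) gives

    dx/dt = (1 - x) W_up(x) - x W_down(x),
    W_up   = 2x(1-x) A,      W_down = 2x(1-x) B,

i.e. `dx/dt = 2x(1-x) [ (1-x)A - xB ]`, a cubic with unstable absorbing
fixed points at 0 and 1 and a stable interior fixed point

    x* = A / (A + B),        tau = -1/drift'(x*) = 1 / (2 x*(1-x*)(A+B)).

`tau` is the exponential time constant for relaxation to `x*`; it is
minimal (`tau = 4` at `alpha = beta = 1/2`) at the symmetric point and
diverges toward the corners of the `(alpha, beta)` square, where the two
synaptic timescales are widely separated — the long-retention regime.

**Time units.** One unit of time is one sweep: one expected update attempt
per synapse. The lattice simulator performs `N` random-sequential updates
per sweep, so lattice and mean-field clocks are directly comparable.

**Relabeling symmetry.** Exchanging the strong and weak labels maps
`(alpha, beta) -> (beta, alpha)` and `x -> 1 - x`; hence
`x*(a,b) = 1 - x*(b,a)` and `tau(a,b) = tau(b,a)`. This symmetry is exact
in the implementation and used as a test oracle throughout.

## Signals and protocols

A signal of strength `s` shifts both parameters by equal and opposite
amounts, `(alpha, beta) -> (alpha + s, beta - s)`, conserving
`alpha + beta`; shifted states move parallel to the `alpha = 1 - beta`
diagonal, and the admissible range
`s ∈ (max(-alpha, beta-1), min(1-alpha, beta))` has maximal length 1
exactly on that diagonal. Phase maps therefore parametrize the default
system by the diagonal coordinate `a`, default params `(a, 1-a)`.

Protocol shapes (each phase held until saturation):

| kind         | phases        |
|--------------|---------------|
| constant     | `[s]`         |
| deadaptation | `[s, 0]`      |
| downscaling  | `[s, s/2]`    |
| reversal     | `[s, -s]`     |

The sign convention is that `+s` increments `alpha`, the strong-adjacent
activation probability. By the relabeling symmetry all reported ratios are
invariant under flipping both the labels and the sign of `s`.

## Saturation and timescale measurement

Every protocol starts at the default fixed point `x*(alpha, beta)`. A phase
"saturates" when the fractional change of the state per time-step falls
below a tolerance. Two conventions here:

- *Per unit time, not per integrator micro-step*: the criterion is
  `|dx/dt| < tol` (equivalently `|x_{n+1} - x_n| < tol·dt` for Euler), so
  measured times are independent of `dt` to first order.
- *Change of the fraction itself*: `x` is already a fraction (of strong
  synapses), so the threshold is applied to its absolute change per unit
  time rather than to the change relative to the current value of `x`. The
  relative-to-`x` variant would break the exact mirror symmetry of the
  reversal protocol (it weighs the two synapse types asymmetrically); with
  the convention used here, the reversal ratio at a symmetric default is 1
  up to `O(dt)` step quantization, which the tests verify.

Defaults: `tol = 1e-6`, `dt = 0.01`, `max_time = 1e5` (all configurable).
Saturation times depend on the tolerance only logarithmically
(`t_sat ≈ tau·ln(C/tol)`; halving `tol` adds `tau·ln 2`, a property the
tests check numerically).

For de-adaptation and downscaling, the second timescale is the phase-2
saturation time from the learned state. For the reversal (anterograde
interference) protocol, the trajectory first relaxes back through the
default level; the relearning time is measured only from the first crossing
of `x*(default)` — located by linear interpolation between recorded points,
removing the `O(dt)` bias — until saturation at the reversed-signal fixed
point.

The analytic counterpart of the measured ratio is the pure time-constant
ratio `tau(phase-2 end-state params) / tau(phase-1 end-state params)`,
since each relaxation is exponential with the time constant of its *end*
state. Measured saturation times additionally contain the logarithmic
distance-to-fixed-point factor, so the two routes are compared by rank
(Spearman) correlation over the `(a, s)` plane rather than elementwise; on
a 30×30 de-adaptation map the correlation is ≈ 0.99.

Degenerate protocols — zero signal, or a phase whose fixed point coincides
with its starting state — raise errors rather than returning 0/0 ratios.

## Lattice simulator

Design choices where the microscopic dynamics is underdetermined:

- **Update scheme**: random sequential — each of the `N` updates per sweep
  picks a site uniformly with replacement and draws fresh, independent
  neuron activations. This matches the effective description's assumption
  of uncorrelated outcomes.
- **Boundary**: periodic, removing edge effects and matching the
  translation-invariant mean-field picture.
- **Absorption**: runs that hit an absorbing state are flagged; the
  interior fixed point is only metastable at finite `N`.
- **Stationary estimates**: mean over a post-burn-in window with a
  batch-means standard error (default 10 batches), which absorbs
  autocorrelation at the batch scale.

The generator is the package's own synthetic-data source: it emulates the
microscopic model exactly (verified against a full master-equation
enumeration at `N = 10`, conditioned on non-absorption, in the tests), not
any empirical recording. Passing tests therefore certify the model's
internal consistency, not agreement with biological data.

**Mean-field accuracy.** The chain develops nearest-neighbour correlations
(domain-wall dynamics) that the effective description discards, so the
stationary strong fraction deviates systematically from `x*` away from the
symmetric line `alpha = beta`: the acceptance script measures a gap of
≈ 0.04 at `(0.6, 0.4)` with `N = 10^4`, far larger than the Monte-Carlo
error, and the deviation does not shrink with `N`. The mean-field level is
exact only as an uncorrelated approximation; what survives on the lattice
is the qualitative structure (direction of the bias of the dominant type,
absorbing states, metastability), which is what the tests assert. All
protocol and phase-map results live at the mean-field level, where the
signal analysis is defined.

## Numerical choices

- Parameters are validated on the open interval with an exclusion margin of
  1e-9; boundary values create absorbing degeneracies.
- The interior fixed point is found by Brent's method on the drift with the
  trivial roots at 0 and 1 factored out (tolerance near machine precision);
  stability (`drift'(x*) < 0`) is asserted.
- `drift'` is evaluated analytically on the enumeration-built cubic.
- Integration is explicit Euler (`dt = 0.01` default; stable since
  `|drift'| ≤ O(1)`), with an optional adaptive RK45 route for
  cross-checks. A step leaving `[0, 1]` raises an instability error.
- Trajectories are recorded every 0.1 time units (plus endpoints);
  long phases are integrated in segments so memory stays bounded while
  `max_time` can be generous.
- Problem sizes in the shipped tests and acceptance script — `N = 10^4`
  chains, 500 sweeps, 30×30 maps, 20-parameter-set oracles — were chosen as
  comfortable desk-scale runs that keep Monte-Carlo and discretization
  errors well below the asserted tolerances.

## Known limitations

- Mean-field ignores spatial correlations; see above. A pair approximation
  or full-correlation treatment is out of scope.
- Signals are piecewise constant and act on both parameters symmetrically;
  preferential or continuously varying signals are not modelled.
- Synapses are undirected and the topology is a 1-D chain; directed
  synapses or general graphs would change the update rules.
- "Savings" (faster relearning before complete forgetting) is visible in
  principle but not quantified here: it is a correlation effect the
  mean-field level cannot represent faithfully.
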