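# Methods

## Model

Players occupy the sites of a periodic `L x L` square lattice and interact
with their 8 Moore neighbors. Each player is a pure cooperator (C) or
defector (D) in the weak prisoner's dilemma: a cooperator meeting a
cooperator earns `R = 1`, a defector exploiting a cooperator earns the
temptation `T = b` (with `1 < b < 2`), and the remaining payoffs are
`P = S = 0`. Each undirected lattice edge carries a weight `w_xy`,
identical for both ends (one stored value per unordered pair, exposed
through a symmetric accessor), initialized at 1 and confined to
`[1 - delta, 1 + delta]`.

The utility of player `x` is the link-weighted payoff sum

    U_x = sum_{y in Omega_x} w_xy * P_xy,

and `U_x / k` with `k = 8` is its per-link average.

One elementary step:

1. a focal player `x` is drawn uniformly at random and collects its 8
   pairwise payoffs and `U_x` under the current weights;
2. every link of `x` is judged against the per-link average: links with
   `P_xy > U_x / k` are rewarded by `+Delta`, all others (including exact
   ties) punished by `-Delta`, and the result is clamped into
   `[1 - delta, 1 + delta]`;
3. a neighbor `y` is drawn uniformly from `Omega_x`; if `U_y > U_x` the
   focal player adopts `s_y` with probability
   `W = min(1, (U_y - U_x) / (D k))`, where `D = T - P = b`.

One Monte Carlo step (MCS) is `N = L^2` elementary steps (focal players
drawn with replacement), so each player is selected once on average. The
order parameter is the cooperation fraction `rho_C`, measured as the mean
over a trailing window of MCS once the dynamics are stationary.

With `Delta = 0` or `delta = 0` the weights never leave 1 and the model is
exactly the classical spatial prisoner's dilemma; this limit is enforced in
the tests by trace-identity against an independently coded classical
implementation sharing the same random stream.

## Design decisions

**Utility timing.** Step 3 compares the utilities that were accrued under
the weights in force when the payoffs were earned; the focal player's
weight adjustment becomes effective from the next interaction. The
alternative — recomputing both utilities from the post-adjustment weights —
is available via `utilities_pre_adjust=False` on `run`,
`monte_carlo_step` and `elementary_step`. This was a genuinely open design
point; we fixed the accrued-utility convention because it produces the
characteristic phenomenology of the coevolutionary model across the whole
amplitude range (an intermediate optimum of `rho_C` at
`Delta/delta ≈ 0.2-0.4`, a mid-level plateau rather than extinction at
`Delta/delta = 1`, and a climb without initial retreat from the prepared
half-and-half state at ratio 0.5), whereas the recompute-first convention
shifts the optimum to much smaller ratios and loses the mid-level plateau.
The classical `Delta = 0` limit is identical under both conventions.

**Ties punish.** The reward condition is strict (`P_xy > U_x / k`), so in a
uniform cooperative region, where every payoff equals the average, all
links drift to the lower clamp. The tie case is consequential only in
exactly homogeneous neighborhoods; treating ties as neutral was tested and
changes the steady states by at most a few percent.

**Probability clipping.** Weighted utilities range up to `8 (1+delta) b`
while the imitation normalizer `D k = 8 b` is inherited from the unweighted
tradition, so the raw ratio can exceed 1; it is clipped at 1. The clip
binds only for extreme utility differences at large `delta`.

**Schedule and RNG contract.** Focal players are drawn with replacement.
The per-MCS randomness is three bulk draws from one `numpy` Generator —
focal sites, neighbor slots, adoption uniforms, each of length `N` — and
the adoption uniform of a step is consumed unconditionally, so the stream
position never depends on the state. The numba kernel and the pure-Python
reference path consume the identical stream and are bit-identical; sweeps
give replicate `r` of grid point `p` the stream
`SeedSequence(seed, spawn_key=(p, r))`, so enlarging a sweep never perturbs
existing realizations.

**Early termination.** All-C and all-D strategy fields are absorbing (with
`P = S = 0` every utility in an all-D state is 0, and copying an identical
strategy is a no-op), so sweep runs may stop once the strategy field is
uniform, extending `rho_C` constantly to the end; time-course runs never
take this shortcut. Spot checks with the shortcut disabled give identical
stationary values.

**Numerics.** Weights are double precision; clamping uses closed-interval
comparisons with no epsilon. Weight histograms align bin edges to
half-integer multiples of `Delta` so every attainable weight value
`1 - delta + m Delta` falls in the interior of its own bin; the variance is
the population variance over all `4 L^2` edges and can never exceed
`delta^2` for a variable confined to an interval of half-width `delta`
(asserted on every summary).

**Extinction thresholds.** The cooperator-extinction temptation is the
largest scanned `b` whose mean stationary `rho_C` exceeds the extinction
tolerance, linearly interpolated to the crossing with the next grid point;
the defector boundary uses the level `1 - tol`. The default tolerance is
`1/N^2`, which makes any surviving individual in the window count as
non-extinct; raising the tolerance can only lower the cooperator threshold
(monotonicity is tested). An unbracketed transition is reported as
out-of-range (`None`), never extrapolated.

## Protocols and problem sizes

Two named protocols:

| protocol | L | total MCS | window | replicates |
|----------|-----|--------|--------|------------|
| `desk` | 50 | 5000 | 500 | 3 |
| `reference` | 100 | 61000 | 1000 | 10 |

The `desk` protocol is the package default and is what the test-suite and
`scripts/acceptance.py` use; it resolves the stationary states of this
model well (finite-size spot checks at L=50 versus L=100 agree within two
pooled standard errors, and the classical extinction threshold interpolates
to `b_c ≈ 1.24-1.26` on a 0.02 grid at either size). The full-scale
protocol is preserved as an opt-in preset for production runs. Time-course
checks from the prepared state use 3000 MCS, by which the trajectories at
`b = 1.34` have visibly settled.

## Initial conditions as study conditions

The generator of initial states is part of the model definition, not a
fixture: `random` assigns C or D independently with probability 1/2
(the default for sweeps and phase diagrams); `half_plane` fills the left
half-columns with cooperators and the right half with defectors (even `L`
only, so `rho_C(0) = 1/2` exactly) — the prepared state used for time
courses and snapshot series, where a single straight interface makes the
invasion/recovery dynamics legible. Orientation of the split is irrelevant
on a torus. An optional `heterogeneous` weight initializer (uniform on
`[1 - delta, 1 + delta]`) exists to check that the equilibrium does not
depend on the initial weight distribution; no specific disorder is
canonical. These initial states emulate controlled experimental
preparations; they do not emulate empirical social networks (no degree
heterogeneity, no community structure, no noise in strategies), so passing
tests demonstrate properties of the model class, not of any real network.

## Known limitations

* Under the symmetric shared-weight rule, both ends of a
  cooperator-defector edge update the same stored value with opposing
  verdicts (the cooperator punishes the link, the defector rewards it), so
  interface weights random-walk rather than pin at the lower clamp. As a
  consequence, at `b = 1.34, delta = 0.4` the rescued steady states level
  off at `rho_C ≈ 0.6` rather than complete cooperator dominance; complete
  dominance does occur at lower temptation (e.g. `rho_C = 1` at `b = 1.20`
  for ratios 0.3-0.6, see `examples/phase_diagram_small.py`). Two
  acceptance-style checks encode the stronger expectation (full dominance
  at ratio 0.5 and a weight-variance maximum at `Delta = 0.2` at this
  temptation) and fail against this implementation; the variance of the
  stationary weight field instead grows monotonically with `Delta`
  (0.099/0.104/0.122 for `Delta` = 0.1/0.2/0.4).
* The stationary weight variance is bounded by `delta^2` (0.16 at
  `delta = 0.4`) by construction; any reported variance above that bound
  for a bounded weight field must refer to a different quantity (e.g. the
  variance of per-player weight sums, which can reach `8^2 delta^2` under
  correlations).
* Only the 8-neighbor periodic lattice is supported: no degree
  heterogeneity, directed or asymmetric weights, synchronous updating,
  strategy noise/mutation, or alternative imitation rules.
* Cluster-geometry observables beyond snapshots (cluster-size
  distributions, interface lengths) are out of scope.
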