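# Methods

## Model and transformation

Times between events are i.i.d. exponential with scale `θ` (the mean).  The
chart operates on `T* = T^(1/3.6)`: a Weibull variate with shape 3.6, whose
skewness is near zero, so subgroup means of `T*` are close to normal even at
`n = 4`.  The shape is fixed at 3.6 throughout (it is what makes the
normal-theory limit formulas usable) but is carried as an explicit
parameter (`shape`) so its role is visible and testable; the package makes
no claim about other shapes.

All moments are evaluated with `scipy.special.gamma` directly:
`Γ(1 + 1/3.6) = 0.9011057`, `√(Γ(1 + 2/3.6) − Γ²(1 + 1/3.6)) = 0.2780203`.

## Interval-valued (neutrosophic) quantities

An indeterminate quantity is an ordered pair of values at the two ends of
its indeterminacy interval, *lower-indeterminacy configuration first*.  The
pair is not sorted: a coefficient pair like `(2.738, 2.66)` is meaningful as
given.  A degenerate pair (equal endpoints) must and does reduce every
operation to its classical counterpart — this is tested exactly (equal
seeds, equal outputs).  The equivalent `a + b·I` form uses
`x(I) = x_L − x_U·I` with `I ∈ [0, (x_L − x_U)/x_U]`, so `x(0)` is the lower
endpoint and `x(I_max)` the upper; the conversion is a helper only, the
endpoint pair is the internal representation.  Endpoint-paired execution
(two independent runs at the L and U configurations) is the package's
semantics for interval-valued designs; per-observation random indeterminacy
is deliberately not simulated, because endpoint evaluation is what the
chart's design tables mean.

## The chart and its head-of-series convention

The plotted statistic at subgroup `i` is the mean of the last
`min(i, w)` transformed subgroup means.  The limit formulas describe the
variance of the *full-window* statistic (`i ≥ w`); partial windows have
variance larger by `w / min(i, w)`, so judging them against the same limits
would inflate early false alarms (at `w = 3`, `k = 2.738`, the first
subgroup would be an effective 1.58-sigma test).  The package therefore
evaluates points against the limits only from `i = w` on — the minimum
possible run length is `w` — while still computing and reporting the
partial-window values for plotting.  An `evaluate_partial` switch restores
head-of-series evaluation for exploration.  This choice is validated
empirically: simulated in-control ARLs under it reproduce the published
design tables this package accompanies, while partial-window evaluation
does not come close.

Boundary values count as in control (signals are strict inequalities); under
the continuous model ties have probability zero, so the choice is
conservative and free.

## Run-length engine

A run is simulated as a stream of subgroups at scale `c·θ₀` monitored with
limits at `θ₀`.  Both the statistic and the limits scale by `θ₀^(1/3.6)`, so
run lengths are invariant to `θ₀`; the engine simulates on the unit scale
and applies only `c`, which makes the invariance hold *bitwise* (tested as
exact equality of summaries at `θ₀ = 1` and `θ₀ = 238.1`).

The engine is vectorised over replications: subgroups are generated in
blocks of 128 columns, full-window moving averages are formed by cumulative
sums with the last `w − 1` means carried across blocks, and replications
leave the active set when they signal.  Runs are censored at
`max_run_length` (default 10⁶) with the censoring count reported and a
warning emitted, since censored runs enter the mean at the cap and bias the
ARL downwards.  Cumulative-sum windowing differs from a naive mean by
O(10⁻¹⁴) relative error, which is irrelevant against limits O(10⁻¹) away;
`w = 1` bypasses it and returns the means unchanged.

ARL standard error is reported as `sdrl/√reps`.  At `w = 1` the run length
is geometric, so `sdrl ≈ √(arl(arl − 1))` and an independent oracle —
`1/p̂` with `p̂` the directly simulated per-subgroup signal probability —
must agree with the sequential engine; both are tested.

## Calibration

`calibrate_k` finds the smallest `k` whose estimated in-control ARL reaches
the target: a coarse upward scan (step 0.05 from 0.5) followed by
refinements at steps 0.005 and 0.001 within the bracketing cell, stopping
early when the achieved ARL is within `tolerance` (default 1.0) of the
target.  Every candidate uses the same seed (common random numbers), which
makes the estimated ARL monotone in `k` — each simulated path signals no
earlier under wider limits — so upward scanning is exact on the grid and
the result is deterministic given the seed.  Targets unreachable within
`k ∈ [0.5, 6]` raise `CalibrationError`.  With 10,000 replications the
Monte Carlo noise at the crossing (se ≈ 2 on an ARL of 200, slope roughly
800 ARL units per unit `k`) corresponds to about ±0.003 in `k`, well inside
the ±0.04 acceptance brackets used in the tests.

## Synthetic data generator

`generate_series` emulates the study design the bundled example comes from:
two endpoint series of exponential event times with endpoint scales
`(θ_L, θ_U)`, subgroup sizes that may differ per endpoint (interval-valued
`n`), and a step change to `c·θ` at a configurable subgroup.  `coupled=True`
drives both endpoints with the same uniforms through the inverse CDF,
making the endpoint series comonotone within each cell — useful for
isolating the effect of the scale interval from sampling noise.  It does
*not* emulate features of real disappearance-time data such as serial
correlation within an incubation run, measurement rounding, or gradual
drifts: passing tests show the monitoring machinery behaves as designed
under the stated model, not that betaine kinetics are exponential.

The bundled Betaine fixture stores the published values exactly as printed
(two decimals); the generated portion of that table cannot be re-simulated
because its generation seed is unknown.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `n` | subgroup size | 4 | smallest size in the design tables; the worked example uses 4 |
| `w` | MA span | 3 | the span the design tables tabulate; 1 gives the Shewhart case |
| `k` | limit coefficient (sigmas of the plotted statistic) | 2.738 | span-3, n=4 coefficient for ARL₀ ≈ 200 |
| `θ0` | in-control scale (time units) | estimated from data when absent | grand mean of raw times is the natural moment estimator |
| `c` | scale-shift multiplier | 1 (in control) | `c < 1`: events more frequent; `c > 1`: less frequent |
| `reps` | Monte Carlo replications | 10,000 | matches the design-table precision (se ≈ 1% of ARL) |
| `max_run_length` | censoring cap | 10⁶ | ≥ 5000× the largest target ARL₀; censoring essentially never occurs there |

## Known limitations

- The published table this package reproduces prints moving-average values
  for the first `w − 1` subgroups of the worked example under a convention
  that matches neither partial nor full windows; those head cells are
  excluded from reproduction tests (everything from the first full window
  on matches cell-for-cell at two decimals).
- A few published extreme-shift cells report ARLs below `w` (e.g. 1.8 at
  `w = 5`), which no convention with a `w − 1` warm-up can produce; they are
  not reproduced.
- Monitoring the worked example's upper-endpoint series at its nominal
  generation scale (1/0.0076) flags subgroups 5–7: the head of that series
  is laboratory data on a visibly larger scale than the generated tail.
  With the scale estimated from the data the high side stays (barely)
  inside the limits and only subgroup 20 dips below the lower limit, so the
  bundled example is best monitored with `--estimate`.
- ARLs for `w > 1` are Monte Carlo only; no Markov-chain or
  integral-equation approximation is attempted.
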