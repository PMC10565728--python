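# Methods

## Model

`evodyn` simulates competition between lineages that share one
fitness-generating function and differ in a single parameter, the
evolvability `k`.  The G-function is Lotka–Volterra competition with
Gaussian kernels:

    G(v, u, x) = (r / K(v)) · (K(v) − Σ_j a(v, u_j) x_j) − d·k
    K(v)       = K_m exp(−(v − γ(t))² / 2σ_k²)
    a(v, u_j)  = exp(−(v − u_j)² / 2σ_a²)

Population dynamics are `dx_i/dt = x_i G|v=u_i`; strategy dynamics follow
the canonical equation of adaptive dynamics, `du_i/dt = k_i dG/dv|v=u_i`,
so `k` converts the local fitness slope into a rate of trait change — a
proxy for additive genetic variance.  Key assumptions:

* **Cost of evolvability.** Each lineage pays `d·k` with its *own* k.
  This is what stacks the slow evolver's adaptive landscape a constant
  `d·(k_fast − k_slow)` above the fast evolver's: with the baseline
  parameters, 0.05 · (0.5 − 0.2) = 0.015 at every strategy.  The cost is
  linear and frequency-independent; other functional forms are out of
  scope.
* **Competition sums run over all extant lineages**, including every
  descendant in radiation runs; extinct lineages are removed from the sums,
  their density pinned at 0 and strategy frozen.
* **γ enters only the carrying capacity**, never the competition kernel.
* **Extinction is a threshold rule**, not demographic stochasticity: a
  lineage is declared extinct when its density is strictly below the
  threshold (default 1.0) at a recorded sample (default spacing 1 time
  unit).  The ODE itself never reaches zero; the rule stands in for Allee
  effects and drift at low density.

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| r | intrinsic growth rate | 0.25 | 1/time |
| K_m | maximum carrying capacity | 100 | density |
| d | cost of evolvability | 0.05 | fitness per unit k |
| σ_k² | environmental niche size | 12.5 | strategy² |
| σ_a² | species niche width | 100 (2 in radiation) | strategy² |
| k (fast / slow) | evolvability | 0.5 / 0.2 | strategy²·time⁻¹ per fitness slope |
| extinction threshold | density declared extinct | 1.0 (0 = off) | density |
| x₀ | founder density | 10 | density |

The single-lineage equilibrium is closed-form: u* = γ and
x* = K(u*)(1 − d·k/r), giving 96 for the slow and 90 for the fast evolver
under the defaults.  Founder density is not part of the published record
for these experiments; x₀ = 10 per founder is the package default, fixed
once against the deterministic clade-initiation extinction times and then
used unchanged everywhere (every output embeds the resolved value in its
header).

## Numerics

* **Integration.** LSODA via `scipy.integrate.solve_ivp`, rtol 1e−8,
  atol 1e−10.  The integrator is hard-restarted at every environmental
  discontinuity (step times, stochastic redraws) and at every extinction
  or speciation event, so no solver step straddles a jump.  Negative
  density overshoot up to 1e−9 is clipped to zero; anything worse raises
  an integration error rather than being silently truncated.
* **Derivatives.** dG/dv and d²G/dv² are coded analytically (both kernels
  have closed-form derivatives) and validated in the test suite against a
  central finite-difference oracle (h = 1e−4) to better than 1e−6
  relative error on randomized communities.  No runtime symbolic or
  numeric differentiation.
* **Singular points.** The selection gradient is evaluated on a regular
  grid (default [−20, 20], step 0.01); every sign change is refined by
  bisection to 1e−8 and classified by curvature: negative → ESS peak,
  positive plus a passing convergence test → convergent-stable minimum
  (branching point).  Convergence is tested by displacing the nearest
  resident to v* ± h and checking that the gradient it experiences points
  back.  An empty community is handled as the vanishing-density limit of a
  monomorphic lineage (pseudo-resident at the carrying-capacity peak),
  which yields the single singular point v* = γ.
* **Seeding.** One master seed per run; environmental redraws and
  speciation offsets consume separate spawned streams, so adding lineages
  does not shift the γ sequence, and replicate batches derive per-replicate
  seeds from the master.  Identical seeds reproduce recorded samples
  bit-for-bit.

## Scenario protocols and design choices

Where the underlying experimental descriptions leave a choice open, the
package makes one explicit choice, listed here.

* **Stochastic tracking** redraws γ ~ U(−2, 2) every 5 time units with
  γ(0) = 0 and the *first redraw at t = 5*.  Redrawing already at t = 0
  was evaluated and shifts the far-start mean extinction time from ~11 to
  ~8 time units; neither variant reproduces the nominal ~5, which appears
  sensitive to unpublished details of the original runs (both variants sit
  inside the documented 3-standard-deviation band, ±9.8).  The keep-γ₀
  reading is the default.  Medium-start (u₀ = 4) statistics depend on an
  explicitly biased, unpublished initial condition and are not treated as
  reproducible.
* **Disturbance regimes** are explicit step schedules shipped as named
  presets (`collapse_*`: 0→−4 at t=900, then −8 at 1800/1700/1600;
  `transient_*`: 0→−4.4 at 900, back to 0 at 2000/1800/1400).  The
  coexistence produced at intermediate timing is *transient* — with the
  1700 schedule the fast evolver eventually dies around t ≈ 2700 — so the
  outcome classification ("coexistence" = both lineages extant at t_end)
  uses the default horizon t_end = 2500, matching the window over which
  the phenomenon is defined.  A `periodic_steps` builder is provided for
  regularly repeating disturbance trains; it is a qualitative fixture (the
  exact schedule behind prolonged cyclical coexistence is a free choice).
* **Adaptive radiation** uses the bounded kernel, σ_a² = 2, one fast and
  one slow founder.  Daughters get the parent's k, density 1, and a
  strategy offset drawn uniformly on [−0.02, +0.02] (a two-point ±0.02
  draw is available as `offset_mode="two_point"`).  Two departures from a
  literal reading of the speciation procedure proved necessary:
  1. *The extinction rule is disabled* (threshold 0) in this scenario:
     daughters are seeded exactly at the threshold and dip below it during
     the insertion transient (the community briefly overshoots its joint
     equilibrium), so a strict rule culls every incipient species.
     Consistently, the radiation accounts this package reproduces contain
     no extinctions at all, and the claim that all three starting
     distances reach the same two-lineage equilibrium also requires the
     rule off (from u₀ = 10 the slow evolver grazes 0.96 during the
     founding transient).
  2. *The trigger is edge-sensitive with hysteresis.*  A lineage fires
     when it enters the 0.02-neighborhood of a convergent minimum, and
     must retreat beyond 0.04 from every minimum before it can fire again,
     plus a 5-time-unit refractory after birth or speciation.  A purely
     level-sensitive trigger re-fires every refractory period while a
     parent is parked on its minimum, flooding the community.
  The canonical radiation run starts at u₀ = 0.5: there the fast clade's
  branching cascade continually reshapes the landscape, every speciation
  event has a fast-evolving parent and the slow lineage persists without
  ever speciating, as expected.  From u₀ = 4 or 10 the timing race is
  closer and the slow lineage can reach a quiescent minimum and branch —
  the all-fast pattern is a property of the sustained cascade, not of the
  rule itself.
* **Landscape frames** default to a strategy grid [−12, 12] at step 0.05
  (auto-widened to cover all strategies ±2) every 50 samples; one curve
  per distinct evolvability class, since the cost term only shifts the
  curve vertically.

## What the simulations do and do not show

All experiments are self-contained ODE simulations; there is no data
ingestion and no fitted noise model.  The stochasticity is entirely in the
environmental schedule (and speciation offsets), so replicate spread
reflects γ-sequence variability only — real systems add demographic noise,
drift, and mutation-limited waiting times that this framework abstracts
away.  Passing tests therefore certify the deterministic skeleton
(equilibria, extinction times, landscape geometry, branching logic) and
the distributional behavior of the schedule-driven runs, not any claim
about biological time scales.

Known limitations: no demographic stochasticity or explicit Allee
dynamics (the threshold is a stand-in); no spatial or stage structure; no
evolution of k itself; the linear cost form is untested against
alternatives; strategy dynamics continue while a density sits between the
threshold and zero only in the sense that the rule is checked at sample
resolution; medium-start stochastic-tracking statistics are not
reproducible without the original initial conditions; and the
reported problem sizes (100 replicates, horizons of 600–10000 time
units) were chosen as the package's own desk-scale defaults.
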