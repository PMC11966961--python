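# Methods

## Scope and modeling stance

`morphogrn` is a "toy model" framework: deliberately small deterministic
ODE models whose value is transparency, not data fitting. Three scales are
linked by construction rather than by coupling constants: the
thermodynamic rate laws derived at the single-gene scale are the
production terms of the GRN motifs, and the motifs are the per-cell
dynamics of the tissue simulators.

All quantities are nondimensional. Unless stated otherwise,
`k_t = λ = production_scale = 1`, so expression levels live in `[0, 1]`
and one time unit is a transcript half-life (up to `ln 2`). The default
Hill coefficient is `n = 4` everywhere: sharp but smooth switching, in
between the illustrative non-cooperative and strongly cooperative regimes.

## Single-gene kinetics

The full binding scheme tracks the bound-operator fraction `D1`, free
activator `X` and transcript `Y` (mass-action, no basal transcription).
Two consequences worth flagging:

- **Conservation and depletion.** `dX/dt = −dD1/dt` conserves
  `X_free + D1`, so binding *depletes* free activator. At `X_total = 1`,
  `K = 1` the stationary bound fraction is the root `(3 − √5)/2 ≈ 0.382`
  of the binding-equilibrium quadratic `(1 − D1)(X_total − D1) = K·D1`,
  not the depletion-free occupancy `1/2`. The depletion-free value is
  recovered when total activator is large compared with the operator.
- **Quasi-steady-state reduction.** `qss_discrepancy` therefore compares
  the full model against the reduction that keeps mass conservation:
  `D1` pinned at the quadratic root, `Y` integrated in closed form. With
  binding 100× faster than transcription the two agree to ≈0.4% (max
  relative deviation over the trajectory); at equal speeds they differ by
  ≈20%. Comparing against the depletion-free Michaelis–Menten form
  instead would leave a speed-independent offset at order-one `X_total`.

State-ensemble rate laws (`tse_rate`) implement the standard gates. The
independent-OR law is the additive occupancy sum as derived from the
doubly-weighted bound state, so its ceiling is `k_t` per binding site
(`2 k_t` for two sites); all other logics are bounded by `k_t`. Identity
of the factorized and expanded state-sum forms is property-tested to
1e-12.

## GRN motifs

Production of each gene is a product of Hill factors (occupancy for
activators, `1/(1 + (G/θ)^n)` for repressors), times an optional external
gain `M/(1+M)`. Defaults: strong repression `θs = 0.1`, weak repression
`θw = 1.0` (one order of magnitude apart — only the ordering is
structurally required), `λ = 1`.

The two-gene loops and the developmental motifs (multistable, cascade,
chain oscillator) behave as intended at these defaults. The three-gene
oscillators need a lower switching threshold to destabilize their
symmetric fixed point at `n = 4`; a sweep over
`θ ∈ {0.1, 0.15, 0.2, 0.3, 0.5}` showed sustained oscillations up to
`θ ≈ 0.3` with amplitude maximal near the low end, and `θ = 0.15` was
fixed as the documented default for both the repressilator and the
two-activator/one-repressor loop.

Attractor classification uses the trailing half of the trajectory: a
fixed point when every gene's peak-to-peak variation is below 5% of its
level (absolute floor 1e-6 for silent genes); otherwise an oscillation,
requiring at least three detected peaks (prominence 25% of range) of the
highest-amplitude gene, with the period the mean inter-peak interval.
Fewer than three peaks raises an error rather than guessing. Exactly
symmetric toggle initial conditions sit on the separatrix; the integrator
preserves the symmetry and the classifier simply reports the (unstable)
symmetric level rather than inventing a winner. Peak ordering flags ties
closer than one sample interval as ambiguous instead of imposing an order.

## Gradients and tissue

Gradients are logistic profiles `M = σ(k (x − x0))`, with a retracting
variant whose inflection moves at velocity `v`, and an induced stable
gradient that integrates `M′/(1+M′)` with zero decay (cumulative
trapezoid — exact, since the rate is state-independent). The default
orientation places the high end at `x = 0` (`k < 0`).

The tissue is 100 cells at integer positions with **no coupling**: each
spatial run integrates `n_cells` independent copies of the per-cell ODE
(vectorized into one solver call; LSODA, rtol 1e-7/atol 1e-9 for fields,
1e-8/1e-10 for single-cell and binding systems, stiff-capable because the
binding and patterning systems separate timescales). Cell autonomy is
testable directly: a tissue restricted to any subset of positions
(`Tissue1D.at_positions`) reproduces the full run's per-cell trajectories
to solver tolerance (~1e-7 observed; any apparent waves are kinematic).

Scenario-level parameters the source models leave open were fixed once,
by sweeps against the intended qualitative layouts, and recorded in
`src/morphogrn/data/scenarios.yaml`:

- **Threshold readout:** activation/repression thresholds
  `K = (0.1, 0.5, 0.1, 0.5)` against a `k = −0.1, x0 = 50` gradient; each
  steady-state boundary sits where `M` crosses the gene's `K`.
- **Two-gradient model:** strong/weak repression thresholds `0.1 / 0.7`;
  gradients `k = ∓0.2`, inflections at 35 and 64 (mirror-symmetric about
  the tissue center, so the two domains are exact mirror images). The
  weak threshold 0.7 (rather than 1.0) keeps the repression factor at
  saturating `M` below one half, which is what holds the domains away
  from the tissue ends.
- **Nested feed-forward ladder:** activation thresholds
  `geomspace(0.02, 0.5, N)`. With the top threshold much above 0.5 the
  last gene's occupancy saturates below its weakly-repressed predecessor
  and never dominates the high-M end; capping at 0.5 yields the N
  abutting ordered domains.
- **Additive stripes:** enhancer activities are pure products of
  repression factors (strong 0.1 / weak 0.7) of two opposing steep
  gradients (`k = ∓0.25`, inflections 45/54); the gene's linear ODE then
  settles at `(E1 + E2)/λ`, one stripe per enhancer.
- **Speed regulation:** `speed_scope="full_rhs"` is the default — the
  gate `M/(1+M)` multiplies production *and* decay, so cells freeze
  completely at `M = 0`; `production_only` (gate on production only) is
  kept as an option. Gradient `k = −0.1`; at `t_end = 120` the tissue
  shows all five fates ordered along the axis.
- **Enhancer switching:** `k_td = k_ts = 1`, competitive weights
  `k_ed = k_es = 1` and promoter cap `k_t = k_td + k_ts`, so additive and
  competitive wild types are comparable in scale. Scenario gradient
  `k = −0.2, x0 = 50`, reference time `t_end = 120` (the low-M half of
  the pattern is frozen by the static module well before this; the
  steeper slope confines the sensitive freezing boundary to a few cells,
  which is what gives the measured robustness margin). The intermediate
  fates appear as travelling waves; the settled pattern retains the
  ordered subset of fates (late fates at high M).

Pattern readouts: `segment_domains` assigns per-cell identity by argmax
(cells below 1e-6 everywhere are unassigned) or per-gene half-max runs;
`mismatch_score` is the fraction of cells whose identity differs;
`wave_trajectory` reports the position of a gene's spatial maximum,
taking the plateau midpoint when the maximum is degenerate (a saturated
terminal gene) and flagging times when the gene is below 5% of its global
maximum as undefined.

## Measured behavior (recomputed by `scripts/acceptance.py`)

The acceptance script recomputes, from scratch: the quasi-steady-state
deviation at speed ratio 100 (≈0.004); the closed-form anchors (0.5,
0.25, 2/3); toggle label-swap symmetry and the negative-feedback
stationarity residual; the oscillator classifications; cascade peak
order; the multistable winner count over seeded random starts (1); the
stripe domain count (2); wave monotonicity violations (0) and the
cell-autonomy deviation; the worst-case enhancer-switching mismatch over
2-fold changes of `θs`, `λ`, `k_ts`, `k_td` (0.10); and the case-study
mismatches (0.60 additive vs 0.03 competitive).

## Limitations

- Deterministic ODEs only: no transcriptional bursting, stochastic
  (Gillespie) kinetics, or TF condensates.
- The binding model treats one operator with single-species cooperativity;
  cooperative binding *between* different TFs is not modeled.
- No reaction–diffusion patterning, no 2-D/3-D tissue, no growth
  mechanics: elongation is represented only by a retracting gradient.
- A single gene responding to two thresholds of one gradient is outside
  the rate laws implemented; the two-gradient and cross-repression
  circuits are the provided workarounds.
- Scenario defaults are this package's documented choices where the
  underlying models specify only orderings or signs; conclusions that
  depend on exact boundary positions should be checked against the sweep
  driver rather than read off a single default run.
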