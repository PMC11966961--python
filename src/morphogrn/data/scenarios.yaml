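# Scenario registry: defaults are data, not code constants, so every
# modeling choice made where the source models leave a gap is auditable.
# Families: dose_response | logic_surface | motif | spatial.
#
# Conventions: nondimensional units (k_t = lam = 1 unless stated); spatial
# scenarios run a 100-cell tissue with integer cell positions 0..99 and a
# gradient whose high end sits at x = 0 (slope k < 0).

sim05:
  title: steady-state transcript level vs activator concentration
  anchor: single-activator dose-response curve saturating at k_t/lam
  family: dose_response
  params: {role: activator, n: 1.0, K: 1.0, k_t: 1.0, lam: 1.0, x_max: 10.0, n_points: 201}

sim06:
  title: steady-state transcript level vs repressor concentration
  anchor: single-repressor dose-response, maximal at zero repressor
  family: dose_response
  params: {role: repressor, n: 1.0, K: 1.0, k_t: 1.0, lam: 1.0, x_max: 10.0, n_points: 201}

sim07:
  title: cooperative activation sharpens the dose-response switch
  anchor: Hill-coefficient comparison (n = 2 vs n = 5) of the activation curve
  family: dose_response
  params: {role: activator, n: 2.0, K: 1.0, k_t: 1.0, lam: 1.0, x_max: 10.0, n_points: 201}

sim08:
  title: two activators on independent sites (OR logic)
  anchor: additive occupancy surface over an (A, B) concentration grid
  family: logic_surface
  params: {logic: or_independent, K_A: 1.0, K_B: 1.0, n: 1.0, k_t: 1.0, c_max: 5.0, n_points: 41}

sim09:
  title: two activators competing for one site (competitive OR)
  anchor: saturating shared-site surface over an (A, B) grid
  family: logic_surface
  params: {logic: or_competitive, K_A: 1.0, K_B: 1.0, n: 1.0, k_t: 1.0, c_max: 5.0, n_points: 41}

sim10:
  title: two activators required simultaneously (AND logic)
  anchor: multiplicative occupancy surface over an (A, B) grid
  family: logic_surface
  params: {logic: and_product, K_A: 1.0, K_B: 1.0, n: 1.0, k_t: 1.0, c_max: 5.0, n_points: 41}

sim11:
  title: mutual-activation positive feedback (both-on / both-off toggle)
  anchor: bistability of the two-activator loop under high and low starts
  family: motif
  params: {kind: pos_feedback_act, theta: 0.5, n: 4.0, lam: 1.0, t_end: 30.0}
  initial_conditions: [[0.0, 0.0], [1.0, 1.0]]

sim12:
  title: mutual-repression positive feedback (one-high / one-low toggle)
  anchor: the two-repressor toggle resolves to opposite states from mirrored starts
  family: motif
  params: {kind: pos_feedback_rep, theta: 0.5, n: 4.0, lam: 1.0, t_end: 30.0}
  initial_conditions: [[1.0, 0.0], [0.0, 1.0]]

sim13:
  title: activator-repressor negative feedback (homeostasis)
  anchor: stable expression levels held near the binding thresholds
  family: motif
  params: {kind: neg_feedback, theta_xy: 0.5, theta_yx: 0.5, n: 4.0, lam: 1.0, t_end: 60.0}
  initial_conditions: [[1.0, 0.0]]

sim14:
  title: two-activator/one-repressor loop oscillates
  anchor: cyclic expression of the three-gene mixed feedback loop
  family: motif
  params: {kind: act_act_rep_oscillator, theta: 0.15, n: 4.0, lam: 1.0, t_end: 200.0}
  initial_conditions: [[0.5, 0.1, 0.0]]

sim15:
  title: repressilator (three cyclic repressors) oscillates
  anchor: periodic expression of the three-repressor ring
  family: motif
  params: {kind: repressilator, theta: 0.15, n: 4.0, lam: 1.0, t_end: 200.0}
  initial_conditions: [[0.5, 0.1, 0.0]]

sim16:
  title: multistable mutual-repression network (winner-take-all)
  anchor: one gene stays active while all others are silenced
  family: motif
  params: {kind: multistable, M: 4, theta_s: 0.1, n: 4.0, lam: 1.0, t_end: 60.0}
  random_ic: {low: 0.0, high: 0.1}

sim17:
  title: de-repression genetic cascade (domino activation)
  anchor: sequential gene peaks ending with the last gene high
  family: motif
  params: {kind: cascade, N: 5, theta_s: 0.1, theta_w: 1.0, n: 4.0, lam: 1.0, t_end: 60.0}
  cascade_ic: true

sim18:
  title: open-chain de-repression oscillator
  anchor: cyclic sequential expression when the last gene releases the first
  family: motif
  params: {kind: chain_oscillator, N: 3, theta_s: 0.1, theta_w: 1.0, n: 4.0, lam: 1.0, t_end: 200.0}
  cascade_ic: true

sim19:
  title: threshold (French Flag) readout of one static gradient
  anchor: four genes activated/repressed at strong/weak thresholds of M
  family: spatial
  operation: french_flag
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.1, x0: 50.0}
    K: [0.1, 0.5, 0.1, 0.5]
    n: 4.0
    lam: 1.0
    t_end: 20.0

sim20:
  title: interior expression domains from two opposing gradients
  anchor: mirror-symmetric domains bounded away from both tissue ends
  family: spatial
  operation: two_gradient
  params:
    n_cells: 100
    m1: {form: static_sigmoid, k: -0.2, x0: 35.0}
    m2: {form: static_sigmoid, k: 0.2, x0: 64.0}
    K_strong: 0.1
    K_weak: 0.7
    n: 4.0
    lam: 1.0
    t_end: 20.0

sim21:
  title: nested feed-forward ladder refines one gradient into five domains
  anchor: abutting ordered domains from threshold activation plus cross-repression
  family: spatial
  operation: nested_feedforward
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.1, x0: 50.0}
    N: 5
    theta_s: 0.1
    theta_w: 1.0
    n: 4.0
    lam: 1.0
    t_end: 30.0

sim22:
  title: two stripes from the sum of two repressed enhancers
  anchor: one expression domain per enhancer under opposing gradients
  family: spatial
  operation: additive_stripes
  params:
    n_cells: 100
    m1: {form: static_sigmoid, k: -0.25, x0: 45.0}
    m2: {form: static_sigmoid, k: 0.25, x0: 54.0}
    K_strong: 0.1
    K_weak: 0.7
    n: 4.0
    lam: 1.0
    t_end: 20.0

sim23:
  title: speed regulation; morphogen-scaled cascade with kinematic waves
  anchor: expression waves travel from high to low M and slow down
  family: spatial
  operation: speed_regulation
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.1, x0: 50.0}
    N: 5
    theta_s: 0.1
    theta_w: 1.0
    n: 4.0
    lam: 1.0
    t_end: 120.0
    speed_scope: full_rhs

sim24:
  title: enhancer switching (dynamic + static enhancers, additive)
  anchor: sequential waves freeze into an ordered pattern at low M
  family: spatial
  operation: enhancer_switching
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.2, x0: 50.0}
    n_genes: 5
    theta_s: 0.1
    theta_w: 1.0
    n: 4.0
    lam: 1.0
    k_td: 1.0
    k_ts: 1.0
    integration: additive
    t_end: 120.0
    mut_flag: 0

sim25:
  title: additive enhancer integration under an overactive enhancer
  anchor: a 10x overactive dynamic enhancer on gene 3 disrupts the additive pattern
  family: spatial
  operation: enhancer_switching
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.2, x0: 50.0}
    n_genes: 5
    theta_s: 0.1
    theta_w: 1.0
    n: 4.0
    lam: 1.0
    k_td: 1.0
    k_ts: 1.0
    integration: additive
    t_end: 120.0
    mut_flag: 1
    mut_gene: 3
    mut_factor: 10.0

sim26:
  title: competitive enhancer integration buffers an overactive enhancer
  anchor: promoter-limited integration preserves the pattern under the same perturbation
  family: spatial
  operation: enhancer_switching
  params:
    n_cells: 100
    gradient: {form: static_sigmoid, k: -0.2, x0: 50.0}
    n_genes: 5
    theta_s: 0.1
    theta_w: 1.0
    n: 4.0
    lam: 1.0
    k_td: 1.0
    k_ts: 1.0
    k_ed: 1.0
    k_es: 1.0
    integration: competitive
    t_end: 120.0
    mut_flag: 1
    mut_gene: 3
    mut_factor: 10.0
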