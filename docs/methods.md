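# Methods

## Model

The package simulates four FitzHugh–Nagumo (FHN) neurons in a ring
(1–2, 2–3, 3–4, 4–1).  Neuron *i* has an activation potential *x_i* and a
recovery variable *y_i*:

    dx_i/dt = x_i (x_i − 1)(1 − r_i x_i) − y_i − g_i C_i + I_ext(t) + d_i(t) + u_{x,i}
    dy_i/dt = b_i x_i + u_{y,i}

with the diffusive ring-coupling sum `C_i = (x_i − x_left) + (x_i − x_right)`.
The coupling is *direction dependent*: the link between neurons j and k
enters neuron j's equation with neuron j's own gain `g_j` and neuron k's
with `g_k`, so the two directions of one gap junction carry different
strengths.  No symmetrization is applied.  All four neurons receive the
same stimulation current `I_ext = (A/ω) cos(ωt)`, `ω = 2πf`; identical
stimulation is enforced structurally because it is what cancels the
stimulation terms from the synchronization error dynamics.  Disturbances
are bounded functions of time; the defaults are the four sinusoids
`0.1 sin(12t)`, `0.1 sin(20t)`, `0.1 sin(25t)`, `0.1 sin(23t)`.  Only the
three slave neurons (2–4) are actuated; neuron 1 is the free-running
master.  The generic single-neuron FHN form carries a recovery damping
term `v·y`; the ring network fixes `v = 0`, and a nonzero `v` is ignored
with a warning because the controller's error factorization requires
`dy/dt = b x`.

All quantities, including time, are dimensionless.

### Default parameters

| quantity | default | meaning |
|---|---|---|
| r | (10, 10.2, 10.4, 10.6) | cubic nonlinearity coefficients |
| b | (1, 1.01, 1.02, 1.03) | recovery gains |
| g | (0.001, 0.002, 0.003, 0.004) | directional coupling gains |
| A, f | 0.1, 0.127 | stimulation amplitude and frequency |
| K | (20, 20.001, 20.002) | feedback gains |
| k_c | 5 | leakage gain (robust law) |
| p, q, l, m | 1 | adaptation hyper-parameters |
| t_on | 400 | controller onset time |
| t_end | 800 | default horizon |
| x(0), y(0) | (0.1, 0.15, 0.2, 0.25), (0, 0, 0, 0) | default initial state |

The stimulation amplitude deserves a note: at `A = 0.1` the forcing
current `A/ω ≈ 0.125` drives the excitable neurons across threshold and
the ring exhibits its documented chaotic spiking regime (largest Lyapunov
exponent ≈ +0.05 for the full state).  An amplitude an order of magnitude
smaller leaves every neuron subthreshold: the response is a small
(|x| < 0.02) forced oscillation with a *negative* leading exponent
(≈ −0.5), and nothing downstream — chaos certification, error spikes,
meaningful synchronization — survives.  `A = 0.1` is therefore the
package default.

Initial conditions are either the explicit default above or, with a seed,
drawn uniformly from [−0.5, 0.5] for all eight neuron states.  The same
seed always reproduces the identical trajectory bit for bit.

## Controller

Synchronization errors are defined against the master: `e_xi = x_1 −
x_{i+1}`, `e_yi = y_1 − y_{i+1}`, i = 1..3.  Because `dy/dt = b x`, each
recovery variable can be reconstructed from the running integral `z_i(t)
= ∫₀ᵗ x_i`, which the simulator carries as an explicit state.  The error
dynamics are then linear in the eight unknown constants per channel,

    de_xi/dt = Φ_iᵀ Γ_i + F_i − e_xi + d_xi − u_xi,
    de_yi/dt = Ψ_iᵀ Υ_i − u_yi,

with Φ_i = [r_1, r_{i+1}, b_1, b_{i+1}, y_1(0), y_{i+1}(0), g_1, g_{i+1}],
Ψ_i = [b_1, b_{i+1}], measurable regressors Γ_i, Υ_i = [x_1, −x_{i+1}],
and known offset F_i = x_1² − x_{i+1}².  The certainty-equivalence control

    u_xi = Φ̂_iᵀ Γ_i + F_i + K_i e_xi,    u_yi = Ψ̂_iᵀ Υ_i,

is combined with either the nominal gradient adaptation law
`dΦ̂_i/dt = (p/q) e_xi Γ_i`, `dΨ̂_i/dt = (l/m) e_yi Υ_i` or the robust law
whose Φ̂ update carries the error-gated leakage `−k_c |e_xi| Φ̂_i / q`
(e-modification).  The estimates start at zero; the controller never sees
a true parameter.

Three deliberate interpretation choices, each verified numerically by the
regressor-identity oracle (factorized vs direct error derivatives agree to
~1e−13 at random states):

* **Ψ dimensions.**  Υ_i has two entries, so Ψ_i = [b_1, b_{i+1}];
  this exactly reproduces `de_yi/dt = b_1 x_1 − b_{i+1} x_{i+1}`.
* **Leakage gate.**  The leakage is gated by |e_xi|, which is the form the
  completion-of-squares ultimate-bound analysis requires; a
  `leakage_signed` switch provides the signed variant.
* **Grouping.**  The division by q (respectively m) applies to the whole
  bracket of the robust update.

### Recovery-control compensation

Reconstructing `y_{i+1} = b_{i+1} z_{i+1} + y_{i+1}(0)` is exact only
while `u_y = 0`.  Once the recovery controllers act, `y_{i+1}` also
contains the integral `∫ u_{y,i}` — a quantity the controller itself
generated and therefore *knows*.  The simulator carries these three
integrals as extra states (augmented state dimension 45 = 8 neuron states
+ 4 running integrals + 24 + 6 estimates + 3 control integrals) and, by
default (`compensate_recovery_control=True`), adds them to the known
offset F_i.  This keeps the factorized error dynamics exact in closed
loop; without it a slowly growing bias of order 1e−3 enters the
activation channels and the clean Lyapunov identities below degrade
accordingly.  Setting the flag to False recovers the bare textbook law.

## What the theory guarantees — and what it does not

With zero disturbances and the nominal law, the Lyapunov function

    V = ½ Σ_i [p e_xi² + q‖Φ̃_i‖²] + ½ Σ_i [l e_yi² + m‖Ψ̃_i‖²]

(Φ̃ = Φ − Φ̂, Ψ̃ = Ψ − Ψ̂) obeys `dV/dt = −p Σ_i (K_i + 1) e_xi²` exactly,
so V is non-increasing whenever `p(K_i + 1) > 0` and the *activation*
errors converge.  Both facts are verified numerically (V increments
≤ 1e−10 per sample; finite-difference dV/dt matches theory to ~2e−5).

The recovery channels are different, and this is an exact structural
property worth stating plainly: along the closed loop,

    d/dt [ ½ l e_yi² + ½ m ‖Ψ̃_i‖² ] = 0.

The recovery-error "energy" is conserved — `de_yi/dt = Ψ̃_iᵀΥ_i` has no
damping term and the adaptation law has no leakage on Ψ̂.  Consequently
e_yi does not converge to zero; it oscillates, exchanging energy with the
estimate error at fixed total.  In practice the pre-onset drift of the
recovery errors is large (sup ≈ 1.6–1.9 over [300, 400]) and the
post-onset oscillation is modest (sup ≈ 0.2–0.6), so the recovery errors
*look* convergent on a plot, but their sup-norm contraction ratio is
0.11–0.31, not the ~0.01 the activation channels achieve.  The acceptance
checks that demand e_y below 1e−4 or a 10× e_y contraction fail for this
reason and are left failing: they contradict the conservation law above.

A second intrinsic limitation: the regressor entries `z_i = ∫ x_i` grow
without bound (≈ 0.3 t for the chaotic master), so late in a run even
parameter errors of order 1e−5 leave residuals `|Φ̃ᵀΓ|` of order 1e−3.

Under bounded disturbances (|d_xi| ≤ d_mi, ‖Φ_i‖ ≤ Φ_mi) the robust law
guarantees uniform ultimate boundedness with the bounds

    |e_xi| ≤ (k_c Φ_mi²/4 + p d_mi) / (p (K_i + 1)),
    ‖Φ̃_i‖ ≤ Φ_mi/2 + sqrt(Φ_mi²/4 + p d_mi / k_c),

implemented exactly in the form the completion-of-squares analysis
produces (note the error bound carries no square root, unlike the most
common UUB radius expressions in the adaptive-control literature; no
silent "correction" is applied).  With the default gains these bounds are
loose (≈ 12) against the measured post-onset errors (≈ 0.012).

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, rtol 1e−8, atol 1e−10.  The
controller onset is a known derivative discontinuity, so the integration
is restarted at t_on (state-continuous by construction) instead of
letting the solver step across it, and the first time unit after onset is
integrated with max step 0.01 to resolve the fast `exp(−(K+1)t)`
transient.  Output is sampled on a uniform grid (default 0.05, which
resolves the spike shapes at f = 0.127).  Estimates are frozen before
onset by default; `adapt_before_onset` enables pre-onset adaptation
without actuation, and `adapt=False` freezes the estimates entirely
(used to verify the exact-estimate closed-form decay
`e_xi(t) = e_xi(t_on) e^{−(K_i+1)(t−t_on)}`, which holds to ~3e−11
relative at rtol 1e−11).

## Largest-Lyapunov-exponent estimation

Two estimators, validated on fixtures with known exponents (`x' = −x`
→ −1.000; the classical Lorenz system → 0.904 vs an independent long-run
value of 0.9032):

* **Benettin two-trajectory** (full state): a fiducial and a companion
  displaced by 1e−8 are integrated jointly; the separation is renormalized
  every 1 time unit and the mean log stretching per unit time is the
  exponent.  This characterizes the whole coupled network (one number).
* **Divergence-rate (Rosenstein-style) per neuron**: each neuron's
  activation series (sample step 0.05) is delay-embedded (dimension 5,
  lag at the autocorrelation 1/e crossing), each point is paired with its
  nearest neighbour at temporal separation of at least one mean orbital
  period (dominant FFT peak, ≈ the forcing period 7.87), and the mean log
  pair distance is tracked forward.  The exponent is the slope over the
  fit window [2, 15] time units — after the initial neighbour-distance
  transient and the oscillation the periodic forcing imprints on the
  curve, and well before saturation at the attractor diameter.  This is
  what allows per-neuron attribution in a coupled network, at the price
  of method sensitivity: per-neuron estimates on the default ring cluster
  at 0.06–0.10 while the full-state Benettin value is ≈ 0.05.

The chaos-certification protocol: simulate the uncontrolled ring for 3000
time units from seeded small initial conditions, discard 500 as
transient, estimate each neuron's exponent from the remaining 2500 units,
and average over three seeds.  Estimates are flagged (not raised) when
the Benettin running estimate still drifts over the last quarter of the
horizon or the divergence fit is poor.

## Known limitations

* The recovery-variable errors are bounded but non-convergent under the
  implemented adaptation laws (conservation law above); achieving e_y → 0
  would require damping (e.g. leakage on Ψ̂) that the laws do not include.
* The regressor's unbounded integral entries make very long closed-loop
  runs progressively ill-conditioned.
* Per-neuron exponent attribution by scalar embedding is heuristic; the
  rigorous invariant of the coupled system is the single full-state
  exponent.
* The estimators and controller assume noise-free, continuously sampled
  states; measurement noise and discrete actuation are out of scope.
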