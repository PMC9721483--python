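# Methods

This note documents the model conventions, numerical choices and scaled-down
protocols behind `rloed`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Model and information dynamics

The chemostat auxotroph model has state `(C0, C1, N)` — two hidden nutrient
concentrations (g/L) and the measured population density (cells/L) — with
double-Monod growth and dilution at rate `q`. Nominal parameters:
μ_max = 1 h⁻¹, K0 = 6.8×10⁻⁵ g/L, K1 = 4.9×10⁻⁴ g/L, γ0 = 4.8×10¹¹ cells/g,
γ1 = 5.2×10¹¹ cells/g, q = 0.5 h⁻¹. The uniform design/inference prior box
for the focal parameters is μ_max ∈ [0.5, 2], K0 ∈ [10⁻⁵, 10⁻⁴],
K1 ∈ [10⁻⁴, 10⁻³]. The yields are practically unidentifiable from `N` alone
and `q` is experimentally set, so the FIM is restricted to
(μ_max, K0, K1).

**Full-state sensitivities.** The sensitivity equations are propagated for
the whole state vector, not just the measured output: the growth rate
depends on the hidden concentrations, so a sensitivity system closed over
`N` alone would be inconsistent. Only the measured row (the `N`
sensitivities) enters the information increment. Sensitivities are
log-scaled (`θ_j ∂X/∂θ_j`), which keeps the FIM well-conditioned across
parameters spanning four orders of magnitude. Correctness is verified
against a central-finite-difference oracle to better than 10⁻³ of the
sensitivity scale over the full 20 h trajectory.

**Noise convention.** The measurement error is Gaussian with a 5%
*coefficient of variation*: sd(ε) = 0.05·N, i.e. Σ = (0.05·N)². Two
considerations fix this choice. First, only a relative noise model makes
D-optimality invariant to the unit the population is expressed in (an
invariance the test suite asserts at 10⁻⁶). Second, the reported accuracy of
downstream parameter estimates in this system is consistent with ~5%
standard-deviation noise and inconsistent with the alternative readings
"variance = 5% of N" (which gives near-noiseless data in cells/L) or
"variance = (0.05)·N²" (22% noise). The linear-variance reading remains
selectable (`NoiseModel(convention="variance_linear")`). Inside the
information increment the population is floored at 10³ cells/L so a washed-out
culture cannot produce a singular covariance; the study's initial conditions
keep `N` ten orders of magnitude above this floor.

**D-optimality and rewards.** The score is `log |I|`, computed from the
eigenvalues; a singular or near-singular FIM (smallest eigenvalue < 10⁻³⁰)
scores a finite sentinel of −10⁶ rather than −∞, so first-interval rewards
stay finite. The per-step reward is the increment in `log |I|` with the
baseline `log |I(0)| := 0`, which makes every episode's return *exactly*
equal to its final D-optimality (asserted for arbitrary policies). Time is
in hours throughout; the FIM accumulates per hour.

**Integration.** The 18-dimensional augmented system (3 states, 9
sensitivities, 6 unique FIM entries) is integrated with the stiff-capable
LSODA solver at rtol 10⁻⁸ / atol 10⁻¹⁰, with the right-hand side (including
hand-derived analytic Jacobian and parameter partials) JIT-compiled.
Chaining two one-hour intervals agrees with a single two-hour interval to
10⁻⁶ relative; each interval's FIM increment is symmetric PSD by
construction and asserted via eigenvalues.

## Episode protocol and observations

Ten 2 h sample-and-hold intervals; fixed initial condition
(C0, C1, N) = (1 g/L, 0, 2×10¹⁰ cells/L); inputs bounded to [0.01, 1] g/L.
Observations are taken at the start of each interval and are noiseless model
outputs — measurement noise enters only when simulated datasets are
generated for parameter fitting, matching the role noise plays in the
physical setup (the reward is a training-time construct, the data are not).

Six observation formulations are supported: with the current measurement,
the nine FIM entries and the scaled step index (Ia, input size 11), the same
without the index (Ib, 10), measurement plus index (IIa, 2), measurement
only (IIb, 1), and the recurrent pair (IIIa/IIIb) in which the full history
of scaled measurements and inputs is consumed by a GRU encoder. Scalings:
population divided by 5×10¹⁰ by default (for prior-spanning runs a square
root followed by a calibrated divisor, with episodes whose scaled
observation exceeds 1 discarded as unstable and resampled); step index
divided by 10; FIM entries divided per-element by the maxima observed in a
seeded random-action trial run (floored at 1); value-regression targets
divided by 100. Note the nominal-parameter carrying capacity implied by the
yields above is ≈4.8×10¹¹ cells/L, so nominal-model training runs use a
population divisor of 5×10¹¹ to keep observations in [0, 1].

## Agents

**Fitted Q-learning.** Q-network: two ReLU layers of 100 over the
observation, linear output of 100 (the 10×10 action grid); a recurrent
variant prepends two GRU layers of 64. After every episode the network is
re-initialised and regressed on bootstrapped targets
`r + γ(1−d)·max_a Q(o′,a)` computed with the previous network over the full
append-only memory (γ = 1: finite horizon, undiscounted, so values stay on
the D-optimality scale). Exploration: ε(e) = clip(1 − log₁₀(e/A), 0, 1)
with ε(0) = 1 and A = E/11, which holds ε = 1 for the first A episodes and
reaches 0 at 10A, before training ends. The printed form of this schedule in
the source material is garbled; the adopted formula is the unique common
form satisfying both stated endpoint properties. The inner regression
(Adam, learning rate 10⁻³, batch 256, one pass per iteration by default) is
deliberately light; the toy-MDP oracle test uses many passes to reach exact
dynamic-programming values.

**Recurrent TD3.** Twin critics and an actor, each a 2×64 GRU encoder over
the (measurement, input) history followed by two ReLU layers of 128; the
critic head additionally consumes the candidate action, the actor squashes
its output through a sigmoid onto the input box. Targets use the minimum of
the two target critics at a smoothed target action
(`clip(π_targ(o′) + clip(ξ, −c, c))`, ξ ~ N(0, σ)); the actor is updated
every second critic update, and target networks track the live ones by
Polyak averaging. Unstated hyperparameters follow the original TD3
conventions: ρ = 0.995, σ = 0.1 and c = 0.25 in scaled action units,
batch 128, one update per environment step, γ = 1. Episodes are simulated
in batches of 10; with a fixed policy and matched seeds, batched and
sequential simulation produce the same transition multiset (asserted).
Exploration: with probability ε a uniform action, otherwise actor output
plus N(0, 0.2ε) noise in scaled units, clipped to the box.

All networks are plain-numpy (float32) with manual backpropagation and Adam;
gradients are verified against finite differences in float64. On one CPU a
critic-plus-actor update at batch 128 takes ~60 ms, which sets the scale of
the training protocols below.

## Classical designers

The greedy one-step-ahead optimiser (OSAO) maximises the end-of-interval
`log |I|` one interval at a time: a 10×10 grid over the input box seeds a
bounded L-BFGS-B polish (finite-difference gradients, step 10⁻⁴). Each
greedy step matches a 50×50 brute-force grid to within 1% of the step's
gain (asserted on a short horizon). The full-horizon designer ("MPC" — one
open-loop NLP over all 20 input variables, no receding horizon) runs six
multistart restarts (the OSAO design, the box midpoint, four uniform random
points) with a budgeted ascent, then polishes the best restart; seeding
with the OSAO design guarantees MPC ≥ OSAO. The landscape is genuinely
multimodal: random restarts routinely beat the OSAO-seeded one by several
log-units, and the best random *design* (not restart) typically beats the
greedy OSAO score itself — greedy myopia is expensive in this system
because early information-greedy inputs starve the culture the later
intervals need.

## Evaluation pipelines

**Value fitting.** Two independent datasets (train/test) of random-policy
episodes, one uniform prior draw per episode, actions uniform on the
discrete grid; per-step returns are suffix sums of rewards (the identity
G(o_τ) = r_τ + G(o_τ+1) holds exactly by construction). A value network per
observation formulation is regressed on the scaled training returns and
scored as unscaled test MSE. The package's scaled-down protocol uses 300
parametrisations per split, five seeds, and 100 (feed-forward) / 40
(recurrent) epochs — sized so the whole study runs in minutes; held-out
error was observed to rise well before 800 epochs, so longer training only
overfits. At this scale the qualitative ordering of the full-scale study
reproduces: the history-reading recurrent formulation (IIIa) predicts
returns best, the FIM-reading (Ia) and measurement+time (IIa) formulations
are close behind, and removing the time index from the memoryless
formulation (IIb) is crippling (≥3× the IIa error).

**Inference quality.** Simulated measurements are drawn on a 3-minute grid
(dt = 0.05 h, 401 points per experiment) — the near-continuous
optical-density readout of a benchtop chemostat — with 5% CV Gaussian noise,
negative draws floored at zero. The focal parameters are refit by weighted
nonlinear least squares in log₁₀-parameter space within the prior box
(weights = model noise sd at the observed values; analytic Jacobian from the
sensitivity equations; trust-region reflective solver; three seeded
restarts). Metrics over replicates are truth-normalised: the normalised MSE
averages ((θ̂−θ)/θ)² over focal parameters and converged replicates, and
log|cov| is the log-determinant of the sample covariance of the θ̂/θ
vectors — the only convention that makes parameters four orders of magnitude
apart commensurable. Noiseless data reproduce the true parameters to
<0.1%; with noise, μ_max is recovered to well under 1% while the two
half-saturation constants remain weakly identified and occasionally pin at
the prior bounds, which makes the empirical estimate covariance much
tighter than an unconstrained analysis would give.

## Scaled-down study protocols

The published-scale protocols (tens of thousands of training episodes, ten
independent agents) are reduced to workstation scale as the package's
defaults for its own study runs:

* RT3D learning progress: 400 episodes, batch 128, one update per step,
  single seed — the greedy policy ends ~5 log-units above the random-policy
  mean (the test asserts ≥ 2).
* Value fitting: 300 parametrisations per split, 5 seeds (above).
* MPC: 6 restarts × 60 budgeted iterations + a 200-iteration polish.
* Inference: 30 replicates, 3 restarts per fit.

What the synthetic studies do and do not show: all data here are generated
by the same ODE model the designers optimise against, so passing tests
demonstrate the correctness and internal consistency of the machinery —
sensitivity propagation, reward telescoping, estimator behaviour, learning
progress — not robustness to model misspecification, real measurement
artefacts (drift, autocorrelated noise), or actuation limits of a physical
bioreactor. Training over the parameter prior (supported and tested via the
sampling mode and stability filter) addresses parametric uncertainty only.

## Known limitations

* The D-optimality scale depends on the measurement-noise convention; under
  this package's convention the nominal-model scores are OSAO ≈ 2.8 and
  MPC ≈ 11.7. Conventions that rescale the noise or the population unit
  shift all scores by a constant without changing the optimal designs.
* The greedy OSAO is a weak baseline here (see above); conclusions about
  "RL sits between greedy and full-horizon optimisation" are
  landscape-dependent.
* The NLP gradients are finite-difference; with 20 variables a full MPC
  solve costs a few minutes of ODE integrations on one CPU.
* Fitted Q-learning trains on the entire memory after every episode by
  design (no replay subsampling), so its cost grows quadratically with
  episode count; it is practical only for short studies.
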