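# Methods

## Generative task model

A trial is a single scalar decision: the initial reach direction, in
degrees, clockwise positive. The hand angle is the motor command plus
Gaussian execution noise; the cursor is the hand plus the imposed
rotation; the observation is the cursor plus Gaussian perceptual noise,
or absent when no cursor is shown. Reward is the indicator of the cursor
crossing within a 6°-wide target (boundary inclusive — "within the
target area" is read as a closed zone), minus an optional quadratic motor
cost `λu²`. λ defaults to 0 because the experimental feedback itself is
binary and a zero cost keeps the generative reward and the reward used by
the fitting filter identical; the quadratic term is available by
configuration. Within-movement kinematics, online corrections and the
10 cm transport are not modelled.

Schedules: 40 zero-rotation baseline trials, a ±1°-per-40-trials ramp to
magnitude 8, an 80-trial hold, and experiment-specific extra plateau
blocks (96 trials for the first experiment, 3×48 for the generalization
experiment, 2×48 for the endpoint-error experiment). The first experiment
ramps clockwise (+8°), the other two counter-clockwise (−8°).

## The learner

Two memories add into the command `u = (target − p̂) + x_r + η`:

* **Estimator.** A scalar Kalman filter tracks the perturbation with
  retention `A` and process noise `q` (time update `p̂⁻ = A p̂`,
  `P⁻ = A²P + q`) and corrects by the sensory prediction error
  `y − (u + p̂⁻)` with gain `K = P⁻/(P⁻ + σ_y²)`. Without an observation
  the gain is structurally zero, so a reward-only learner's `p̂` stays at
  its initial value exactly. A matrix backend over the extended state
  (hand, perturbation, target) is provided and agrees with the scalar
  reduction to 1e−9; the hand component carries no uncertainty because
  the efference copy determines it up to noise, and the target is known.
* **Action selector.** One reach is one TD step: the successor value is
  the current critic value, giving `δ = r + γv − v` (γ = 0 reduces this
  to `δ = r − v`). The critic moves by `α_c δ`; the actor offset moves by
  `α_a δ η` along the executed search noise — a REINFORCE-style
  eligibility, the standard actor-critic realization of "update the
  policy by the reward prediction error".

The perceived hand position is the forward-model prediction
`ĥ = u + p̂`: as the estimator absorbs the rotation, `ĥ` migrates toward
the cursor while the actual hand moves the other way, so the modelled
localization illusion is `ĥ − h ≈ p̂`. (The algebraically tempting
alternative `ĥ = y − p̂` equals the true hand whenever the estimate is
accurate and therefore predicts *no* illusion; it is not used.)

### Defaults and units

| parameter | default | units | rationale |
|---|---|---|---|
| retention `A` | 0.99 | — | slow perturbation drift prior |
| process noise `q` | 0.01 | deg² | keeps a small steady-state gain |
| obs. noise sd | ERR 1.0, EPE √8, RWD — | deg | EPE ≈ 8× ERR variance; RWD channel absent |
| motor noise sd | 1.0 | deg | typical endpoint variability |
| search noise sd | ERR 0.5, EPE 1.0, RWD 1.5 | deg | exploration grows as vision degrades |
| actor/critic lr | 0.15 | — | mid-range, stable on 496-trial sessions |
| discount γ | 0.9 | — | episodic task; config-overridable |
| motor cost λ | 0 | deg⁻² | binary task feedback; see above |
| initial state | p̂=0, P=1 deg², x_r=0, v=0 | | naive learner |

All defaults are config-overridable and are dumped next to every
simulation output. Under these defaults the continuous-vision learner is
rewarded on ~98% of adaptation-phase trials, the reward-only learner on
~88% of its final 100 trials, remapping falls from ~7.8° to ~0 as the
observation variance rises from 0.1 to 10⁶ deg², and adaptation stays
within 1° of the 8° plateau throughout — the reward channel absorbs what
the sensory channel loses.

Summary conventions: adaptation is |mean reach over the final window −
baseline mean|; reach variability uses the population-SD convention
(ddof = 0); the reward fraction is computed over adaptation-phase trials;
"remapping" is the mean `p̂` over the final window (the last-trial `p̂`
inherits per-trial noise when the gain is near 1, the windowed mean is
the steady-state quantity).

## Synthetic subjects

The learner generates each subject's adaptation series; the probe
responses are layered on phenomenologically because a scalar learner has
no direction tuning:

* **Localization** values are stored as pointing error relative to the
  actual hand. PRE errors are zero-mean noise; POST errors are
  `remap_fraction × terminal p̂` plus noise, i.e. the estimate is
  displaced opposite the compensatory reach change, toward the cursor.
  Ten probes per phase, mirroring the 4-shooting-+1-localization
  micro-block structure.
* **Generalization** probes use the 80-trial baseline-block composition
  (32 centre, 8 per peripheral direction in {±10°, ±20°, ±30°}, shuffled
  by seed) and transfer the terminal reach change with a Gaussian falloff
  `exp(−θ²/2w²)` in probe angle θ (a raised-cosine alternative is
  provided). Width defaults: ERR 25°, EPE 15°, RWD 8° — broad for
  sensory-driven learning, narrow for reward-driven learning.

Cohort structure is imposed by the config sampler. The coupled sampler
draws one latent reliance-on-vision variable per subject and maps it to
both the remap fraction and the generalization width; under a negative
rotation this makes the signed illusion more negative exactly when
generalization is broader, so the cross-subject correlation is negative
by construction — only its sign, not its magnitude, is a modelled claim.
The uncoupled sampler is the null. What passing tests show: the analysis
pipeline recovers the structure the generator put in; they do not show
that human probes follow a Gaussian transfer or that the latent-coupling
law is the true between-subject mechanism.

## Dual-memory fitting

Given observed reaches, imposed rotations and binary rewards, the filter
reconstructs both memories deterministically: the residual
`η_k = reach_k − x_p,k − x_r,k` is the inferred search noise and drives
the actor update, while the sensory prediction error is formed from the
imposed rotation (`p_k − p̂⁻`), driving the Kalman update. All memories
start at zero. Minimizing Σηₖ² (equivalently, the squared difference
between observed and model-predicted reaches) over the free parameters
uses trust-region-reflective least squares with bounds (variances > 0,
rates in [0, 1]) and ≥10 Latin-hypercube starts, deterministic given a
seed; the landscape is multimodal on short series, and below 50 trials
recovery fails routinely, so shorter series are rejected.

Free parameters: for ERR/EPE the triple (σ_y², shared actor/critic rate
α, process variance q) under the default mapping, or (σ_y², α_c, α_a)
with q fixed under the alternative `split_rates` mapping — the mapping is
a single configuration point. For RWD the gain is forced to zero and the
pair (α_a, α_c) is fitted. γ is fixed during fitting (not co-estimated);
the critic is co-updated with the actor's rate under the default mapping.

Identifiability, measured on synthetic data at the 496-trial session
length (20 seeds): the terminal memory split is recovered cleanly at the
extremes (all-sensory for ERR, all-reward with `x_p ≡ 0` for RWD) and as
a genuine mixture for EPE; the residual-variance ordering ERR < EPE < RWD
is recovered. The fit has a mild bias toward the sensory channel at few
starts because a high-gain estimator tracks the rotation almost as well
as the true mixture; 10 starts remove most of it. The learning rate is
identified only where the reward channel does real work (RWD, EPE);
on an ERR series the residual objective is nearly flat in α and the
fitted rate is not interpretable — rate-recovery assertions are
restricted accordingly.

## Numerical choices and limitations

* Search/motor noise draws are skipped (exact 0.0) when the configured
  sd is zero, so noiseless limits are exact, not merely small.
* `kalman_gain(0, 0)` is a degenerate-input error rather than a NaN.
* Simulations are bit-reproducible given a seed
  (`numpy.random.default_rng`); cohort members are re-seeded from the
  cohort seed.
* Problem sizes in the test-suite recovery studies: 20 subjects per
  condition at the full 496-trial schedule with 10 optimizer starts;
  sweep cells use 20 seeds. These sizes make Monte-Carlo margins
  comfortable for every asserted ordering.
* The generalization and localization *mechanisms* are phenomenological;
  the package deliberately does not model neural tuning, within-session
  proprioceptive drift, or opposite-hand pointing biomechanics. Group
  statistics are descriptive (no multiple-testing correction is applied,
  and none is claimed).
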