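# Methods

This note documents the model implemented by `ocddm`, the statistical
choices behind its fitting schemes, what the synthetic-data generator and
the recovery benchmark do and do not emulate, and the package's known
limitations.

## Model

The accumulator follows `dx = v dt + σ dW` between two absorbing
thresholds. The simulator uses the Euler–Maruyama form
`x_{k+1} = x_k + v Δt + σ √Δt η_k`, `η_k ~ N(0,1)`; a decision is triggered
at the first step where the transformed state `|z(x)|` reaches the bound
`b̂(t)` (constant `b` for the vanilla model, `exp(ω0 − ω1 t)` for the
exponentially collapsing variant, with ω1 < 0 — an expanding bound —
permitted), and the response time adds the non-decision latency `T_nd` to
the hitting time. Time units are arbitrary but must be consistent; all
package defaults are expressed in the dimensionless convention of the
reference setting `v = 1/2, x0 = 1, b = 10, σ = 4`, which yields ≈30%
errors.

Writing the state as `x_t = x0 + v t + σ √t η̃_t` defines the normalized
cumulative perturbation `η̃_t = Σ η_k / √(n_steps)`, standard normal at
every horizon in the absence of bounds. The bound-hit condition turns each
observed response time into the self-consistency identity quoted in the
README. Two properties matter downstream:

* **Joint scale invariance.** Rescaling `(v, x0, b, σ)` by a common factor
  leaves choices and response times exactly unchanged (with the package's
  scale-adaptive default step, even path-by-path under a shared seed). A
  single dataset therefore constrains only ratios unless the drift is
  known; this is the fundamental non-identifiability of the model.
* **Overshoot.** The discrete accumulator crosses the bound by a positive
  excess of mean ≈0.58 σ√Δt. Evaluated at the generating parameters, the
  self-consistency residual equals that overshoot converted to time
  (`o·δ/v`), so it shrinks as √Δt.

## Simulation step and horizon defaults

Two different accuracy demands, two defaults:

* `default_dt`: `σ√Δt = 0.05 · b̂(0)` — resolves the state space (the
  overshoot bias on outcome probabilities and moments is well below
  Monte-Carlo error at the benchmark sizes). Used everywhere data are
  generated in bulk.
* `fine_dt`: `σ√Δt = 10⁻³ · b̂(0)` — used when demonstrating the
  self-consistency identity itself, where the quantity of interest *is* the
  overshoot-dominated residual; at the reference setting the 95th
  percentile of `|y − g|/y` is then ≈1%.

The default horizon is ten times the slower of the drift time scale
`b/|v|` and the diffusion time scale `(b+|x0|)²/σ²`, capped for collapsing
bounds once the bound has decayed to a negligible height; non-absorbed
trials are flagged censored and excluded from fitting with a warning (the
model does not describe non-responses). Each trial consumes its own
counter-based RNG stream derived from `(seed, trial index)`, so datasets
are bit-reproducible.

## The no-barrier noise prior

Let `Q` be the observed proportion of correct responses (outcome matching
the sign of the trial's drift; drift exactly zero counts `+1` as correct —
a documented arbitrary tie-break). With `c = Φ⁻¹(1 − Q)`, the conditional
moments of the **drift-aligned** perturbation `ζ = sign(v) · η̃` are the
standard truncated-normal expressions

    μ_c = φ(c)/Q,        Σ_c = 1 + c μ_c − μ_c²      (correct trials)
    μ_e = −φ(c)/(1−Q),   Σ_e = 1 + c μ_e − μ_e²      (error trials),

which satisfy the total-expectation and total-second-moment identities
exactly. The sign alignment is essential with mixed-sign drifts: a correct
decision under negative drift hits the lower bound and requires a negative
perturbation. (An alternative transcription with the two denominators
swapped is kept behind `conditional_moments(..., printed_variant=True)`
for comparison; it violates the total-expectation identity away from
`Q = 1/2` and is not used.)

`enforce_moments` maps free per-trial dummies to perturbation estimates
whose within-group sample mean and population variance (denominator = group
size) equal these targets exactly, whatever the dummies — the
moment-enforcing device that caps the effective degrees of freedom of the
overcomplete model. `Q` is global (a single split point); see Limitations
for what this costs with collapsing bounds.

How good is the approximation? The conditional *signs* and the ordering are
always right, and across random parameter draws the predicted and sampled
conditional moments correlate at r ≈ 0.98. But bound hits exclude
near-zero perturbations (the marginal distribution of `η̃` is bimodal), so
sampled conditional means are systematically **more extreme** than the
truncated-normal prediction — by ~40% on average under the benchmark's
parameter distribution, and the package's tests assert exactly this
behavior rather than a perfect identity. In noise-dominated regimes the
amplification is largest (for a pure-noise hit, `η̃ = (b − x0)/(σ√τ)` is
bounded away from zero).

## The overcomplete inversion

The likelihood attaches a Gaussian residual to the self-consistency
identity. Three implementation decisions define this package's inversion
(each adopted after the simpler alternative demonstrably failed; the
residual scale and hyperparameters below are package choices — the
source formulation leaves them open):

1. **Bound-normalized evidence-scale residual.** The physical residual is
   the bound overshoot — an *evidence*-scale quantity. The fitted residual
   is `r_i = [x0 + v_i τ_i + σ √τ_i η̃_i − z⁻¹(o_i b̂(τ_i))] / |z⁻¹(b̂(τ_i))|`
   (τ = y − T_nd). Working on the raw response-time scale would weight
   trials by `1/v_i`, letting near-zero-drift trials dominate; working
   unnormalized would leave the likelihood scale-indifferent. The per-trial
   bound normalization keeps the outcome term `±1` in the residual, which
   blocks both the shrink (`b,σ,x0 → 0`) and the inflate (`ω1 → ∞`)
   degeneracies. Because overshoot is constant in absolute evidence units,
   the residual variance carries the known per-trial factor
   `(b̂(0)/b̂(τ_i))²` for collapsing bounds.
2. **Exact marginalization of the nuisances.** The residual is affine in
   each trial's `ζ_i`, so the Gaussian conditional prior `N(μ_g, Σ_g)`
   integrates out in closed form: each trial contributes
   `N(a_i + c_i μ_g, λ + c_i² Σ_g)` to the marginal likelihood. This is the
   exact counterpart of the fixed-form Gaussian (variational-Laplace)
   treatment of the per-trial nuisances, and it reduces the optimization to
   4–6 structural parameters plus `log λ`.
3. **An informative residual-variance prior.** The self-consistency
   likelihood conditions on the observed response times and therefore never
   "pays" for failing to explain their distribution; with a vague prior on
   λ the fit can drift along near-scale-free directions. λ (the variance of
   the bound-normalized residual) carries an inverse-gamma prior with shape
   2 and rate 3·(0.03)², centering it at the squared relative overshoot
   scale of the simulator's default step — the physically expected residual
   magnitude. This is the scale anchor of the whole inversion.

Unconstrained parameters carry standard-normal priors through the usual
maps (`b = e^{φ1}`, `σ = e^{φ2}`, `T_nd = min(RT)·s(φ3)`,
`x0 = b(2s(φ4)−1)`, `v = ballistic·(2s(φ5)−1)` with the ballistic limit
`(b+|x0|)/(min RT − T_nd)`; collapsing bounds use `(ω0, ω1)` untransformed).
The objective is maximized by a deterministic multi-start Nelder–Mead
simplex (five fixed starts, the drift-sign start oriented by the majority
outcome) with a Powell polish; the reported free-energy trace is the
best-so-far objective and is monotone by construction. The posterior
covariance is the inverse curvature (central differences) at the mode.
Per-trial noise estimates are the Gaussian-conditioning posterior means
passed through the moment-enforcing map, so their group statistics equal
the no-barrier targets exactly.

Fitting regimes: `full` (all five parameters; the drift-sign parameter
makes the fit non-singular), `fixed_drift` (drift known), `varying_drift`
(per-trial drift taken from the dataset, i.e. offset 0 and slope 1 on the
predictor). The affine drift mode `(v0, v1)` is deliberately not part of
the benchmark — freeing it reintroduces the scale degeneracy. A fit
requires at least two trials in each outcome class *and* each correctness
class; all-correct datasets are infeasible for the group construction.

## Baseline estimators and first-passage backends

The method of moments maximizes a bootstrap-weighted match (500 seeded
resamples; adjusted Fisher–Pearson skewness) of the seven statistics
{P(up), conditional RT mean/variance/skewness per boundary} plus the
standard-normal prior, with five seeded quasi-Newton starts. Classes with
fewer than 10 trials drop their unstable higher moments with a warning.
The method of trial means maximizes a Gaussian likelihood of each trial's
RT around its model-implied conditional mean (residual variance profiled
in closed form); by design it is blind to accuracy beyond the two
conditional means (an optional Bernoulli outcome term is available but off
by default — with it on, the estimator no longer shows the characteristic
weakness in the fixed-drift regime that defines its role in the
benchmark). With many distinct drifts the per-drift conditional means are
evaluated on a 13-point grid and PCHIP-interpolated. Both baselines are
deliberately restricted to the vanilla model even on collapsing-bound data
— they serve as robustness references, mirroring their standard usage.

Two deterministic backends stand behind them. The Markov-chain solver
propagates the exact Euler transition kernel (CDF differences over a
400-cell state grid, absorbing cells beyond ±b), conserves probability to
machine precision, and mirrors the simulator's discretization including
overshoot — it is the solver cross-checked against Monte Carlo at the
3-standard-error level. The moment backend solves the Feynman–Kac
hierarchy `(σ²/2) w_k'' + v w_k' = −k w_{k−1}` with an exponentially
fitted (Il'in) tridiagonal scheme, stable at any drift/diffusion ratio,
giving the continuous-diffusion conditional moments in ~1 ms — fast enough
to sit inside the baselines' optimization loops. The two differ by the
discretization bias (a few percent at the reference setting), which is
part of the estimation error budget, not of the comparisons.

## Recovery benchmark

Per replication: draw `φ ~ N(0, I)` on the unconstrained scale (the same
scale the fitters' priors live on), map to native parameters with a unit
reference time, simulate 200 trials, fit each method, and compare on the
common scale `(log σ, log b, x0, T_nd)` (+ `v` for the full set, `ω1` for
collapsing bounds). Three generation conventions make the benchmark
well-posed:

* The non-decision time is set after simulating the decision times so that
  `T_nd / min(RT) = s(φ3)` exactly — the same data-dependent
  parameterization the fitters use; a fixed-reference convention would park
  most truths at the edge of the prior.
* Varying-drift regimes draw the per-trial predictor i.i.d. normal scaled
  by the sampled drift magnitude; collapsing-bound decay rates are
  half-normal `|N(0,1)|` (spanning vanilla-like ≈0 to clearly collapsing).
* Draws whose dataset cannot support any fit (a degenerate outcome or
  correctness split, or majority censoring — up to a fifth of raw draws
  are near-deterministic) are rejection-resampled deterministically, and
  the redraw count is reported.

Metrics: per-parameter relative estimation error
`(est−true)²/mean(true²)` summarized as mean log REE (floor −30);
recovery matrices of squared partial correlations (controlling for the
other simulated parameters) in %; the identifiability index ΔV = mean over
rows of (diagonal − mean off-diagonal); paired contrasts of per-replication
mean log REE with a two-sided F-test (F = t² of the paired mean
difference). The REE and ΔV formulas are this package's committed
definitions. Failed fits are excluded listwise per method (contrasts stay
paired); a study aborts if any method fails on more than 10% of
replications.

Scales: the headline recovery quantities use 200 replications of 200
trials; the test suite's three-method comparisons use 100 replications.
At these scales the observed patterns are: method of moments best with a
fixed drift; worst with trial-varying drift (its moment targets lump
predictable and stochastic variability); the overcomplete approach
unharmed by collapsing bounds while both vanilla baselines degrade; and
overcomplete recovery-matrix diagonals of roughly 70–95% for
`(log σ, log b, x0, T_nd)` in the varying-drift and collapsing regimes.

## What the generator emulates — and what passing tests show

The synthetic data are exactly the model: i.i.d. trials, Gaussian
increment noise, no inter-trial parameter variability (no slow drifts of
attention, no sequential effects, no contaminant RTs, no lapses), censoring
only through the simulation horizon. Passing recovery tests therefore
demonstrates *internal* consistency — the estimators recover the
parameters of the process that generated the data — not robustness to the
mis-specifications real data carry. The value-experiment generator
likewise emulates only the qualitative structure of a default-bias design
(likeability values i.i.d. normal per item, the bias planted in the initial
condition, frames related by a per-trial relabeling) and carries no claims
about any particular empirical dataset.

## Known limitations

* The bound's decay rate `ω1` is poorly recovered (single-digit diagonal
  percentages) even though the other parameters of the collapsing model
  recover well: the global single-threshold noise prior cannot represent
  the decline of conditional perturbations with elapsed decision time, and
  the decay parameter absorbs that mis-specification. A time-resolved
  group structure would be the natural extension.
* With a fixed, known drift the overcomplete fit is noticeably weaker than
  both baselines (there is no trial-varying leverage, and the scale anchor
  carries most of the weight); use the method of moments in that regime.
* The no-barrier conditional means are biased low by ~40% under broad
  parameter sampling (see above); the inversion inherits a corresponding
  calibration bias in extreme regimes.
* The entropy limit `P(up) → 1/2` under `σ → ∞` holds only for `x0 = 0`;
  with an initial bias the drift-free limit is `(x0+b)/(2b)` (martingale
  argument), e.g. 0.55 at the reference setting.
* The self-consistency equation cannot generate data (the observed RT
  appears on both sides); the simulator is the only generator, and
  model-evidence comparison across DDM variants is out of scope.
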