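# Methods

This note documents the models implemented in `emosearch`, the assumptions
behind them, the defaults and why they were chosen, and the places where the
design was genuinely open.

## Task and data model

The package targets visual-search experiments in which a 3×3 grid of faces
is shown on every trial; on half the trials all faces are neutral
(target-absent), on the other half exactly one face is angry or happy (with
equal probability), and the participant answers whether all expressions were
the same. Each trial yields a reaction time (RT, seconds) and a yes/no
response; participants belong to age groups (school grades "I", "V", "IX").
Two separate models are fitted, mirroring the two behavioral channels:

1. an ex-Gaussian model of RTs per age group × display condition, and
2. an equal-variance signal-detection (SDT) model of accuracy per age
   group × target emotion.

The two channels are modelled (and simulated) independently given the
design: RTs do not depend on trial accuracy in the generator, and the
analyses never share parameters.

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions the analysis is
meant for: three groups, 96 trials per participant (48 target-absent, 24
angry, 24 happy — the split is exact, not stochastic; when the present half
of a custom trial count is odd, the extra trial goes to the angry target on
even participant indices and to the happy target on odd ones), group-level
ex-Gaussian parameters per group × condition and sensitivities per group ×
emotion taken from published posterior medians for this paradigm, and a
between-participant spread of 10% of the group value (Normal on µ and on
d′; lognormal on σ and τ to keep them positive; the decision threshold gets
an absolute SD of 0.10 because criteria can be zero). Trials per participant
and the spread are conventions — the source experiments report session
length, not trial counts — so both are configurable.

Responses come from the equal-variance SDT observer. Each participant has
one absolute decision threshold λ on the noise-distribution axis, shared
across emotions because the target-absent trials that generate false alarms
are common to both. Writing c_e = λ − d_e/2 recovers the familiar midpoint
parameterization (hit = Φ(d_e/2 − c_e), false alarm = Φ(−d_e/2 − c_e))
per emotion; the generator sets λ_i as the mean over emotions of
c_e + d_e,i/2. A literal shared-c-with-two-d parameterization would make
the false-alarm probability emotion-dependent, which is incoherent when
both emotions share one pool of target-absent trials — the shared-λ form is
the coherent reading.

RT draws are Normal(µ_i, σ_i) + Exponential(τ_i); non-positive draws are
rejected and redrawn (negligible probability at RT scales, but the
ex-Gaussian itself has support on all reals).

What the generator does **not** emulate: sequential effects (fatigue,
practice, post-error slowing), RT–accuracy coupling, response omissions,
block structure, and any dependence of RT on target position. Passing
recovery tests therefore show that the estimators are correct for the
assumed data-generating process, not that real children's data satisfy that
process.

For the salience modules the generator renders parametric face-like patches
(elliptical head, eyes, brows, mouth on a 0.5-gray background) with
controllable contrast, mouth curvature, brow angle and oriented grating
texture. These are stand-ins for posed-face photographs, which are
license-restricted; they reproduce the *structure* of the simulation
(nine distinct items, one target, randomized placement), not the appearance
of real faces.

## Outlier filtering

Tukey's rule with strict inequalities: drop v iff v > Q3 + 1.5·IQR or
v < Q1 − 1.5·IQR, quartiles by linear interpolation between order statistics
(numpy/R default; Tukey's original hinges differ on small samples, which is
why the convention is documented). Values exactly on a fence are kept, so a
zero-IQR sample loses nothing.

The **scope** within which fences are placed matters more than the rule.
Per participant × condition fences look natural given the large group ×
condition RT differences, but simulation shows they clip 2–4% of each
cell's own exponential tail at desk-scale cell sizes (24–48 trials), which
biases the downstream ex-Gaussian fit (τ collapses toward zero, µ rises to
absorb the mean). Participant-level fences — pooling the participant's
conditions — remove ~0.6–1.5% and leave parameter recovery intact, which is
also the removal rate regime reported for this paradigm. The pipeline
therefore defaults to `scope="participant"`; `"cell"` and `"global"` remain
options. Note the rule is *not* idempotent under re-estimated fences
(removal moves the quartiles inward), so the report records the fences
actually used.

RT models are fitted to correct trials only by default (`correct_only`),
since error-trial RTs mix detection failures with motor slips; the switch
is exposed because the convention is not universal.

## Ex-Gaussian model

Density (stable form used throughout, with z = (σ/τ − (t−µ)/σ)/√2):

    f(t) = 1/(2τ) · exp(−(t−µ)²/(2σ²)) · erfcx(z)

`erfcx` is the scaled complementary error function; this form avoids the
overflow of the textbook exponential form when σ/τ is large. For z below
−6 the expression is evaluated in its exact exponential-tail form
−log τ + σ²/(2τ²) − (t−µ)/τ, because the generic expression cancels
catastrophically there. Mean and variance are µ + τ and σ² + τ².

Hierarchy, per age group (groups are fitted as independent sub-models, with
that group's conditions jointly):

    µ_ic ~ Normal(M_µ[c], S_µ[c])
    log σ_ic ~ Normal(M_lσ[c], S_lσ[c])
    log τ_ic ~ Normal(M_lτ[c], S_lτ[c])
    rt ~ ExGaussian(µ_ic, σ_ic, τ_ic)

σ and τ are hierarchical on the log scale to keep them positive, so the
reported group-level σ and τ are exp of the log-scale means — the
between-participant *median*, which coincides with the generating value
under the generator's lognormal spread. Priors are weakly informative and
scale-adaptive: group means Normal centered on per-cell moment estimates
with SD 2× the data SD (µ) or 1.5 (log scales); between-participant SDs
half-Normal with scale 2× the spread of the per-cell moment estimates
(that spread overstates the true between-participant SD by the estimation
noise, keeping the prior conservative). The group-mean prior is not
truncated at zero: with RT data far from zero the truncated and
untruncated posteriors are numerically indistinguishable, and the
untruncated form admits an exact conjugate update.

## SDT model

Per participant: three latent quantities (d_angry, d_happy, λ) drawn from
group-level Normals; binomial likelihoods

    hits_e ~ Binomial(n_signal_e, Φ(d_e − λ))
    false alarms ~ Binomial(n_noise, Φ(−λ))

Priors: group means Normal(0, 2), between-participant SDs half-Normal(1) —
weakly informative on the probit scale. Reported quantities: group-level
µ_d per emotion and the criterion c_e = λ − d_e/2. `collapse_and_refit`
relabels the named groups to one pooled group and refits, giving the more
precise posterior that motivates collapsing comparable groups. The
point-estimate utility `dprime_point` (z(hit) − z(fa)) applies the 1/(2N)
edge correction only when rates are exactly 0 or 1 and the trial counts are
supplied; the Bayesian model needs no correction because the binomial
likelihood handles extreme counts natively.

## Posterior computation

No probabilistic-programming backend is assumed; both models share one
sampler (`emosearch.mcmc`) exploiting their common structure — conditionally
independent parameter blocks with Normal priors around group means. Per
iteration, all chains advancing together in vectorized numpy:

1. **Block updates.** Preconditioned MALA (Metropolis-adjusted Langevin)
   when an analytic gradient is available — both likelihoods provide one via
   numba kernels — otherwise random-walk Metropolis. Proposal covariances
   per block are adapted during warmup from the chains' pooled history; a
   per-chain scalar step adapts by Robbins–Monro (targets 0.574 for MALA,
   0.3 for the random walk). All adaptation freezes at the end of warmup.
2. **Group means**: exact conjugate Gibbs draws.
3. **Between-block SDs**: Metropolis on the log scale with the half-Normal
   prior (likelihood-free given the blocks, so several sweeps per iteration
   are effectively free).
4. **Non-centered translation**: a group mean and all of its blocks shift
   together, accepted on the likelihood and the mean's hyperprior. This is
   what gives group-level means fast mixing — their conditional posterior
   given the blocks is far narrower than their marginal.
5. **Non-centered rescale**: log S is perturbed with the standardized
   residuals held fixed (blocks move with S), one parameter component at a
   time — the standard interweaving remedy for the hierarchical funnel when
   the between-participant SD is small.

Presets: "desk" (ex-Gaussian: 4 chains × 5,000 iterations, 2,000 warmup;
SDT: 8 chains × 3,000/1,000 — the tiny SDT arrays make extra chains nearly
free and more chains sharpen the diagnostics) and "paper"
(2 chains × 50,000 iterations, 5,000 warmup) mirroring a published budget.
The desk presets were sized so that the group-level quantities reported in
the posterior summaries reach R̂ ≤ 1.01 with effective sample sizes above
~1,000 at the recovery-test problem sizes. R̂ (rank-normalized, via arviz)
and bulk ESS are recorded for every reported quantity; the fitted model
also records the maximum R̂ over *all* sampled quantities (including
participant-level nuisance blocks) and warns above the 1.01 threshold.
Convergence gating in `build_report` uses that maximum unless overridden.

Numerical details: the ex-Gaussian kernels evaluate log erfcx and its
derivative by linear interpolation of a 2¹⁵-point table over z ∈ [−8, 30]
(absolute error ~10⁻⁶; the public `exgauss_pdf` uses scipy's erfcx
exactly); Metropolis–Hastings then targets the table-approximated
posterior, a ~10⁻⁶ relative perturbation of the exact one. Initialization
is per-cell method-of-moments with per-chain jitter, so chains start
overdispersed. All randomness flows from a single seed through
`numpy.random.SeedSequence`, making every fit bit-reproducible.

## Decisions and effect sizes

Two cells are `credibly_different` iff their 95% credible intervals are
disjoint; a shared endpoint counts as overlap (the conservative reading of
an interval-overlap rule). The rule is symmetric and is applied to the
angry-vs-happy contrast per group for RT µ and for sensitivity d.

The δt standardized effect size is computed per posterior draw as the mean
difference divided by the square root of summed variance components, then
summarized by its posterior median and 95% CI. Which components enter the
denominator is genuinely ambiguous in multilevel models; the package's
choices, exposed through the `sd_components` argument:

- sensitivity contrasts: the pooled between-participant SD of d over the
  two emotions (no trial-level residual exists on the probit scale beyond
  the binomial likelihood);
- RT µ contrasts: the pooled between-participant SD of µ plus the pooled
  group-level within-person residual SD √(σ² + τ²).

δt is scale-invariant and its sign equals the sign of the mean difference.
Because the denominator convention and the generator's between-participant
spread both scale δt, its numeric values are comparable only within a
convention.

## Salience validation

The saliency model is the classic center-surround architecture: a 9-level
Gaussian pyramid; intensity, red–green and blue–yellow opponency (for color
input), and four Gabor orientation channels (0°, 45°, 90°, 135°);
across-scale differences between center levels {2, 3, 4} and surrounds
c + {3, 4}; the max-normalization operator N(·) that promotes maps with one
dominant peak (weight (1 − m̄)² with m̄ the mean of non-global local
maxima); per-channel conspicuity maps summed at a common scale, equally
weighted, and the result upsampled to input resolution. Grayscale inputs
skip the color channel. Two departures from a natural-image default are
deliberate:

- **Periodic boundaries** (`boundary="wrap"`). The displays are uniform
  3×3 grids with margins equal to half the item spacing, so periodic
  continuation makes every slot statistically equivalent; reflective
  boundaries give corner items systematically different surrounds (up to
  ±6% on the saliency index of identical items). With wrap, an
  all-identical display yields index 1 within ±0.5%.
- **A small floor on the N(·) weight** (10⁻⁴). The pure (1 − m̄)² weight is
  exactly zero for a display whose local maxima are all equal — precisely
  the homogeneous-display case the equating simulation must evaluate. The
  floor keeps such maps finite; since it scales a whole map, activation
  *ratios* (the saliency index) are unaffected. A uniform image still maps
  to exactly zero because its center-surround differences vanish before
  normalization.

The saliency index is total map activation in the target rectangle divided
by the mean activation of the eight distractor rectangles. The equating
simulation draws the target slot uniformly, fills the other slots with
distractor identities sampled without replacement, jitters positions,
renders, and computes the index; it reports per-emotion means, the mean
difference with its two-sample SE, and a 95% percentile-bootstrap interval
(2,000 resamples) — the interval construction for this quantity is not
standardized, and the bootstrap makes no distributional assumption.

Image motion between two frames: sum intensities in non-overlapping
20×20-pixel blocks ("blocks of 20×20 pixels", not a 20×20 grid of blocks —
the alternative reading is available via `block_size`), then sum the
absolute differences of the reduced images. Frames whose sides are not
multiples of the block size are zero-padded. The raw value scales with
intensity units and block count; `normalized=True` divides by the number of
blocks. The metric is symmetric, zero iff the reduced images are equal, and
satisfies the triangle inequality.

## Pipeline

`run_pipeline` sequences simulate/load → filter → ex-Gaussian fit → SDT
counts and fit → comparisons (angry vs happy per group, RT µ and d) →
report. Every artifact is written to the output directory and listed with a
SHA-256 checksum in `manifest.json` together with the seed and a config
hash; reruns with the same config and seed are bit-identical. Stage errors
carry the stage name; partial artifacts persist.

## Test-scale choices

Recovery tests run at 30 participants × 48 trials/condition (RT model) and
85 participants × 24 signal/48 noise (SDT), with 20 replicates each — sizes
at which a desk machine completes the suite in tens of minutes while CIs
are narrow enough to be informative. The end-to-end scenario (RT anger
advantage only in the oldest group, accuracy advantage everywhere) uses 18
participants × 192 trials and a 0.4 s µ gap in the oldest group: detecting
a ~0.2 s gap by CI disjointness, as the source studies do, requires their
~85 participants per group, which is beyond a unit-test budget. The
acceptance checks of these tests gate convergence on the group-level
quantities the analysis reports; participant-level R̂ is recorded and
warned on but not gated, being a noisy maximum over hundreds of nuisance
quantities.

## Known limitations

- The sampler is tailored to the two models' structure (independent blocks,
  Normal hierarchy); it is not a general PPL, and badly mis-specified
  likelihoods would need re-tuning.
- Group-level σ and τ are between-participant medians (log-scale means);
  studies reporting arithmetic group means of participant parameters would
  differ by a lognormal correction factor at large spreads.
- The equal-variance SDT assumption is untested within the package
  (no ROC data in a yes/no design); unequal-variance extensions are out of
  scope.
- The saliency implementation follows the published architecture but is not
  numerically identical to any specific toolbox; comparisons should be made
  within this implementation.
- Real RT data violate the generator's independence assumptions in known
  ways (sequential effects, lapses); recovery results bound estimator
  correctness, not robustness to those violations.
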