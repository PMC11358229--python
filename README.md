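# emosearch

Hierarchical Bayesian analysis of emotional visual-search experiments.

Developmental studies of the **anger superiority effect** (ASE) ask whether
children detect an angry face among neutral distractors faster or more
accurately than a happy one. A typical experiment shows 3×3 grids of faces;
on half the trials all nine faces are neutral, on the other half one face is
angry or happy. Two behavioral channels carry the answer: reaction times and
yes/no detection accuracy. `emosearch` implements the full analysis chain
for this design, plus the stimulus-validation computations used to show that
any effect is not a low-level salience confound:

- **Synthetic data generation** — trial tables with the exact design
  (half target-absent, present half split angry/happy), reaction times from
  per-participant ex-Gaussian distributions, responses from an
  equal-variance signal-detection observer, and parametric face-like image
  patches for the salience simulations.
- **Preprocessing** — Tukey-fence outlier removal (a value is dropped iff it
  lies strictly beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR) and reduction of trials
  to per-participant hit / false-alarm counts.
- **Reaction-time model** — the ex-Gaussian distribution (Normal(µ, σ)
  convolved with Exponential(τ); mean µ + τ, variance σ² + τ²) with
  participant-level parameters partially pooled toward group × condition
  means, estimated by MCMC (`HierarchicalExGaussModel`).
- **Detection model** — hierarchical equal-variance signal detection theory:
  participant sensitivity d′ per target emotion and one decision threshold,
  binomial likelihoods on hit and false-alarm counts
  (`HierarchicalSDTModel`, with `collapse_and_refit` for pooling age groups).
- **Inference** — credible-interval overlap decisions (two cells differ iff
  their 95% CIs are disjoint) and the δt standardized effect size (posterior
  of the mean difference divided by the summed-variance-component SD).
- **Stimulus salience** — center-surround (Itti–Koch-style) saliency maps
  with intensity, color-opponency and orientation channels; the saliency
  index of a 3×3 display (target activation ÷ mean distractor activation);
  a Monte-Carlo equating check over randomized displays; and the
  block-reduction image-motion metric (sum of |difference| of 20×20-pixel
  block sums).

Models follow scikit-learn conventions: configure in the constructor, call
`fit`, read trailing-underscore attributes (`posterior_`, `report_`).
Because no probabilistic-programming backend is assumed, the package ships
its own blocked Metropolis-within-Gibbs sampler with gradient-based (MALA)
block updates, non-centered translation/rescale moves for the hierarchical
funnel, and arviz R̂/ESS diagnostics.

## Worked example

```python
import emosearch as es

cfg = es.SimulationConfig(n_participants_per_group=10, rng_seed=7)
trials = es.generate_behavioral_dataset(cfg)
print(f"{len(trials)} trials from {trials.participant_id.nunique()} participants")

filtered, report = es.filter_trials(trials, scope="participant")
print(f"outliers removed: {report.n_removed} ({100*report.fraction_removed:.2f}%)")

counts = es.to_sdt_counts(trials)
post = es.fit_hierarchical_sdt(counts, random_state=7)
for g in ("I", "V", "IX"):
    a, h = post.median(g, "angry", "d"), post.median(g, "happy", "d")
    lo, hi = post.ci(g, "angry", "d")
    print(f"group {g}: d'_angry = {a:.2f} (95% CI {lo:.2f}-{hi:.2f}), d'_happy = {h:.2f}")
```

Output:

```
2880 trials from 30 participants
outliers removed: 89 (3.09%)
group I: d'_angry = 2.75 (95% CI 2.35-3.25), d'_happy = 2.49
group V: d'_angry = 2.90 (95% CI 2.51-3.38), d'_happy = 2.58
group IX: d'_angry = 2.88 (95% CI 2.54-3.26), d'_happy = 2.73
```

The generator's default sensitivities give every age group ("I", "V", "IX"
school grades) a higher d′ for angry than for happy targets; the fitted
group-level posterior medians recover that ordering already at 10
participants per group, with the 95% credible intervals quantifying the
remaining uncertainty. The same estimator exposes the criterion posteriors,
between-participant spreads, per-quantity R̂ and effective sample sizes in
`post.summary`.

The full chain — simulate (or load a CSV), filter, fit both models, compare
conditions, write a report with a checksummed manifest — runs as one call
(`emosearch.run_pipeline`) or from the shell:

```bash
emosearch run-all --out-dir results_run --participants 30 --seed 1
emosearch salience --reps 504 --seed 1 --out salience.csv --summary salience.json
```

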