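# imukit

Movement biomarkers from wearable inertial sensors for cerebellar ataxia.

Degenerative cerebellar ataxias impair the coordination, rhythmicity and
speed of movement.  Clinician-scored scales such as the Brief Ataxia Rating
Scale (BARS, 0–30) are coarse and require a clinic visit; wrist- and
ankle-worn inertial measurement units (IMUs) recorded during a few minutes
of standard clinical tasks — finger-nose-finger, fast alternating hand
movements, heel-shin — offer a direct, higher-resolution measurement of the
same motor phenomena.  `imukit` turns such recordings into two complementary
feature sets and uses them to estimate disease status and severity:

1. **Time-frequency features.**  Each tri-axial accelerometer/gyroscope
   stream is reduced to its first principal component (removing the
   dependence on sensor orientation), split into task and rest halves, and
   transformed with a wavelet synchrosqueezed transform (analytic bump
   wavelet, frequencies capped at 15 Hz).  Sixteen features per
   (task, side, modality) — band powers around the task cutoff, power
   ratios, center frequencies, spreads, temporal self-similarity — give
   192 features per session.

2. **Sticky AR-HMM features.**  The denoised (Symlets-4, threshold 0.04),
   10x-downsampled 2-D projections are modeled with a truncated sticky
   HDP-HMM whose emissions follow per-state vector autoregressions:

       x_t | x_{t-1} ~ Categorical(pi[x_{t-1}, :])
       y_t | x_t = k ~ MVN(A^(k) [y_{t-1}; ...; y_{t-n}], Sigma^(k)),  n = 5

   with priors beta ~ Dir(gamma/L), pi_i ~ Dir(alpha*beta + kappa*delta_i)
   (L = 5, alpha = gamma = kappa = 20) and a matrix-normal inverse-Wishart
   prior on each (A, Sigma).  Two-stage blocked Gibbs sampling learns shared
   dynamics on a small training subset, then per-recording state sequences.
   Twenty-seven summaries of the inferred segmentation (state frequencies,
   self-transition probabilities, run-length statistics, sample-mode
   concentration, entropy rate) per (task, side) give 162 features per
   session.

Disease-status classification uses a balanced random forest (200 trees,
per-tree bootstraps undersampled to the minority class); BARS regression
uses a 200-tree forest with depth 10 and an MAE criterion.  Everything is
evaluated under leave-one-subject-out cross-validation with pooled
out-of-fold metrics (AUROC, sensitivity/specificity, Pearson r, MAE,
test–retest reliability across repeat visits).

Clinical recordings of this kind are not publicly distributable, so the
package includes a seeded synthetic cohort generator that emulates the
structure the analysis assumes (rhythmic task motion below the band cutoff,
severity-scaled tremor and phase irregularity above it, arbitrary sensor
orientation, task/rest halves, repeat sessions).  See `docs/methods.md` for
the full model description and design choices.

## Worked example

Prior-predictive calibration of the sticky transition prior (the check that
motivates alpha = gamma = kappa = 20):

```bash
$ imukit prior-predictive --draws 1000 --seed 1
median run length: 156.25 ms (IQR 78.12-234.38 ms, 142485 runs from 1000 draws)
```

At these hyperparameters the expected self-transition probability is
E[pi_ii] = (alpha/L + kappa) / (alpha + kappa) = 0.6, so the median
latent-state run is 2 steps at 12.8 Hz = 156.25 ms: segments of one to a few
hundred milliseconds, a natural granule for parsing rhythmic movement.

A full synthetic-cohort analysis, end to end:

```python
from imukit.pipeline import PipelineConfig, analyze_cohort

cfg = PipelineConfig(seed=1)
cfg.generator.n_ataxia, cfg.generator.n_control = 25, 15
cfg.generator.repeat_fraction = 0.2
cfg.gibbs.stage1_iters, cfg.gibbs.stage1_burn, cfg.gibbs.stage1_truncate_at = 200, 20, 100

result = analyze_cohort(cfg)
clf = result["reports"]["classification"]
reg = result["reports"]["regression_bars_total"]
print(clf.auroc, clf.sensitivity, clf.specificity, clf.test_retest_corr)
print(reg.pearson_r, reg.mae)
```

which prints (about seven minutes on one CPU; the reduced Gibbs schedule is
the example/test default, the production schedule 2000/100/1000 is the
package default):

```
1.0 0.967741935483871 1.0 0.9987322028145263
0.9888462783567968 0.3552556724490583
```

i.e. on a 40-subject synthetic cohort with the default effect sizes the
balanced random forest separates ataxia from control perfectly (AUROC 1.0,
sensitivity 0.97 / specificity 1.0 at the 0.5 threshold), out-of-fold
classification scores are stable across repeat visits (test–retest r 0.999),
and predicted severities track the generated BARS-like scores (r 0.99,
MAE 0.36 points).  These numbers characterize the pipeline's sensitivity on
idealized synthetic signals, not clinical performance.

The same analysis is available from the shell with cached, resumable stages:

```bash
imukit run --seed 1 --out runs/demo      # writes features_*.csv, report.json
imukit report --out runs/demo
```

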