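# vmil

**Predicting trial-to-trial motor performance from pre-trial EEG.**

When people practice reaching movements — here, guiding a robot arm to 3D
targets — their performance improves along a slow learning curve. `vmil`
implements a complete cross-subject decoding analysis asking whether the
*current state* of that learning process is visible in the EEG recorded
*before* each movement (during rest or movement planning), and which
cortical rhythms carry the information. It is aimed at researchers in
motor learning, neurorehabilitation and brain–computer interfacing who
want a tested, reproducible reference implementation of this analysis —
including synthetic multi-subject cohorts with a known ground truth, since
no public recordings exist for this paradigm.

## The analysis

Per trial, performance is the **normalized time-to-target**
`TTT = movement time / start-to-target distance` (s/m). The decoding
chain:

1. common average reference; zero-phase 3rd-order Butterworth high-pass;
2. subjects pooled in time, reduced by PCA, whitened;
3. **SOBI** source separation — an orthogonal matrix **V** jointly
   diagonalizing the time-lagged covariances `C_τ` of the reduced signal
   (Jacobi rotations, closed-form Givens angles), giving independent
   components (ICs) with channel topographies; non-cortical ICs are
   rejected by automated spectral/topographic criteria;
4. per trial and IC, **log band power** (Hann window + FFT) in δ 0.1–4,
   θ 4–7, α/μ 8–14, β 20–30 and γ 55–85 Hz, low-pass filtered **across
   trials** at c = 0.1 rad/trial;
5. a **random forest** (bagged CART trees, random feature subsets)
   predicts the slow component of TTT under **leave-one-subject-out**
   cross-validation — trials within a subject are autocorrelated, so
   subjects are the exchangeable unit;
6. prediction quality per held-out subject is scored with

   R²_mod(x, y) = R²(x, y) / R²(x, LP(x, c)),

   the ordinary coefficient of determination rescaled by the best value
   achievable by a model band-limited below c (R²_mod = 1: all
   explainable slow variance explained; < 0: variance added). Group-level
   significance comes from a permutation test that independently shuffles
   each subject's trial order 10,000 times;
7. model interpretation: out-of-bag permutation **variable importance**
   and value-substitution **influence curves** per (IC, band) variable.

The companion generator simulates cohorts in which a latent learning
state jointly drives the TTT decline and the α/μ band power of designated
cortical sources, so source recovery, feature relevance, decoding and
inference can all be validated against ground truth. See
[`docs/methods.md`](docs/methods.md) for the model, parameter defaults,
calibration and known limitations (including an anti-conservatism
analysis of the trial-permutation test).

## Worked example

```python
from vmil import PipelineConfig, run

config = PipelineConfig(seed=7, n_perm=2000)   # default synthetic cohort
report, extras = run(config, keep_results=True)
results = extras["results"]["planning"]
print(results.summary())
```

```text
Cross-subject TTT decoding (leave-one-subject-out)
====================================================
subjects: 6   trials/subject: 200   features: 80
forest: 500 trees, min leaf 5, cut-off c = 0.1 rad/trial
----------------------------------------------------
            r2  r2_lowpass  r2_mod
subject
0        0.163       0.868   0.188
1       -0.189       0.916  -0.206
2        0.175       0.849   0.206
3        0.025       0.912   0.027
4        0.086       0.835   0.102
5        0.198       0.911   0.217
----------------------------------------------------
group mean R2_mod:   +0.089
group median R2_mod: +0.145
```

Each row is one held-out subject: `r2` is the plain coefficient of
determination of the prediction against that subject's standardized TTT,
`r2_lowpass` the best value any trial-domain band-limited model could
reach, and `r2_mod` their ratio — e.g. subject 5 explains about 22% of
its explainable slow TTT variance, subject 1's model adds variance
instead. Group-level inference and interpretation hang off the same
results object:

```python
perm = results.permutation_test(n_perm=2000, seed=0)
top = results.importance_summary(n_repeats=5, seed=0).head(3)
```

```text
group permutation test: observed mean R2_mod = +0.089, p = 0.0004998 (2000 permutations)

top variables by cross-fold importance:
               mean_importance  consistency
variable
ic07_alpha_mu            0.528        1.000
ic02_alpha_mu            0.122        0.667
ic01_alpha_mu            0.107        0.333
```

The permutation p-value is the position of the observed group-mean R²_mod
in the trial-shuffled null distribution (see `docs/methods.md` for why
this p-value should be read as a test of trial-exchangeability rather
than taken at face value). The top-ranked variables are α/μ-band powers —
the band whose generative sources were coupled to the learning state —
and their influence curves (`results.feature_influence("ic07_alpha_mu")`)
decrease monotonically: enhanced α/μ power predicts faster movements.

The same run is available from a shell:

```bash
vmil simulate --out data/                 # write a synthetic cohort
vmil run --config cfg.yaml --out out/     # full pipeline -> report.json
vmil report --in out/                     # summarize a previous run
```

## Layout

| module | contents |
| --- | --- |
| `vmil.simulate` | synthetic cohorts: learning curves, coupled oscillatory sources, linear mixing |
| `vmil.preprocess` | CAR, Butterworth high-pass, epoching, pooled PCA |
| `vmil.sobi` | lagged covariances, Jacobi joint diagonalization, IC rejection, Amari index |
| `vmil.features` | log band power, feature tables, trial-domain filter, TTT and its PSD |
| `vmil.model` | `TTTDecoder` / `DecodingResults`: LOSO forest decoding, summaries, plots |
| `vmil.evaluate` | R², R²_mod, group permutation test |
| `vmil.interpret` | OOB variable importance, influence curves, cross-fold aggregation |
| `vmil.calibration` | feature-level null-calibration harness for the permutation test |
| `vmil.pipeline` / `vmil.cli` | one-config orchestration, reports, `vmil` command |
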