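# betadesync

A synthetic, fully reproducible implementation of a classic motor-control
EEG analysis: **movement-related beta desynchronization (MRBD) during
bimanual motor planning and execution**, and its relation to aging and
task complexity.

The package is for researchers who want to exercise, test or teach this
analysis chain without access to raw EEG recordings: every input is
generated by seeded simulators whose ground truth is known, so each stage
of the pipeline can be validated by parameter recovery.

## The science

**Task.** In the bimanual tracking task (BTT) the two hands rotate dials
(left hand → ordinate, right hand → abscissa) to steer a cursor after a
dot moving at constant speed along an inclined line. Conditions are the
inter-hand frequency ratios 1:1, 1:3 and 3:1. Each trial is 1 s rest +
2 s planning + 5 s execution; a session is 4 blocks × 3 conditions × 13
trials = 156 trials. The per-trial score is the **tracking error**

```
TE = mean_t [ ‖c(t) − d(t)‖ + d⊥(c(t), line) ]
```

the time-averaged sum of the cursor-to-dot Euclidean distance and the
orthogonal cursor-to-line distance (normalized units; lower is better).

**MRBD.** Epochs (−3 to 3.5 s around execution onset) are decomposed with
complex Morlet wavelets (3–35 Hz) and dB-normalized against the
frequency-specific condition-average baseline at −2.5 to −2.2 s:
`dB(f,t) = 10·log10(P(f,t)/B(f))`. A grand-average matrix (all
participants × electrodes × conditions — blind to group) yields a
significance mask: each beta-band (13–30 Hz) cell in the planning
(−2–0 s) or execution (1–3 s) window is tested against the distribution
of rest-stage (−3 to −2 s) values at its frequency, with the Bonferroni
cell threshold `α / (n_frequencies × n_timepoints)`. The mean masked dB
value per participant × electrode × condition × stage is the MRBD
statistic (negative = desynchronization).

**Statistics.** Tracking error is modeled with an inverse-Gaussian,
identity-link GLMM (family chosen by AIC); MRBD with Gaussian LMMs over
CONDITION × GROUP × HEMISPHERE × REGION; all models carry a participant
random intercept, are reduced by backward stepwise elimination, and
significant effects are interpreted through pairwise contrasts with
Benjamini–Hochberg FDR correction. An association model regresses
tracking error on the twelve regional MRBD predictors, and Spearman
correlations relate right-central planning MRBD to performance per age
group. Inverse-Gaussian and Gamma mixed models are fitted by adaptive
Gauss–Hermite quadrature implemented in `betadesync.glmm` (cross-checked
against R's lme4 in the test suite).

## Worked example

```python
from betadesync import NeuralSimConfig
from betadesync.pipeline import process_cohort

out = process_cohort(NeuralSimConfig(n_per_group=4, n_trials=6, seed=21))
for stage, mask in out["masks"].items():
    print(stage, f"{mask.included_fraction:.1f}%")
```

prints

```
planning 64.7%
execution 100.0%
```

— the execution-stage mask covers every candidate beta cell (the injected
execution desynchronization, −2.3 to −4.7 dB, dwarfs the rest-stage
variability), while the planning mask covers only the post-onset part of
the window, because planning desynchronization in the generator develops
about 0.8 s after the cue. Comparing extracted to injected depths for the
same cohort:

```
                    injected  extracted
stage     region
execution central      -4.07      -4.09
          frontal      -2.61      -2.29
          parietal     -3.28      -3.27
planning  central      -0.79      -0.80
```

The masked extraction recovers the injected ground truth to a fraction of
a dB. `examples/` contains five narrative scripts covering the behavior
simulator, the EEG generator, the time-frequency stage, masking and
extraction, and the full study (`python examples/05_full_study.py`).

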