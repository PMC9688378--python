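# Methods

This note documents the models, generators and numerical choices behind
`betadesync`, in the spirit of the methods documentation of simulation
packages: what is simulated, what the defaults mean, and what passing
tests do and do not establish.

## Task simulator and tracking error

The bimanual tracking task is simulated in a normalized first-quadrant
frame: the target line has length 1 and the dot traverses it at constant
speed during the 5 s execution stage, sampled at the 100 Hz encoder rate.
Absolute dial angles are not defined by the task description, so
cumulative rotation is pre-normalized — the condition's required rotation
ratio (1:1, 1:3, 3:1) is carried entirely by the line angle
`atan2(left_factor, right_factor)`, and per-hand gains are equal. The
on-screen display flip (the real task draws in the lower-right screen
quadrant) is presentation-only and omitted. The familiarization block is
not simulated; no analyzed data would derive from it.

The behavior model is deliberately minimal: cursor velocity equals the
target velocity delayed by `lag_s`, plus independent Gaussian
angular-velocity noise per hand (`motor_noise_sd`, units per sample), plus
a coupling term that pulls the slow hand's speed toward the fast hand's
by fraction `coupling`. This is the smallest controller that produces the
qualitative pattern the statistics must detect: noise raises error
uniformly, coupling selectively penalizes the non-iso-frequency
conditions, and a noise-free controller scores exactly zero. The
controller is feedback-free; it does not correct accumulated error the
way a human using the on-screen feedback would, so per-trial error grows
with drift rather than saturating. Defaults (younger: noise 0.0020, lag
0.05 s, coupling 0.18; older: noise 0.0058, lag 0.10 s, coupling 0.33)
were calibrated once so that group and condition mean tracking errors
fall in the ~0.06–0.27 range with older > younger and non-iso > iso.

Tracking error uses the infinite line for the orthogonal term (clipping
to the segment would double-count the Euclidean term at the endpoints)
and averages over all 500 execution samples at the encoder rate.

The session schedule is a greedy constrained shuffle: within each block
every condition appears equally often, and a candidate condition is
rejected whenever it would push any ordered transition count more than
one step out of balance with its reverse; construction restarts on dead
ends and is seed-deterministic.

## Synthetic EEG generator

Each epoch spans −3 to 3.5 s around execution onset (t = 0) at a default
256 Hz (the pipeline is sampling-rate agnostic; 256 Hz keeps the 13–30 Hz
band far below Nyquist at desk-scale cost). Only the six electrodes of
interest (F3/F4, C3/C4, P3/P4) are synthesized. A channel is the sum of

* spectrally shaped 1/f Gaussian background (exponent 1.0, RMS 0.02),
* a 20 Hz sinusoid with randomized phase whose amplitude envelope encodes
  the experimental structure, and
* a slow (< 1 Hz) multiplicative amplitude modulation of the oscillation
  (SD 0.2), emulating the waxing and waning of real beta activity.

The envelope is `a_rest · 10^(D(t)/20)`: amplitude is modulated and depths
are stated in power dB, so dB bookkeeping is exact (10·log10 for power,
20·log10 for amplitude, everywhere). `D(t)` is 0 during rest, ramps
(100 ms raised cosine) to the planning depth at −1.2 s — desynchronization
builds up while the movement is prepared, which is also what makes the
planning mask cover roughly 60% of its window instead of all of it — and
steps to the execution depth at t = 0. Default depths follow the
qualitative structure of sensorimotor aging studies: strongest centrally,
planning slightly left-lateralized with small condition offsets,
execution right-lateralized and 1–1.5 dB deeper in the older group
(−2.3 to −4.7 dB); resting beta amplitude is 30% higher in the older
group. A per-participant planning-depth offset (SD 1 dB, shared across
electrodes and conditions) models stable individual differences; the
pipeline correlates it with log motor noise (r = 0.56 older, 0.14
younger), so deeper planning desynchronization goes with better tracking
in the older group.

The beta-to-background ratio is intentionally high. The generator's job
is parameter recovery — the masked dB extraction must return the injected
depths — and a strong oscillation keeps the dB values at off-center beta
rows from being diluted by background power. Real EEG has far lower SNR,
single-trial variability of many origins, artifacts, and broadband rather
than single-frequency beta; passing recovery tests therefore validates
the *pipeline arithmetic* (decomposition, baselining, masking,
extraction, statistics), not robustness to realistic noise. The amplitude
modulation is stage-independent and multiplicative, so expected dB depths
are unchanged while rest-window power acquires realistic temporal
variability; it is the parameter that controls how far mask significance
extends into the ramp tails.

## Time-frequency stage

Complex Morlet wavelets on a linear 3–35 Hz grid (33 frequencies), cycle
count rising linearly from 3 to 10, unit-energy normalization, FFT
convolution with reflect padding by one maximal wavelet half-length, and
8-fold output decimation (31.25 ms steps). The wavelet bank is
precomputed per (sampling rate, epoch length) and reused across epochs.
Cells whose wavelet half-length reaches past an epoch boundary are marked
edge-invalid and excluded from the mask's rest sample — the rest window
starts exactly at the epoch edge, where the reflected oscillation
produces a spurious transient. The cycle counts trade temporal for
spectral resolution; at the top of the band the spectral SD is
f/cycles ≈ 3.3 Hz, so tone energy concentrates within roughly ±4 Hz.

dB normalization divides by the frequency-specific baseline B(f): the
mean over the −2.5 to −2.2 s window of the across-condition average
power, per participant and electrode (a per-condition baseline is
available but off by default). Zero or negative baselines raise; nothing
is silently floored.

## Mask and extraction

The grand average is the cellwise mean of every participant × electrode ×
condition dB matrix, blind to group. Candidate cells are beta rows
(13–30 Hz) in the stage window. Each cell is scored against the rest
distribution at its frequency with a two-sided single-observation t-test
(prediction-interval form, `t = (cell − rest_mean)/(s·√(1+1/n))`,
df = n−1): this statistic is exactly t-distributed when stage and rest
cells share one distribution, so with the Bonferroni cell threshold
`α/(n_freqs × n_times of the full grid)` a stationary null yields
essentially zero inclusions, while the strong execution effect includes
every candidate cell. Scoring against the rest *mean's* standard error
instead would inflate the statistic by √n and admit ~a third of null
cells; the distribution form is the one whose operating characteristics
match the procedure's intent. Inclusion is by p-value only; a
desynchronization-only (`negative_only`) option exists and is off by
default. The extracted MRBD value is the arithmetic mean of a matrix's
dB values over the masked cells of a stage; an empty mask raises rather
than returning zero.

Because the planning mask includes ramp-adjacent cells where the effect
is still building, extracted planning MRBD is mildly diluted relative to
the plateau depth (a property shared by any mask-average statistic);
execution extraction is unbiased to within a few hundredths of a dB.

## Mixed models

All models have exactly one random intercept (participant). Gaussian
identity models are fitted by the exact closed-form marginal likelihood
(per-group covariance σ²I + τ²J via the Woodbury identity, analytic
gradient, L-BFGS-B); inverse-Gaussian and Gamma models with identity,
log or inverse links are fitted by adaptive Gauss–Hermite quadrature
(11 nodes; per-group integrand mode and Fisher curvature located by
Newton steps, nodes centered and scaled there). Identity links can
propose invalid (non-positive) means; those node evaluations are
penalized and mode-search steps are damped, never silently clipped.
Both objectives share one likelihood machinery, so AIC values are
comparable across families; `k` counts fixed effects + 2 variance
parameters. Standard errors come from the numerical Hessian at the
optimum; when a variance parameter sits on its boundary the fixed-effect
block of the Hessian is inverted alone. Agreement with statsmodels
MixedLM and R lme4 is asserted in the test suite (~1e-5 on estimates and
log likelihood for the Gaussian case).

Per-term tests are Wald chi-square (recorded on the fit). Backward
stepwise elimination removes, per step, the least-supported term among
those not contained in a retained interaction, using likelihood-ratio
tests at α = 0.05 (AIC-based removal available); the full trace is
returned and reproducible. Family selection fits the candidate list in
declared order and takes the lowest AIC among converged fits, ties going
to the earlier candidate. Pairwise contrasts are differences of
estimated marginal cell means (design rows averaged over the other
categorical factors, covariates at their mean), Wald z tests,
BH-FDR-adjusted within each contrast family — not across the whole
analysis. Spearman correlations use midranks; p-values are exact
(full permutation enumeration) for n ≤ 10 and t-approximate above. A
Q-Q/Shapiro residual diagnostic is available (`qq_diagnostic`) and never
gates the pipeline.

The association model regresses per-participant-condition mean tracking
error on the twelve regional MRBD predictors plus group and condition.
With the shared per-participant planning trait the planning predictors
are strongly collinear, so stepwise reduction may retain a proxy
predictor; the pipeline therefore also reports the central-right planning
slope from the minimal model (group + condition + that predictor) when
stepwise did not retain it. The MRBD × group and MRBD × condition
interactions are part of `association_model`'s default but are switched
off in `run_all`'s default configuration: the desk-scale cohort's 60
participant-condition rows cannot identify ~50 fixed-effect columns.

## Study sizes and determinism

The default study is 10 participants per group, the full 156-trial
behavior session, and 12 EEG trials per condition at 256 Hz — chosen as
the package's desk-scale operating point; recovery and directional
properties are stable at this size. Simulation-based test checks use
100 replicates for GLMM coverage (39 participants × 12 trials) and 200
replicates for stepwise retention/drop rates. Every stage seed derives
from the master seed via SHA-256, so reruns are byte-identical; output
tables carry a provenance header with the configuration hash and seed.

## Known limitations

* The behavior controller has no feedback correction and no trial-level
  learning or fatigue; blocks differ only by sampling noise.
* The EEG generator is six electrodes, one oscillation at one frequency,
  no artifacts, no volume conduction, and high SNR; preprocessing
  (filtering, ICA, surface Laplacian) is out of scope because inputs are
  born clean.
* Post-movement beta rebound is not modeled.
* Random slopes, Satterthwaite degrees of freedom, and cluster-based
  permutation statistics are not implemented; per-term tests are Wald.
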