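# Methods

## Generative model

Sounds are represented as a nonnegative spectrogram (default 30
log-spaced channels, 125–8000 Hz, 10 ms bins). `N` binary features
switch independently between on and off; per bin, an off feature turns
on with probability `p_on` and an on feature turns off with `p_off`.
While on, feature `j` adds its predictive field `q_{·j} ≥ 0` to each
receptor's Poisson intensity on top of a baseline `q_{i0}`. Time bins
are 0-based, left-aligned, half-open `[t·dt, (t+1)·dt)`.

**Rates vs probabilities.** Switching is public as rates in 1/s and
converted internally with `p = min(rate · dt, 1)`. The canonical values
`r_on = 1 Hz`, `r_off = 20 Hz` give per-bin probabilities 0.01 and 0.2
at `dt = 10 ms` — a mean on-time of 50 ms and a stationary on-fraction
of `r_on/(r_on + r_off) ≈ 4.8%`. Values this large cannot be per-bin
probabilities, which is why the rate convention was adopted.

**Baseline floor.** `q_{i0}` is floored at `1e-6` so that likelihood
ratios stay finite; the baseline acts as one always-on feature and is
never represented as a column of `Q`.

## Inference

Each detector carries the log-odds `L_j(t)` of its feature. One update
is: the prior ratio propagated from the previous posterior through the
two-state transition, plus the Poisson log likelihood ratio evaluated
under a mean-field substitution — all *other* features replaced by their
posterior probabilities from the previous bin. Updates are synchronous:
every detector reads the same previous-bin state, with no within-bin
sweeps. `L` is initialized at the stationary prior log-odds.

The likelihood ratio has an exact form, `Σ_i s_i log(1 + q_{ij}/ŝ_i^j)
− q_{ij}`, and a linearized form dropping the log (valid for
`q ≪ ŝ`). The exact form is the default (`use_log1p_exact=True`); with
one feature, or disjoint feature supports, it makes the filter *exact*
(equal to full 2^N forward filtering), which the test suite asserts at
1e-10 / 1e-6. An enumeration oracle (`exact_filter_oracle`, guarded at
N ≤ 12) provides the reference.

The firing-rate readout is the rectified *linearized* new evidence,
using the previous bin's posteriors inside `ŝ^j`:
`f_j = [Σ_i (s_i q_{ij}/ŝ_i^j − q_{ij})]_+`. Two conventions were
genuinely open and decided here: the `−q_{ij}` term sits inside the
rectified sum (the two groupings differ only when rectification binds),
and the readout uses `p(t)` from the previous bin, consistent with
interpreting `f_j` as newly arriving evidence. Real-valued inputs
(trial-averaged rates) are evaluated by the same formulas.

Division guards: predicted inputs `ŝ^j` and prior ratios are floored at
`epsilon_floor = 1e-9`; with `q0 > 0` this is a no-op in normal
operation.

**No-inhibition ablation.** The likelihood denominator is the baseline
`q_{i0}` instead of other detectors' predictions; prior propagation,
readout, rates and gain are shared with the intact model so the two are
comparable.

**A note on dynamics.** With strong per-bin evidence and heavily
overlapping fields, the synchronous mean-field update can alternate
between competing detectors on consecutive bins (a known artifact of
parallel fixed-point iterations). The phenomenology fixtures therefore
use moderate intensity scales where disambiguation takes a few bins.

## Learning

E step: one inference step per bin. M step: one stochastic-gradient
ascent step on that bin's Poisson log likelihood,
`Δq_{ij} = η · p_j(t) (s_i(t)/λ̂_i(t) − 1)`, followed by clipping at
zero (the PF cone is part of the model). `q0` and the switching rates
are fixed. The per-epoch objective is the mean per-bin log likelihood
(up to the `s!` constant); learning aborts if it becomes non-finite.

No learning rate or schedule is canonical for this model; the default is
`η = 1e-3` with an optional `1/epoch` decay, which satisfies the
monotonicity check on the single-feature fixture. The parameter-recovery
study uses `η = 5e-3` for 10 epochs on `T = 2·10^4` bins with five
planted fields at overlap 0.7 and "random bump" initialization (uniform
noise in `[0, 0.1·peak]` plus a Gaussian bump of 2-channel width at each
field's peak channel). Substantial spectral overlap is essential to the
inhibition contrast: with lightly overlapping fields the feedforward
ablation recovers the fields almost as well as the intact model, because
competition is rarely exercised. Recovery is scored by optimal bipartite
matching (Hungarian assignment) on the column-correlation matrix, ties
to the lowest index.

## Filter estimation

Encoding filters solve `min Σ_t (r(t) − Σ_{i,τ} h_i(τ) s_i(t−τ))^2`,
i.e. `h = C_SS^{-1} C_Sr`; decoding filters the converse
`g = C_RR^{-1} C_RS`. Both are computed as centered ridge regressions
(the estimate is a whitened cross-covariance; an intercept absorbs the
means — without centering, a constant response would produce a spurious
flat filter). The penalty grid is logarithmic, `1e-4 … 1e4` in 13
steps; cross-validation folds are contiguous time blocks (shuffled bins
would leak through temporal autocorrelation), ties to the smaller
penalty, refit on all data at the chosen value. Lagged designs are
zero-padded at the edges to preserve length alignment.

The SRF is the encoding filter restricted to a single delay (30 weights
plus one optimized response delay → 31 free parameters per neuron at
the canonical binning). The extracted PF is the frequency-only decoding
filter: because responses lag the stimulus, the stimulus is shifted back
by 0–200 ms in 10 ms steps and the single shift maximizing the
channel-averaged training reconstruction is kept — one global shift for
the joint fit, since the regression couples all neurons per channel.
PFs are rectified and unit-max normalized before entering the model;
a completely negative decoding vector yields a flat PF and is flagged
for exclusion, mirroring the neuron-selection rule (single-neuron
reconstruction cc > 0.2, all-negative filters dropped).

Reconstruction accuracy is reported as the per-channel Pearson cc
averaged over channels (per-fold values are also available); widths of
one-dimensional filters are full width at half maximum around the
positive peak (linearly interpolated, in channels or octaves), with a
±1/±2-octave mass fraction as a more robust alternative.

## Prediction pipeline

`run_predict` extracts PFs on each training fold, runs the intact and
no-inhibition models over the stimulus, fits the SRF baseline
(rectified linear convolution), aligns each prediction to its paired
neuron by a training-set-optimal delay (0–200 ms, fixed for the test
fold), and scores Pearson cc plus first/second-derivative cc on the
held-out fold; 10 contiguous outer folds, 5 inner folds for ridge.

Three global parameters govern the Bayesian predictions: `r_on`,
`r_off`, and a gain. The gain multiplies the **PF matrix**, not the
stimulus: extracted PFs are unit-max shapes, and under the exact
log-likelihood a stimulus scalar is *not* equivalent to restoring the
PFs' intensity scale (it rescales the evidence itself). With the gain on
the PFs the model is exactly self-consistent — re-running inference with
the true fields and the matching gain reproduces the generating model's
rates. When a `gain_grid` is supplied the gain is chosen once, on the
first training fold, and held fixed. The model baseline `q0` defaults to
the per-channel 10th percentile of the stimulus.

## Synthetic data

The fixture generator emulates the target recording regime: 30
log-spaced channels, 10 ms bins, five stimulus repetitions. Planted PFs
are Gaussian bumps with controlled overlap (overlap 0 truncates
supports to exact disjointness) or harmonic stacks (fundamental plus
partials at one and log2 3 octaves, amplitudes 1/0.6/0.4) for a crude
speech-likeness. Stimuli are the noiseless intensity `q0 + QX` by
default; optional Poisson observation noise makes the spectrogram
full-rank, which the reverse-correlation fixtures need (a noiseless
stimulus lies in the feature subspace and the whitened regression
returns minimum-norm filters for *any* response model). Neuron banks
run the chosen inference model on the fixture stimulus and emit
per-trial Poisson counts around the model rates; the 5-trial average
plays the role of recorded rates.

What the generator does **not** emulate: formant trajectories or any
quantitative speech statistics, non-Poisson variability, across-trial
adaptation, and — critically — response variance that is not a function
of the stimulus. Real cortical responses are shaped by unrecorded
neurons and intrinsic dynamics; synthetic bank responses are a
deterministic function of the spectrogram plus trial noise. Passing
tests on these fixtures therefore validate the estimators and the
model's internal phenomenology, not its fit to biological recordings.

One consequence is measured directly by the acceptance battery: linear
reconstruction of the stimulus from the *SRF baseline's* predictions
scores at least as high as reconstruction from the intact model's own
responses, because a rectified-linear function of a low-rank stimulus
retains nearly all linearly decodable information in this world. The
intact-vs-no-inhibition orderings (prediction cc and derivative cc) are
robust; orderings that hinge on real responses containing structure no
static stimulus model captures are not reproducible from self-generated
data.

## Event-triggered analysis

A stimulus event is a local maximum of the first difference of the
band-averaged power within ±10 channels of a neuron's best frequency
(argmax of its frequency-only encoding filter, ties to the lowest
channel). Peaks are selected greedily by height (earlier peak wins
ties) under a 200 ms minimum separation, capped at 150 events, and
reported at the bin where the increased power first appears. Transient
windows are the first 100 ms after an event, sustained the next 100 ms
(10 bins each at 10 ms; other bin widths scale, rounding down); events
whose 200 ms window overruns the data are dropped. Windowed encoding
filters restrict the regression rows to the window bins; population
summaries center each neuron's filter at its best frequency before
averaging. The transient-window width estimate is noisy when few events
exist or onset responses are spiky; the sustained-vs-transient contrast
is asserted on the population-averaged filters.

## Known limitations

- Mean-field filtering is exact only for one feature or disjoint
  supports; with overlap it is an approximation whose KL gap to the
  exact filter is regression-tested, not bounded.
- Synchronous updates can oscillate under strong competition (above).
- The EM study conditions (learning rate, epochs, overlap) are package
  choices; no canonical values exist for this model.
- The half-maximum width metric describes the positive peak only and
  can collapse on spiky averages; the octave-mass metric is provided as
  the robust alternative.
- The CLI's HDF5 containers store a single precision-preserving copy of
  each matrix; very long stimuli should be generated on the fly rather
  than shipped.
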