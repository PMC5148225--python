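# predecode

Predictive ensemble decoding of auditory spectrograms: a normative
Bayesian model of how a population of auditory neurons can collectively
infer the features composing a sound, together with the filter
estimators used to compare such a model against neural recordings.

## Who this is for

Computational and auditory neuroscientists who want to (a) simulate and
fit the switching-feature generative model of sounds, (b) run online
Bayesian inference with divisive "explaining away" between feature
detectors, (c) estimate encoding (STRF/SRF) and decoding filters from
spectrogram/response pairs by ridge-regularized reverse correlation, or
(d) reproduce the receptive-field phenomenology that lateral competition
produces — all without any proprietary recordings: a synthetic-data
module generates every fixture.

## The model

Sounds are modelled as `N` elementary spectral features `x_j(t) ∈ {0,1}`
that switch on and off as independent two-state Markov chains with rates
`r_on`, `r_off` (Hz). While on, feature `j` adds its nonnegative
*predictive field* (PF) `q_{·j}` to the intensity of `M` spectral
receptors, which emit Poisson counts per 10 ms bin:

    s_i(t) ~ Poisson( q_{i0} + Σ_j q_{ij} x_j(t) )

Each feature detector tracks the log-odds of its feature,
`L_j(t) = log A_j(t) + B_j(t)`, where `B_j` propagates the two-state
prior and `log A_j` is the Poisson likelihood ratio with all other
features replaced by their posterior probabilities from the previous bin
(mean field). The detector's firing rate is the rectified, linearized
new evidence

    f_j(t) = [ Σ_i q_{ij} ( s_i(t) / ŝ_i^j(t) − 1 ) ]_+ ,
    ŝ_i^j(t) = q_{i0} + Σ_{k≠j} q_{ik} p_k(t),

a sum of fractional prediction errors: input already explained by
competing detectors is divisively cancelled ("explaining away"). The
*no-inhibition* ablation replaces `ŝ^j` by the baseline `q_{i0}`.

PFs can be learned from stimulus statistics by online EM (gradient
`p_j(t)(s_i/λ̂_i − 1)` with clipping at zero), and estimated from data as
frequency-only decoding filters `g = C_RR^{-1} C_RS` (ridge-regularized,
blocked cross-validation).

## Worked example

```python
import numpy as np
from predecode import (FixtureSpec, make_pf_set, make_neuron_bank,
                       extract_pf, pf_recovery_score)
from predecode.filters import pf_matrix, estimate_srf, half_max_width

# a synthetic "recording session": 8 overlapping spectral features,
# 100 s of stimulus, model responses with 5-trial Poisson noise
spec = FixtureSpec(n_features=8, overlap=0.6, duration_s=100.0, seed=21)
Q_true = make_pf_set(spec)
bank = make_neuron_bank(spec, Q_true, "intact", observation_noise=True)

# recover each neuron's predictive field from its responses
pf_bank, best_delay, _ = extract_pf(bank.rates, bank.stimulus, delay_scan=range(6))
Q_hat, flagged = pf_matrix(pf_bank)
cc, _ = pf_recovery_score(Q_hat, Q_true)
print(f"extracted PFs match planted fields: mean cc = {cc.mean():.3f} "
      f"(optimal delay {best_delay * 10} ms)")

# explaining away narrows the measured receptive fields
srf, _ = estimate_srf(bank.stimulus, bank.rates, 0)
w_pf = np.mean([half_max_width(Q_true[:, n]) for n in range(8)])
w_rf = np.mean([half_max_width(srf.reduced[n]) for n in range(8)])
print(f"mean PF width {w_pf:.1f} channels, measured RF width {w_rf:.1f} channels")
```

prints

```
extracted PFs match planted fields: mean cc = 0.897 (optimal delay 0 ms)
mean PF width 8.1 channels, measured RF width 5.1 channels
```

The first line shows the decoding-based PF extraction closing the loop
on the planted fields. The second shows the model's signature: each
detector's feedforward selectivity (PF) spans ~8 channels, but its
measured receptive field is ~40% narrower because competing detectors
explain away the shared part of the input.

A command-line interface mirrors the library
(`predecode simulate | infer | learn | fit-filters | reconstruct |
select | analyze-events | predict | make-fixtures`); every command
writes a JSON manifest with its arguments and seed next to its output.

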