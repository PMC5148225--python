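"""Synthetic fixtures: speech-like spectrograms and model neuron banks.

Real cortical recordings and speech audio are not bundled; instead every
estimator is exercised on data generated by the package's own generative
model.  Spectrograms are built from planted predictive fields (Gaussian
bumps with controlled overlap, or harmonic stacks for a crude
speech-likeness) driven by on/off Markov feature dynamics; synthetic
"recorded" neuron banks are produced by running the Bayesian inference
model on such stimuli and adding Poisson trial noise, emulating a
five-trial averaged recording session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import (
    FeatureTrajectory,
    GenerativeParams,
    Spectrogram,
    log_spaced_channels,
    sample_features,
)
from .inference import DetectorTrace, InferenceConfig, run_inference, run_no_inhibition


@dataclass
class FixtureSpec:
    """Conditions of a synthetic experiment.

    Defaults mirror the canonical recording regime this package targets:
    30 log-spaced channels between 125 and 8000 Hz, 10 ms bins, feature
    switching at r_on = 1 Hz / r_off = 20 Hz, five stimulus repeats.
    ``overlap`` in [0, 1] controls how much adjacent predictive fields
    share channels (0 = disjoint supports).
    """

    n_channels: int = 30
    f_lo: float = 125.0
    f_hi: float = 8000.0
    dt: float = 0.01
    n_features: int = 5
    feature_shape: str = "gaussian_bump"
    overlap: float = 0.0
    duration_s: float = 50.0
    n_trials: int = 5
    seed: int = 0
    r_on: float = 1.0
    r_off: float = 20.0
    baseline: float = 0.1
    amplitude: float = 5.0

    def __post_init__(self) -> None:
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if self.feature_shape not in ("gaussian_bump", "harmonic_stack"):
            raise ValueError(f"unknown feature shape {self.feature_shape!r}")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_s / self.dt))

    @property
    def channels(self) -> np.ndarray:
        return log_spaced_channels(self.n_channels, self.f_lo, self.f_hi)

    def params(self, Q: np.ndarray) -> GenerativeParams:
        return GenerativeParams(
            Q=Q,
            q0=np.full(self.n_channels, self.baseline),
            r_on=self.r_on,
            r_off=self.r_off,
            dt=self.dt,
        )


def make_pf_set(spec: FixtureSpec) -> np.ndarray:
    """Planted predictive fields, one unit-max column per feature.

    Gaussian bumps are centered evenly across the channel axis; their
    width and support grow with ``spec.overlap`` (overlap 0 truncates
    supports so pairwise column dot products are exactly zero).
    Harmonic stacks add bumps at the 2nd and 3rd harmonics (one and
    log2(3) octaves above the fundamental) with decaying amplitude.
    Scaled by ``spec.amplitude``.
    """
    m, n = spec.n_channels, spec.n_features
    spacing = m / n
    if spec.overlap == 0 and spacing < 2:
        raise ValueError(
            f"disjoint supports infeasible: {n} features need >= 2 channels "
            f"each but only {spacing:.1f} are available"
        )
    centers = (np.arange(n) + 0.5) * spacing
    idx = np.arange(m, dtype=float)[:, None]
    sigma = spacing * (0.2 + 1.3 * spec.overlap)
    radius = spacing * (0.499 + 2.0 * spec.overlap)
    Q = np.exp(-((idx - centers[None, :]) ** 2) / (2 * sigma**2))
    Q[np.abs(idx - centers[None, :]) > radius] = 0.0

    if spec.feature_shape == "harmonic_stack":
        oct_per_ch = np.log2(spec.f_hi / spec.f_lo) / (m - 1)
        for h, amp in ((1.0, 0.6), (np.log2(3.0), 0.4)):
            hc = centers + h / oct_per_ch
            part = amp * np.exp(-((idx - hc[None, :]) ** 2) / (2 * sigma**2))
            part[np.abs(idx - hc[None, :]) > radius] = 0.0
            Q += part

    peaks = Q.max(axis=0)
    if np.any(peaks == 0):
        raise ValueError("a feature fell entirely outside the channel range")
    return spec.amplitude * Q / peaks


def pairwise_shared_mass(Q: np.ndarray) -> np.ndarray:
    """Fraction of each column's mass shared with its right neighbor.

    Shared mass between columns a, b is ``sum(min(a, b)) / sum(a)``.
    """
    out = np.empty(Q.shape[1] - 1)
    for j in range(Q.shape[1] - 1):
        out[j] = np.minimum(Q[:, j], Q[:, j + 1]).sum() / Q[:, j].sum()
    return out


def make_spectrogram(
    spec: FixtureSpec,
    Q: np.ndarray,
    observation_noise: bool = False,
) -> tuple[Spectrogram, FeatureTrajectory]:
    """Stimulus generated by the switching-feature model, plus the truth.

    Features are sampled with the spec's rates; the spectrogram is the
    noiseless intensity ``q0 + Q X`` by default (the stimulus itself is
    deterministic; receptor noise belongs downstream), optionally
    Poisson-corrupted.
    """
    params = spec.params(Q)
    traj = sample_features(params, Q.shape[1], spec.n_bins, seed=spec.seed)
    S = params.q0[:, None] + Q @ traj.X.astype(float)
    if observation_noise:
        rng = np.random.default_rng(spec.seed + 1)
        S = rng.poisson(S).astype(float)
    return Spectrogram(S=S, dt=spec.dt, channels=spec.channels), traj


@dataclass
class NeuronBank:
    """A synthetic 'recording': model-generated rates plus trial noise."""

    stimulus: Spectrogram
    truth: FeatureTrajectory
    trace: DetectorTrace
    trials: np.ndarray  # (n_trials, n_neurons, T) Poisson counts
    rates: np.ndarray  # (n_neurons, T) trial-averaged rates

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]


def make_neuron_bank(
    spec: FixtureSpec,
    Q: np.ndarray,
    model: str = "intact",
    inference_config: InferenceConfig | None = None,
    observation_noise: bool = False,
) -> NeuronBank:
    """Run the chosen inference model on a fixture stimulus and add noise.

    One synthetic neuron per feature detector: the model's rectified
    firing rates drive independent Poisson spike counts on each of
    ``spec.n_trials`` trials, and the trial average plays the role of
    the recorded rates.
    """
    if model not in ("intact", "no_inhibition"):
        raise ValueError("model must be 'intact' or 'no_inhibition'")
    stim, truth = make_spectrogram(spec, Q, observation_noise=observation_noise)
    params = spec.params(Q)
    obs = _as_observations(stim)
    runner = run_inference if model == "intact" else run_no_inhibition
    trace = runner(obs, params, inference_config)
    rng = np.random.default_rng(spec.seed + 2)
    trials = rng.poisson(trace.F, size=(spec.n_trials,) + trace.F.shape).astype(float)
    return NeuronBank(
        stimulus=stim,
        truth=truth,
        trace=trace,
        trials=trials,
        rates=trials.mean(axis=0),
    )


def _as_observations(stim: Spectrogram):
    from .generative import ReceptorObservations

    return ReceptorObservations(S=stim.S, dt=stim.dt)
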