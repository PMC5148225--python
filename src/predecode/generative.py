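"""Generative model of sounds: switching binary features and Poisson receptors.

Auditory events are modelled as ``N`` elementary features that switch on
and off independently as two-state Markov chains with rates ``r_on`` and
``r_off`` (Hz).  While on, feature ``j`` adds its nonnegative predictive
field (PF) column ``q[:, j]`` to the intensity of ``M`` sensory
receptors, on top of a baseline ``q0``.  Receptors emit Poisson counts
per time bin:

    s_i(t) ~ Poisson( q0_i + sum_j q_ij x_j(t) )

Rates are public in 1/s and converted to per-bin switching probabilities
``p = min(rate * dt, 1)``; with the canonical 10 ms binning the default
rates r_on = 1 Hz, r_off = 20 Hz become per-bin probabilities 0.01 and
0.2.  Time bins are 0-based, left-aligned, half-open ``[t*dt, (t+1)*dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Q0_FLOOR = 1e-6


@dataclass
class GenerativeParams:
    """Parameters of the switching-feature Poisson generative model.

    Attributes
    ----------
    Q : ndarray, shape (M, N)
        Nonnegative predictive fields: weight added to receptor ``i``'s
        per-bin intensity while feature ``j`` is on.
    q0 : ndarray, shape (M,)
        Baseline per-bin intensity of each receptor; floored at 1e-6 so
        likelihood ratios stay finite (equivalent to one always-on
        feature supplying the baseline).
    r_on, r_off : float
        Switching rates in 1/s (on: off->on, off: on->off).
    dt : float
        Bin width in seconds (default 0.01).
    """

    Q: np.ndarray
    q0: np.ndarray
    r_on: float = 1.0
    r_off: float = 20.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.q0 = np.asarray(self.q0, dtype=float)
        if self.Q.ndim != 2:
            raise ValueError("Q must be a 2-D (receptors x features) matrix")
        if self.q0.shape != (self.Q.shape[0],):
            raise ValueError(
                f"q0 has shape {self.q0.shape}, expected ({self.Q.shape[0]},)"
            )
        if np.any(self.Q < 0) or np.any(self.q0 < 0):
            raise ValueError("Q and q0 must be nonnegative")
        if self.r_on < 0 or self.r_off < 0:
            raise ValueError("switching rates must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.q0 = np.maximum(self.q0, Q0_FLOOR)

    @property
    def n_receptors(self) -> int:
        return self.Q.shape[0]

    @property
    def n_features(self) -> int:
        return self.Q.shape[1]

    @property
    def r_on_bin(self) -> float:
        """Per-bin switch-on probability min(r_on * dt, 1)."""
        return min(self.r_on * self.dt, 1.0)

    @property
    def r_off_bin(self) -> float:
        """Per-bin switch-off probability min(r_off * dt, 1)."""
        return min(self.r_off * self.dt, 1.0)


@dataclass
class FeatureTrajectory:
    """Binary hidden feature states, shape (N features, T bins)."""

    X: np.ndarray
    dt: float = 0.01

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.size and not np.isin(self.X, (0, 1)).all():
            raise ValueError("feature states must be binary")
        self.X = self.X.astype(np.int8)

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]


@dataclass
class ReceptorObservations:
    """Nonnegative receptor activity, shape (M receptors, T bins).

    Integer counts when Poisson-sampled; real-valued entries (e.g.
    trial-averaged rates) are also accepted by the inference code.
    """

    S: np.ndarray
    dt: float = 0.01

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.size and self.S.min() < 0:
            raise ValueError("receptor observations must be nonnegative")

    @property
    def n_receptors(self) -> int:
        return self.S.shape[0]

    @property
    def n_bins(self) -> int:
        return self.S.shape[1]


def log_spaced_channels(
    n_channels: int = 30, f_lo: float = 125.0, f_hi: float = 8000.0
) -> np.ndarray:
    """Center frequencies (Hz) of log-spaced spectrogram channels."""
    return np.geomspace(f_lo, f_hi, n_channels)


@dataclass
class Spectrogram:
    """Nonnegative frequency x time stimulus matrix with bin metadata.

    ``S[i, t]`` is the power in channel ``i`` during bin ``t``; channels
    carry their center frequencies in Hz (default: 30 log-spaced bins,
    125-8000 Hz, 10 ms bins).
    """

    S: np.ndarray
    dt: float = 0.01
    channels: np.ndarray = field(default_factory=log_spaced_channels)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.S.ndim != 2:
            raise ValueError("spectrogram must be 2-D (channels x time)")
        if self.S.size and self.S.min() < 0:
            raise ValueError("spectrogram must be nonnegative")
        if self.channels.shape != (self.S.shape[0],):
            raise ValueError("channel metadata must match the frequency axis")

    @property
    def n_channels(self) -> int:
        return self.S.shape[0]

    @property
    def n_bins(self) -> int:
        return self.S.shape[1]

    @property
    def octaves_per_channel(self) -> float:
        return float(
            np.log2(self.channels[-1] / self.channels[0]) / (self.n_channels - 1)
        )


def stationary_on_probability(r_on_bin: float, r_off_bin: float) -> float:
    """Stationary P(on) of the two-state chain, r_on / (r_on + r_off).

    Defined as 0 when both probabilities are 0 (frozen chain stays off
    by convention).
    """
    total = r_on_bin + r_off_bin
    if total == 0:
        return 0.0
    return r_on_bin / total


def sample_features(
    params: GenerativeParams,
    n_features: int,
    n_bins: int,
    seed: int,
    initial_state: np.ndarray | None = None,
) -> FeatureTrajectory:
    """Sample independent two-state Markov chains for each feature.

    Each feature switches off->on with per-bin probability
    ``params.r_on_bin`` and on->off with ``params.r_off_bin``.  The state
    at bin 0 is one transition step past ``initial_state``; when no
    initial state is given it is drawn from the stationary distribution.
    """
    if n_features < 1 or n_bins < 1:
        raise ValueError("need at least one feature and one bin")
    p_on, p_off = params.r_on_bin, params.r_off_bin
    rng = np.random.default_rng(seed)
    if initial_state is None:
        pi = stationary_on_probability(p_on, p_off)
        state = (rng.random(n_features) < pi).astype(np.int8)
    else:
        state = np.asarray(initial_state).astype(np.int8)
        if state.shape != (n_features,):
            raise ValueError("initial_state must have length n_features")

    X = np.empty((n_features, n_bins), dtype=np.int8)
    u = rng.random((n_features, n_bins))
    for t in range(n_bins):
        switch_on = (state == 0) & (u[:, t] < p_on)
        switch_off = (state == 1) & (u[:, t] < p_off)
        state = np.where(switch_on, 1, np.where(switch_off, 0, state)).astype(np.int8)
        X[:, t] = state
    return FeatureTrajectory(X=X, dt=params.dt)


def receptor_intensity(params: GenerativeParams, x: np.ndarray) -> np.ndarray:
    """Per-bin Poisson intensity lambda_i = q0_i + sum_j q_ij x_j."""
    x = np.asarray(x)
    if x.shape != (params.n_features,):
        raise ValueError(
            f"x has shape {x.shape}, expected ({params.n_features},)"
        )
    return params.q0 + params.Q @ x.astype(float)


def sample_observations(
    params: GenerativeParams, traj: FeatureTrajectory, seed: int
) -> ReceptorObservations:
    """Sample Poisson receptor counts given a feature trajectory.

    ``S[i, t] ~ Poisson(q0_i + (Q @ X)[i, t])`` independently across
    receptors and bins.
    """
    if traj.n_features != params.n_features:
        raise ValueError(
            f"trajectory has {traj.n_features} features, params expect "
            f"{params.n_features}"
        )
    rng = np.random.default_rng(seed)
    lam = params.q0[:, None] + params.Q @ traj.X.astype(float)
    S = rng.poisson(lam).astype(float)
    return ReceptorObservations(S=S, dt=params.dt)
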