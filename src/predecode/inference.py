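"""Online Bayesian filtering of switching features with explaining away.

Each feature detector ``j`` tracks the log-odds of its feature being on,

    L_j(t) = log A_j(t) + B_j(t),

where ``B_j`` is the two-state prior ratio propagated from the previous
posterior and ``log A_j`` is the Poisson likelihood ratio evaluated under
a mean-field substitution: the unknown binary states of all *other*
features are replaced by their posterior probabilities from the previous
bin.  The resulting synaptic drive is divisively normalized by the other
detectors' prediction of each receptor,

    s_hat^j_i(t) = q0_i + sum_{k != j} q_ik p_k(t),

which implements "explaining away": input that is already accounted for
by competing detectors is cancelled.  The detector firing-rate readout is
the rectified, linearized log likelihood

    f_j(t) = [ sum_i ( s_i(t) q_ij / s_hat^j_i(t) - q_ij ) ]_+,

i.e. a sum of fractional prediction errors weighted by the PF.  The
"no inhibition" ablation replaces ``s_hat^j`` by the baseline ``q0``,
removing all competition while keeping the rest of the recursion.

An exact forward filter over all 2^N joint configurations is provided as
an oracle for small N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import (
    GenerativeParams,
    ReceptorObservations,
    stationary_on_probability,
)


@dataclass
class InferenceConfig:
    """Numerical and model options for the online filter.

    epsilon_floor : floor for predicted-input denominators and prior
        ratio clamping (q0 > 0 makes this a no-op in normal operation).
    use_log1p_exact : evaluate the likelihood ratio with the exact
        ``log(1 + q/s_hat)`` form; when off, the linearized ``q/s_hat``
        small-argument approximation is used.
    gain : global scalar applied to the stimulus before inference.
    """

    epsilon_floor: float = 1e-9
    use_log1p_exact: bool = True
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon_floor <= 0:
            raise ValueError("epsilon_floor must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class DetectorTrace:
    """Per-detector time series produced by the online filter.

    L : log-odds, shape (N, T).
    P : posterior on-probabilities, logistic(L).
    F : rectified firing-rate readout, nonnegative.
    """

    L: np.ndarray
    P: np.ndarray
    F: np.ndarray
    dt: float = 0.01

    @property
    def n_features(self) -> int:
        return self.L.shape[0]

    @property
    def n_bins(self) -> int:
        return self.L.shape[1]


def _logistic(L: np.ndarray) -> np.ndarray:
    out = np.empty_like(L, dtype=float)
    pos = L >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-L[pos]))
    ez = np.exp(L[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def prior_log_odds(
    p_prev: float | np.ndarray,
    r_on_bin: float,
    r_off_bin: float,
    epsilon_floor: float = 1e-9,
) -> float | np.ndarray:
    """Prior ratio B_j for the two-state chain, propagated one bin.

    Given the previous posterior ``p_prev``, the prior probability of
    being on at the next bin is ``p_prev (1 - r_off) + (1 - p_prev) r_on``
    (stay on, or switch on); the off probability is the complement
    through the same transitions.  Both are clamped at
    ``epsilon_floor`` so the log stays finite.
    """
    p = np.asarray(p_prev, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_prev must lie in [0, 1]")
    for r in (r_on_bin, r_off_bin):
        if not 0.0 <= r <= 1.0:
            raise ValueError("per-bin switching probabilities must lie in [0, 1]")
    num = p * (1.0 - r_off_bin) + (1.0 - p) * r_on_bin
    den = p * r_off_bin + (1.0 - p) * (1.0 - r_on_bin)
    out = np.log(np.maximum(num, epsilon_floor) / np.maximum(den, epsilon_floor))
    return float(out) if out.ndim == 0 else out


def predicted_input(
    Q: np.ndarray,
    q0: np.ndarray,
    p: np.ndarray,
    j: int,
    epsilon_floor: float = 1e-9,
) -> np.ndarray:
    """Other detectors' prediction of each receptor, s_hat^j.

    ``s_hat^j_i = q0_i + sum_{k != j} q_ik p_k``, floored at
    ``epsilon_floor``.
    """
    Q = np.asarray(Q, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    p = np.asarray(p, dtype=float)
    if not 0 <= j < Q.shape[1]:
        raise IndexError(f"feature index {j} out of range for {Q.shape[1]} features")
    shat = q0 + Q @ p - Q[:, j] * p[j]
    return np.maximum(shat, epsilon_floor)


def _predicted_input_all(
    Q: np.ndarray, q0: np.ndarray, p: np.ndarray, epsilon_floor: float
) -> np.ndarray:
    """s_hat^j for every j at once, shape (M, N)."""
    total = q0 + Q @ p
    return np.maximum(total[:, None] - Q * p[None, :], epsilon_floor)


def evidence_log_ratio(
    s_t: np.ndarray,
    Q: np.ndarray,
    q0: np.ndarray,
    p: np.ndarray,
    j: int,
    config: InferenceConfig | None = None,
) -> float:
    """Mean-field log likelihood ratio log A_j for one feature.

    Exact form: ``sum_i [ s_i log(1 + q_ij / s_hat^j_i) - q_ij ]``;
    linearized form drops the log.  Real-valued ``s`` (trial-averaged
    rates) is evaluated as written.
    """
    config = config or InferenceConfig()
    s_t = np.asarray(s_t, dtype=float)
    qj = np.asarray(Q, dtype=float)[:, j]
    shat = predicted_input(Q, q0, p, j, config.epsilon_floor)
    if config.use_log1p_exact:
        return float(np.sum(s_t * np.log1p(qj / shat) - qj))
    return float(np.sum(s_t * qj / shat - qj))


def firing_rate(
    s_t: np.ndarray,
    Q: np.ndarray,
    q0: np.ndarray,
    p: np.ndarray,
    j: int,
    config: InferenceConfig | None = None,
) -> float:
    """Rectified linearized log likelihood — the detector readout.

    ``[ sum_i ( s_i q_ij / s_hat^j_i - q_ij ) ]_+``, algebraically equal
    to the divisive predictive-coding form
    ``[ sum_i q_ij (s_i / s_hat^j_i - 1) ]_+`` whose per-receptor factor
    is the fractional prediction error.
    """
    config = config or InferenceConfig()
    s_t = np.asarray(s_t, dtype=float)
    qj = np.asarray(Q, dtype=float)[:, j]
    shat = predicted_input(Q, q0, p, j, config.epsilon_floor)
    return float(max(np.sum(s_t * qj / shat - qj), 0.0))


def inference_step(
    L_prev: np.ndarray,
    s_t: np.ndarray,
    params: GenerativeParams,
    config: InferenceConfig | None = None,
    no_inhibition: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronous update of all detectors.

    All detectors read the posterior ``p_prev = logistic(L_prev)`` from
    the previous bin (no within-bin sweeps), then

        L_j = log A_j(s_t, p_prev) + B_j(p_prev_j).

    The firing-rate readout also uses ``p_prev``, so it reports the new
    evidence arriving this bin.  Returns ``(L, p, f)``.
    """
    config = config or InferenceConfig()
    L_prev = np.asarray(L_prev, dtype=float)
    if not np.all(np.isfinite(L_prev)):
        raise ValueError("L_prev must be finite")
    return _step_arrays(
        L_prev,
        np.asarray(s_t, dtype=float) * config.gain,
        params.Q,
        params.q0,
        params.r_on_bin,
        params.r_off_bin,
        config,
        no_inhibition,
    )


def _step_arrays(
    L_prev: np.ndarray,
    s_t: np.ndarray,
    Q: np.ndarray,
    q0: np.ndarray,
    p_on: float,
    p_off: float,
    config: InferenceConfig,
    no_inhibition: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array-level core of inference_step (gain already applied)."""
    p_prev = _logistic(L_prev)
    if no_inhibition:
        shat = np.broadcast_to(q0[:, None], Q.shape)
    else:
        shat = _predicted_input_all(Q, q0, p_prev, config.epsilon_floor)

    ratio = Q / shat
    linear = s_t @ ratio - Q.sum(axis=0)
    if config.use_log1p_exact:
        log_a = s_t @ np.log1p(ratio) - Q.sum(axis=0)
    else:
        log_a = linear
    prior = prior_log_odds(p_prev, p_on, p_off, config.epsilon_floor)
    L = log_a + prior
    return L, _logistic(L), np.maximum(linear, 0.0)


def _run(
    S: ReceptorObservations,
    params: GenerativeParams,
    config: InferenceConfig | None,
    no_inhibition: bool,
) -> DetectorTrace:
    config = config or InferenceConfig()
    n = params.n_features
    T = S.n_bins
    if S.n_receptors != params.n_receptors:
        raise ValueError(
            f"S has {S.n_receptors} receptors, params expect {params.n_receptors}"
        )
    L = np.empty((n, T))
    P = np.empty((n, T))
    F = np.empty((n, T))
    pi = stationary_on_probability(params.r_on_bin, params.r_off_bin)
    pi = min(max(pi, config.epsilon_floor), 1.0 - config.epsilon_floor)
    L_prev = np.full(n, np.log(pi / (1.0 - pi)))
    for t in range(T):
        L_prev, p, f = inference_step(
            L_prev, S.S[:, t], params, config, no_inhibition=no_inhibition
        )
        L[:, t] = L_prev
        P[:, t] = p
        F[:, t] = f
    return DetectorTrace(L=L, P=P, F=F, dt=S.dt)


def run_inference(
    S: ReceptorObservations,
    params: GenerativeParams,
    config: InferenceConfig | None = None,
) -> DetectorTrace:
    """Filter a whole observation sequence with the intact model.

    The log-odds are initialized at the stationary prior; the trace has
    one column per stimulus bin.
    """
    return _run(S, params, config, no_inhibition=False)


def run_no_inhibition(
    S: ReceptorObservations,
    params: GenerativeParams,
    config: InferenceConfig | None = None,
) -> DetectorTrace:
    """Feedforward ablation: detectors do not explain away each other.

    The likelihood denominator is the baseline intensity ``q0`` instead
    of other detectors' predictions; prior propagation, readout and
    initialization are unchanged.
    """
    return _run(S, params, config, no_inhibition=True)


def exact_filter_oracle(
    S: ReceptorObservations,
    params: GenerativeParams,
    max_features: int = 12,
) -> np.ndarray:
    """Exact HMM forward filter over all 2^N joint feature states.

    Enumerates every configuration; transitions factorize over the
    independent two-state chains and emissions are product-Poisson with
    ``lambda_i = q0_i + sum_k q_ik x_k``.  Returns the exact posterior
    marginals ``P(x_j(t) = 1 | s_0..t)`` as an (N, T) matrix.  The
    initial state distribution is stationary and, matching the online
    filter's convention, one transition step is applied before the first
    observation.  Intended as a small-N oracle; refuses N above
    ``max_features``.
    """
    n = params.n_features
    if n > max_features:
        raise ValueError(f"exact enumeration limited to N <= {max_features}")
    T = S.n_bins
    states = np.array(
        [[(a >> j) & 1 for j in range(n)] for a in range(2**n)], dtype=float
    )  # (2^N, N)

    p_on, p_off = params.r_on_bin, params.r_off_bin
    pi = stationary_on_probability(p_on, p_off)
    # per-feature transition probabilities P(x' | x)
    trans1 = np.array([[1 - p_on, p_on], [p_off, 1 - p_off]])
    n_states = 2**n
    trans = np.ones((n_states, n_states))
    for j in range(n):
        xa = states[:, j].astype(int)
        trans *= trans1[xa[:, None], xa[None, :]]

    lam = params.q0[None, :] + states @ params.Q.T  # (2^N, M)
    log_lam = np.log(np.maximum(lam, 1e-300))

    alpha = np.array([pi**s.sum() * (1 - pi) ** (n - s.sum()) for s in states])
    alpha /= alpha.sum()
    marginals = np.empty((n, T))
    for t in range(T):
        alpha = trans.T @ alpha
        loglik = S.S[:, t] @ log_lam.T - lam.sum(axis=1)
        loglik -= loglik.max()
        alpha = alpha * np.exp(loglik)
        alpha /= alpha.sum()
        marginals[:, t] = states.T @ alpha
    return marginals
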