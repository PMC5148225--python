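"""Learning predictive fields by expectation-maximization.

With the posterior feature probabilities ``p_j(t)`` from the online
filter standing in for the hidden binary states (E step), the PFs are
updated by stochastic gradient ascent on the Poisson log likelihood of
the observations (M step).  The gradient of the per-bin log likelihood
with respect to ``q_ij`` is

    dL/dq_ij = p_j(t) ( s_i(t) / lambda_hat_i(t) - 1 ),
    lambda_hat_i(t) = q0_i + sum_k q_ik p_k(t),

a Hebbian-like product of postsynaptic belief and presynaptic fractional
prediction error.  Learning is online (one gradient step per bin,
alternating with one inference step); entries driven negative are
clipped to exactly zero, keeping the PFs in the nonnegative cone.
Baselines ``q0`` and the switching rates are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .generative import GenerativeParams, ReceptorObservations
from .inference import InferenceConfig, _step_arrays
from .generative import stationary_on_probability


@dataclass
class LearningConfig:
    """Settings for online EM.

    learning_rate : gradient-ascent step size (default 1e-3); optional
        1/epoch decay via ``decay``.
    n_epochs : passes over the stimulus; the pure online mode is 1.
    init_mode : 'random_bump' (low uniform noise plus a Gaussian bump at
        ``bump_center``), 'flat_random', or 'given' (use the passed
        initial_Q as is).
    """

    learning_rate: float = 1e-3
    n_epochs: int = 1
    seed: int = 0
    init_mode: str = "given"
    bump_center: np.ndarray | None = None
    bump_width: float = 2.0
    decay: bool = False
    clip_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.init_mode not in ("random_bump", "flat_random", "given"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


def initialize_pfs(
    n_receptors: int,
    n_features: int,
    config: LearningConfig,
    peak: float = 1.0,
) -> np.ndarray:
    """Build an initial PF matrix according to ``config.init_mode``.

    'random_bump' places uniform noise in [0, 0.1*peak] plus a Gaussian
    bump (sd = bump_width channels, height = peak) at each feature's
    designated center channel.
    """
    rng = np.random.default_rng(config.seed)
    Q = rng.uniform(0.0, 0.1 * peak, size=(n_receptors, n_features))
    if config.init_mode == "random_bump":
        centers = config.bump_center
        if centers is None:
            centers = np.linspace(0, n_receptors - 1, n_features)
        idx = np.arange(n_receptors)[:, None]
        Q += peak * np.exp(
            -((idx - np.asarray(centers)[None, :]) ** 2)
            / (2.0 * config.bump_width**2)
        )
    return Q


def poisson_log_likelihood(
    S: np.ndarray, Q: np.ndarray, q0: np.ndarray, P: np.ndarray
) -> float:
    """Mean per-bin Poisson log likelihood (up to the s! constant).

    ``mean_t sum_i [ s_i(t) log lambda_hat_i(t) - lambda_hat_i(t) ]``
    with the features replaced by their expected values ``P``.
    """
    lam = np.maximum(q0[:, None] + Q @ P, 1e-12)
    return float(np.mean(np.sum(S * np.log(lam) - lam, axis=0)))


def m_step_gradient(
    S: np.ndarray,
    P_trace: np.ndarray,
    Q: np.ndarray,
    q0: np.ndarray,
) -> np.ndarray:
    """Gradient of the expected log likelihood w.r.t. the PF matrix.

    ``G[i, j] = sum_t p_j(t) ( s_i(t) / lambda_hat_i(t) - 1 )``; the
    intensity estimate is floored to keep the ratio finite.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    P_trace = np.atleast_2d(np.asarray(P_trace, dtype=float))
    if S.shape[1] != P_trace.shape[1]:
        raise ValueError("S and P_trace must cover the same bins")
    lam = np.maximum(q0[:, None] + Q @ P_trace, 1e-12)
    return (S / lam - 1.0) @ P_trace.T


def online_em(
    S: ReceptorObservations,
    initial_Q: np.ndarray,
    q0: np.ndarray,
    params: GenerativeParams,
    learn_config: LearningConfig | None = None,
    inference_config: InferenceConfig | None = None,
    inhibition: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Learn PFs by alternating one inference and one gradient step per bin.

    Each bin: the filter's posterior under the current ``Q`` is the E
    step; a single stochastic-gradient ascent step on that bin's log
    likelihood is the M step, followed by clipping at zero.  The
    ``inhibition`` flag selects the intact versus feedforward-only
    E step.  Returns the learned ``Q`` and the per-epoch mean log
    likelihood trace.

    Raises ``FloatingPointError`` if the objective diverges.
    """
    learn_config = learn_config or LearningConfig()
    inference_config = inference_config or InferenceConfig()
    Q = np.maximum(np.asarray(initial_Q, dtype=float).copy(), 0.0)
    q0 = np.asarray(q0, dtype=float)

    # fold the gain into the data once so E and M steps see the same s
    S_eff = S.S * inference_config.gain
    step_config = replace(inference_config, gain=1.0)

    T = S_eff.shape[1]
    n = Q.shape[1]
    pi = stationary_on_probability(params.r_on_bin, params.r_off_bin)
    pi = min(max(pi, step_config.epsilon_floor), 1 - step_config.epsilon_floor)
    L0 = np.log(pi / (1.0 - pi))

    objective = np.empty(learn_config.n_epochs)
    for epoch in range(learn_config.n_epochs):
        eta = learn_config.learning_rate
        if learn_config.decay:
            eta /= 1.0 + epoch
        L_prev = np.full(n, L0)
        P_epoch = np.empty((n, T))
        p_on, p_off = params.r_on_bin, params.r_off_bin
        for t in range(T):
            L_prev, p, _ = _step_arrays(
                L_prev, S_eff[:, t], Q, q0, p_on, p_off, step_config,
                no_inhibition=not inhibition,
            )
            P_epoch[:, t] = p
            if eta > 0:
                s_bin = S_eff[:, t]
                lam = np.maximum(q0 + Q @ p, 1e-12)
                g = np.outer(s_bin / lam - 1.0, p)
                Q = Q + eta * g
                if learn_config.clip_nonnegative:
                    np.maximum(Q, 0.0, out=Q)
        objective[epoch] = poisson_log_likelihood(S_eff, Q, q0, P_epoch)
        if not np.isfinite(objective[epoch]):
            raise FloatingPointError(
                f"objective diverged at epoch {epoch}: {objective[epoch]}"
            )
    return Q, objective


def pf_recovery_score(
    Q_learned: np.ndarray, Q_true: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Match learned to true PF columns and score the recovery.

    Builds the matrix of Pearson correlations between every learned and
    true column, solves the optimal one-to-one assignment maximizing the
    summed correlation, and returns the per-pair correlations with the
    ``(learned, true)`` index pairs.  Constant columns correlate 0 with
    everything.
    """
    Ql = np.asarray(Q_learned, dtype=float)
    Qt = np.asarray(Q_true, dtype=float)
    if Ql.shape[0] != Qt.shape[0]:
        raise ValueError("PF matrices must share the receptor dimension")

    def _std_cols(A: np.ndarray) -> np.ndarray:
        Z = A - A.mean(axis=0)
        norm = np.linalg.norm(Z, axis=0)
        norm[norm == 0] = np.inf
        return Z / norm

    C = _std_cols(Ql).T @ _std_cols(Qt)  # (N_learned, N_true)
    rows, cols = linear_sum_assignment(-C)
    order = np.argsort(rows)
    rows, cols = rows[order], cols[order]
    return C[rows, cols], list(zip(rows.tolist(), cols.tolist()))
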