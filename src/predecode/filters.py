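"""Encoding and decoding filter estimation by normalized reverse correlation.

Encoding (STRF): the linear frequency x delay filter ``h(tau, n)``
minimizing ``sum_t (r(t,n) - sum_{i,tau} h_i(tau,n) s_i(t-tau))^2``,
which in closed form is the stimulus-autocorrelation-whitened
cross-correlation ``C_SS^-1 C_Sr``.  Decoding: the converse map
``g_i(tau, n) = C_RR^-1 C_RS_i`` with which the population linearly
reconstructs each stimulus channel.  Both are ridge-regularized, with
the penalty chosen by cross-validation over contiguous time blocks
(shuffled bins would leak through temporal autocorrelation).

Reduced one-delay forms: the SRF (frequency-only encoding filter) and
the extracted PF (frequency-only decoding filter, rectified and
unit-max normalized before being plugged into the Bayesian model as a
feature's predictive field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import Spectrogram

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 13)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, Spectrogram):
        return x.S
    if hasattr(x, "S"):
        return np.asarray(x.S, dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class FitReport:
    """Cross-validation record for one ridge fit."""

    cv_scheme: str
    lambda_grid: np.ndarray
    val_errors: np.ndarray  # (n_lambdas, n_folds)
    chosen_lambda: float
    optimal_delays: np.ndarray | None = None

    def __post_init__(self) -> None:
        mean_err = self.val_errors.mean(axis=1)
        chosen = mean_err[np.argmin(np.abs(self.lambda_grid - self.chosen_lambda))]
        if chosen > mean_err.min() + 1e-12:
            raise ValueError("chosen lambda does not attain the minimal CV error")


@dataclass
class FilterBank:
    """A set of per-neuron linear filters.

    W has shape (n_units, n_channels, n_delays); the reduced SRF/PF form
    has exactly one delay.  ``kind`` is 'encoding' (stimulus -> response)
    or 'decoding' (responses -> stimulus).
    """

    kind: str
    W: np.ndarray
    delays: np.ndarray
    channels: np.ndarray | None = None
    ridge_lambda: np.ndarray | float | None = None
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.delays = np.asarray(self.delays, dtype=int)
        if self.kind not in ("encoding", "decoding"):
            raise ValueError("kind must be 'encoding' or 'decoding'")
        if self.W.ndim != 3:
            raise ValueError("W must be (units, channels, delays)")
        if np.any(self.delays < 0) or np.any(np.diff(self.delays) < 0):
            raise ValueError("delays must be nonnegative and ascending")
        if self.W.shape[2] != self.delays.size:
            raise ValueError("delay axis of W must match delays")

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    @property
    def is_reduced(self) -> bool:
        return self.delays.size == 1

    @property
    def reduced(self) -> np.ndarray:
        """(units, channels) view of a one-delay bank."""
        if not self.is_reduced:
            raise ValueError("bank has multiple delays; not a reduced SRF/PF form")
        return self.W[:, :, 0]

    def n_free_parameters(self, n_global: int = 0) -> int:
        """Free parameters of the model built on one filter of this bank.

        Per-neuron filter weights, plus one optimized response delay per
        neuron, plus any shared global parameters (e.g. the Bayesian
        decoding model adds r_on, r_off and a gain).
        """
        per_neuron = self.W.shape[1] * self.W.shape[2] + 1
        return per_neuron + n_global


def lagged_design(S, delays) -> np.ndarray:
    """Time x (channel, delay) design matrix of lagged stimulus copies.

    Row ``t`` holds ``s_i(t - tau)`` for every channel ``i`` and delay
    ``tau``; lags reaching before the first bin are zero-padded so the
    design keeps the stimulus length.
    """
    S = _as_matrix(S)
    delays = np.asarray(delays, dtype=int)
    if np.any(delays < 0):
        raise ValueError("delays must be causal (>= 0)")
    M, T = S.shape
    X = np.zeros((T, M * delays.size))
    for d, tau in enumerate(delays):
        X[tau:, d :: delays.size] = S[:, : T - tau].T if tau else S.T
    return X


def contiguous_folds(T: int, n_folds: int) -> list[np.ndarray]:
    """Split time bins into contiguous blocks for cross-validation."""
    return [np.asarray(f) for f in np.array_split(np.arange(T), n_folds)]


def ridge_reverse_correlation(
    design: np.ndarray,
    target: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, FitReport]:
    """Ridge-regularized normalized reverse correlation with blocked CV.

    Design and target are mean-centered (the estimate is a whitened
    cross-covariance; an implicit intercept absorbs the means).  For
    each penalty ``lam`` solves ``(X'X + lam I)^-1 X'y`` on the
    training blocks, scores MSE on the held-out block, then refits on
    all data at the CV-optimal penalty (ties go to the smaller
    penalty).  The fold layout is deterministic (contiguous time
    blocks); ``seed`` is accepted for interface uniformity.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(target, dtype=float).reshape(-1, 1)
    W, reports, _ = _multi_target_ridge(X, y, lambda_grid, n_folds)
    return W[:, 0], reports[0]


def _multi_target_ridge(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_grid,
    n_folds: int,
) -> tuple[np.ndarray, list[FitReport], np.ndarray]:
    """Centered ridge for each column of Y, sharing X factorizations.

    Returns the (K, n_targets) weights, one FitReport per target, and
    the per-target intercepts ``mean(y) - mean(x) @ w``.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be positive")
    T, K = X.shape
    if Y.shape[0] != T:
        raise ValueError("design and target lengths differ")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    n_targets = Y.shape[1]
    folds = contiguous_folds(T, n_folds)
    XtX = Xc.T @ Xc
    XtY = Xc.T @ Yc
    eye = np.eye(K)
    val = np.empty((n_targets, lambda_grid.size, n_folds))
    for f, idx in enumerate(folds):
        Xv, Yv = Xc[idx], Yc[idx]
        XtX_tr = XtX - Xv.T @ Xv
        XtY_tr = XtY - Xv.T @ Yv
        for li, lam in enumerate(lambda_grid):
            Wl = np.linalg.solve(XtX_tr + lam * eye, XtY_tr)
            resid = Yv - Xv @ Wl
            val[:, li, f] = (resid**2).mean(axis=0)
    W = np.empty((K, n_targets))
    reports = []
    # solve final weights per chosen lambda, grouping targets by lambda
    best = np.argmin(val.mean(axis=2), axis=1)
    for li in np.unique(best):
        cols = np.where(best == li)[0]
        Wl = np.linalg.solve(XtX + lambda_grid[li] * eye, XtY[:, cols])
        W[:, cols] = Wl
    intercepts = y_mean - x_mean @ W
    for n in range(n_targets):
        reports.append(
            FitReport(
                cv_scheme=f"{n_folds}-fold contiguous time blocks",
                lambda_grid=lambda_grid,
                val_errors=val[n],
                chosen_lambda=float(lambda_grid[best[n]]),
            )
        )
    return W, reports, intercepts


def estimate_encoding_filters(
    S,
    R,
    delays,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    time_mask: np.ndarray | None = None,
) -> tuple[FilterBank, list[FitReport]]:
    """Fit one frequency x delay encoding filter (STRF) per neuron.

    ``time_mask`` optionally restricts the regression to a subset of
    time bins (used by the event-triggered transient/sustained
    analysis); the lagged design is always built on the full stimulus
    so lags reach outside the mask.
    """
    S_mat = _as_matrix(S)
    R_mat = _as_matrix(R)
    if S_mat.shape[1] != R_mat.shape[1]:
        raise ValueError("stimulus and responses must be aligned in time")
    delays = np.asarray(delays, dtype=int)
    X = lagged_design(S_mat, delays)
    Y = R_mat.T
    if time_mask is not None:
        X, Y = X[time_mask], Y[time_mask]
    W_flat, reports, intercepts = _multi_target_ridge(X, Y, lambda_grid, n_folds)
    n_neurons = R_mat.shape[0]
    W = W_flat.T.reshape(n_neurons, S_mat.shape[0], delays.size)
    channels = S.channels if isinstance(S, Spectrogram) else None
    bank = FilterBank(
        kind="encoding",
        W=W,
        delays=delays,
        channels=channels,
        ridge_lambda=np.array([r.chosen_lambda for r in reports]),
        intercepts=intercepts,
    )
    return bank, reports


def estimate_srf(
    S,
    R,
    fixed_delay: int = 0,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[FilterBank, list[FitReport]]:
    """Reduced frequency-only encoding filter at one fixed delay.

    With a 30-channel spectrogram the SRF-based response model has 31
    free parameters per neuron: 30 channel weights plus the optimized
    response delay.
    """
    return estimate_encoding_filters(
        S, R, [int(fixed_delay)], lambda_grid, n_folds, seed
    )


def estimate_decoding_filters(
    R,
    S,
    delays,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[FilterBank, list[FitReport]]:
    """Fit population decoding filters g(tau, n).

    Each stimulus channel is regressed jointly on all neurons' lagged
    responses (the CV chooses one penalty per channel); the fitted
    weights are regrouped into one frequency x delay filter per neuron.
    """
    S_mat = _as_matrix(S)
    R_mat = _as_matrix(R)
    if S_mat.shape[1] != R_mat.shape[1]:
        raise ValueError("responses and stimulus must be aligned in time")
    delays = np.asarray(delays, dtype=int)
    X = lagged_design(R_mat, delays)
    G_flat, reports, intercepts = _multi_target_ridge(X, S_mat.T, lambda_grid, n_folds)
    n_neurons = R_mat.shape[0]
    n_channels = S_mat.shape[0]
    # G_flat rows are (neuron, delay) pairs, columns are channels
    W = G_flat.reshape(n_neurons, delays.size, n_channels).transpose(0, 2, 1)
    channels = S.channels if isinstance(S, Spectrogram) else None
    bank = FilterBank(
        kind="decoding",
        W=W,
        delays=delays,
        channels=channels,
        ridge_lambda=np.array([r.chosen_lambda for r in reports]),
        intercepts=intercepts,
    )
    return bank, reports


def reconstruct_stimulus(R, decoding: FilterBank) -> np.ndarray:
    """Linear stimulus reconstruction from population responses.

    ``s_hat_i(t) = sum_n sum_tau g_i(tau, n) r(t - tau, n)``.
    """
    R_mat = _as_matrix(R)
    if decoding.kind != "decoding":
        raise ValueError("need a decoding filter bank")
    if R_mat.shape[0] != decoding.n_units:
        raise ValueError("response rows must match decoding bank units")
    X = lagged_design(R_mat, decoding.delays)
    # columns of the design are (neuron, delay); regroup W to match
    G = decoding.W.transpose(0, 2, 1).reshape(-1, decoding.W.shape[1])
    out = X @ G
    if decoding.intercepts is not None:
        out = out + decoding.intercepts
    return out.T


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 for degenerate (constant) inputs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def channel_averaged_cc(S_hat: np.ndarray, S: np.ndarray) -> float:
    """Reconstruction accuracy: per-channel Pearson cc averaged over channels."""
    S_hat, S = _as_matrix(S_hat), _as_matrix(S)
    return float(np.mean([pearson_cc(S_hat[i], S[i]) for i in range(S.shape[0])]))


def extract_pf(
    R,
    S,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    delay_scan=None,
    seed: int = 0,
) -> tuple[FilterBank, int, np.ndarray]:
    """Frequency-only decoding filters: the empirical predictive fields.

    The decoding regression is restricted to a single delay.  Because
    responses lag the stimulus, the stimulus is shifted back by each
    candidate delay (default 0-200 ms in 10 ms steps) before the fit,
    and the shift maximizing the training-set reconstruction cc
    (channel-averaged) is kept.  Returns the reduced bank at the best
    delay, the best delay in bins, and the per-scanned-delay cc curve.
    Use ``pf_matrix`` to turn the bank into nonnegative model PFs.
    """
    S_mat = _as_matrix(S)
    R_mat = _as_matrix(R)
    dt = S.dt if isinstance(S, Spectrogram) else 0.01
    if delay_scan is None:
        delay_scan = np.arange(0, int(round(0.2 / dt)) + 1)
    delay_scan = np.asarray(delay_scan, dtype=int)
    ccs = np.empty(delay_scan.size)
    banks = []
    for di, d in enumerate(delay_scan):
        S_shift = np.zeros_like(S_mat)
        S_shift[:, d:] = S_mat[:, : S_mat.shape[1] - d] if d else S_mat
        bank, _ = estimate_decoding_filters(
            R_mat, S_shift, [0], lambda_grid, n_folds, seed
        )
        ccs[di] = channel_averaged_cc(reconstruct_stimulus(R_mat, bank), S_shift)
        banks.append(bank)
    best = int(np.argmax(ccs))
    bank = banks[best]
    if isinstance(S, Spectrogram):
        bank.channels = S.channels
    return bank, int(delay_scan[best]), ccs


def pf_matrix(bank: FilterBank) -> tuple[np.ndarray, np.ndarray]:
    """Rectify and unit-max normalize reduced decoding filters into PFs.

    Returns ``(Q, all_negative)``: Q is (channels x neurons) with each
    column clipped at zero and scaled to unit maximum; columns with no
    positive part come back flat zero and are flagged (such neurons are
    excluded from further analysis).
    """
    V = bank.reduced.T.copy()  # (channels, neurons)
    all_negative = V.max(axis=0) <= 0
    Q = np.clip(V, 0.0, None)
    peaks = Q.max(axis=0)
    peaks[peaks == 0] = 1.0
    return Q / peaks, all_negative


def select_neurons(
    R,
    S,
    threshold: float = 0.2,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    delays=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep neurons whose individual reconstruction beats ``threshold``.

    Each neuron alone reconstructs the stimulus through its own decoding
    fit; neurons with channel-averaged cc > threshold survive, and
    neurons with completely negative decoding filters are dropped
    regardless.  Returns (kept indices, per-neuron cc).
    """
    if not -1 <= threshold < 1:
        raise ValueError("threshold must lie in [-1, 1)")
    S_mat = _as_matrix(S)
    R_mat = _as_matrix(R)
    dt = S.dt if isinstance(S, Spectrogram) else 0.01
    if delays is None:
        delays = np.arange(0, int(round(0.2 / dt)) + 1, 2)
    ccs = np.empty(R_mat.shape[0])
    keep = []
    for n in range(R_mat.shape[0]):
        bank, _ = estimate_decoding_filters(
            R_mat[n : n + 1], S_mat, delays, lambda_grid, n_folds, seed
        )
        ccs[n] = channel_averaged_cc(
            reconstruct_stimulus(R_mat[n : n + 1], bank), S_mat
        )
        if ccs[n] > threshold and bank.W.max() > 0:
            keep.append(n)
    return np.asarray(keep, dtype=int), ccs


def optimal_response_delay(
    pred: np.ndarray,
    target: np.ndarray,
    scan_bins=None,
) -> tuple[int, float]:
    """Delay (in bins) of the target that maximizes Pearson cc to pred.

    Scans shifting the target earlier by 0..20 bins (0-200 ms at 10 ms
    binning) by default; ties break to the smallest delay, and constant
    segments score cc = 0.  The chosen delay is meant to be fixed on
    training data and reused unchanged on test data.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if scan_bins is None:
        scan_bins = np.arange(0, 21)
    scan_bins = np.asarray(scan_bins, dtype=int)
    if scan_bins.max() >= pred.size:
        raise ValueError("delay scan exceeds data length")
    best_d, best_cc = int(scan_bins[0]), -np.inf
    for d in scan_bins:
        cc = pearson_cc(pred[: pred.size - d] if d else pred, target[d:])
        if cc > best_cc + 1e-12:
            best_d, best_cc = int(d), cc
    return best_d, float(best_cc)


def half_max_width(w: np.ndarray, octaves_per_channel: float | None = None) -> float:
    """Full width at half maximum of a 1-D filter, around its peak.

    Walks from the peak to the first crossings below half maximum on
    each side with linear interpolation; width is in channels, or in
    octaves when the channel spacing is given.  Negative lobes are
    ignored (the metric describes the positive peak).
    """
    w = np.asarray(w, dtype=float)
    peak = int(np.argmax(w))
    half = w[peak] / 2.0
    if w[peak] <= 0:
        return 0.0

    def _cross(direction: int) -> float:
        i = peak
        while 0 <= i + direction < w.size and w[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= w.size:
            return abs(i - peak) + 0.5  # ran off the edge; credit half a bin
        # linear interpolation between i (>= half) and j (< half)
        frac = (w[i] - half) / (w[i] - w[j])
        return abs(i - peak) + frac

    width = _cross(-1) + _cross(+1)
    if octaves_per_channel is not None:
        width *= octaves_per_channel
    return float(width)


def octave_band_mass(
    w: np.ndarray, octaves_per_channel: float, band_octaves: float = 1.0
) -> float:
    """Fraction of a filter's positive mass within +/- band_octaves of its peak."""
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    total = w.sum()
    if total == 0:
        return 0.0
    peak = int(np.argmax(w))
    radius = int(round(band_octaves / octaves_per_channel))
    lo, hi = max(0, peak - radius), min(w.size, peak + radius + 1)
    return float(w[lo:hi].sum() / total)
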