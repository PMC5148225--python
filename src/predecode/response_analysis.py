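"""Event-triggered response analysis: transient vs sustained receptive fields.

After a sudden power increase near a neuron's best frequency, cortical
and model responses show a strong but weakly selective transient phase
followed by a sharper, weaker sustained phase, as divisive competition
between detectors accumulates.  This module finds such events in a
spectrogram (local maxima of the band-averaged power derivative),
estimates encoding filters restricted to the 100 ms transient and the
following 100 ms sustained windows, and provides the cross-covariance
and derivative-correlation summaries used to compare model predictions
against recorded rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import (
    FilterBank,
    FitReport,
    DEFAULT_LAMBDA_GRID,
    estimate_encoding_filters,
    pearson_cc,
)
from .generative import Spectrogram


@dataclass
class EventTable:
    """Detected stimulus events for a set of neurons.

    One row per event: neuron index, event time bin, and the neuron's
    best-frequency channel.  Consecutive events of a neuron are at least
    the minimum separation apart and capped in number.
    """

    table: pd.DataFrame  # columns: neuron, time_bin, best_frequency

    def events_for(self, neuron: int) -> np.ndarray:
        sel = self.table[self.table["neuron"] == neuron]
        return sel["time_bin"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def best_frequency(encoding_1d: np.ndarray) -> int:
    """Channel of the maximum of a frequency-only encoding filter.

    Ties break to the lowest channel; a constant filter has no best
    frequency and is rejected.
    """
    w = np.asarray(encoding_1d, dtype=float)
    if np.all(w == w[0]):
        raise ValueError("constant filter has no best frequency")
    return int(np.argmax(w))


def detect_events(
    S,
    bf: int,
    band_halfwidth: int = 10,
    max_events: int = 150,
    min_sep_ms: float = 200.0,
    dt: float | None = None,
) -> np.ndarray:
    """Sudden power increases near a best frequency.

    Averages the spectrogram over ``bf +/- band_halfwidth`` channels
    (clipped at the edges), takes the first difference, finds its local
    maxima, and greedily keeps the largest peaks subject to the minimum
    separation (ties go to the earlier peak).  At most ``max_events``
    event bins are returned, time-sorted; fewer exist on quiet stimuli.
    """
    if isinstance(S, Spectrogram):
        mat, dt = S.S, S.dt
    else:
        mat = np.asarray(S, dtype=float)
        dt = dt or 0.01
    lo = max(0, bf - band_halfwidth)
    hi = min(mat.shape[0], bf + band_halfwidth + 1)
    band = mat[lo:hi].mean(axis=0)
    d = np.diff(band)
    # strict local maxima of the derivative
    peaks = np.where((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))[0] + 1
    if peaks.size == 0:
        return np.array([], dtype=int)
    min_sep = int(round(min_sep_ms / 1000.0 / dt))
    order = peaks[np.lexsort((peaks, -d[peaks]))]  # height desc, time asc on ties
    chosen: list[int] = []
    for p in order:
        if all(abs(p - c) >= min_sep for c in chosen):
            chosen.append(int(p))
        if len(chosen) == max_events:
            break
    # event time = bin of the increase (derivative index t refers to the
    # jump from bin t to t+1, so the response window starts at t+1)
    return np.sort(np.asarray(chosen, dtype=int) + 1)


def build_event_table(
    S, encoding_1d: np.ndarray, **kwargs
) -> EventTable:
    """Detect events for every neuron of a (neurons x channels) SRF matrix."""
    rows = []
    for n in range(encoding_1d.shape[0]):
        bf = best_frequency(encoding_1d[n])
        for t in detect_events(S, bf, **kwargs):
            rows.append({"neuron": n, "time_bin": int(t), "best_frequency": bf})
    return EventTable(pd.DataFrame(rows, columns=["neuron", "time_bin", "best_frequency"]))


def _window_mask(
    events: np.ndarray, T: int, start_bins: int, stop_bins: int
) -> np.ndarray:
    mask = np.zeros(T, dtype=bool)
    for e in events:
        if e + stop_bins <= T:
            mask[e + start_bins : e + stop_bins] = True
    return mask


def windowed_rf(
    S,
    R,
    events: np.ndarray,
    window: str,
    delays=(0,),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    dt: float | None = None,
) -> tuple[FilterBank | None, list[FitReport], np.ndarray]:
    """Encoding filters restricted to transient or sustained windows.

    Transient = the first 100 ms after an event; sustained = the next
    100 ms (10 bins each at 10 ms binning; other bin widths scale with
    rounding down).  Events whose full 200 ms window runs past the end
    of the data are dropped.  Also returns the event-aligned mean
    response over the 200 ms window, per neuron.
    """
    if window not in ("transient", "sustained"):
        raise ValueError("window must be 'transient' or 'sustained'")
    if isinstance(S, Spectrogram):
        dt = S.dt
    dt = dt or 0.01
    w = max(1, int(0.1 / dt))  # bins per 100 ms window
    R_mat = R.S if hasattr(R, "S") else np.asarray(R, dtype=float)
    T = R_mat.shape[1]
    events = np.asarray(events, dtype=int)
    events = events[events + 2 * w <= T]

    n_neurons = R_mat.shape[0]
    aligned = np.zeros((n_neurons, 2 * w))
    if events.size:
        for e in events:
            aligned += R_mat[:, e : e + 2 * w]
        aligned /= events.size

    if events.size == 0:
        return None, [], aligned
    start = 0 if window == "transient" else w
    mask = _window_mask(events, T, start, start + w)
    bank, reports = estimate_encoding_filters(
        S, R_mat, delays, lambda_grid, n_folds, seed, time_mask=mask
    )
    return bank, reports, aligned


def mean_cross_covariance(
    pred: np.ndarray,
    target: np.ndarray,
    max_lag_bins: int = 20,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized cross-covariance profile between predictions and data.

    For each neuron, the Pearson correlation between ``pred(t)`` and
    ``target(t + lag)`` over lags ``-max_lag..max_lag``, averaged over
    neurons; the confidence band is a 95% bootstrap over neurons.
    Returns (lags, mean profile, (2, n_lags) band).
    """
    P = np.atleast_2d(np.asarray(pred, dtype=float))
    Tg = np.atleast_2d(np.asarray(target, dtype=float))
    if P.shape != Tg.shape:
        raise ValueError("pred and target must have the same shape")
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    profiles = np.zeros((P.shape[0], lags.size))
    for n in range(P.shape[0]):
        for li, lag in enumerate(lags):
            if lag >= 0:
                a, b = P[n, : P.shape[1] - lag], Tg[n, lag:]
            else:
                a, b = P[n, -lag:], Tg[n, : P.shape[1] + lag]
            profiles[n, li] = pearson_cc(a, b)
    mean = profiles.mean(axis=0)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, lags.size))
    for b in range(n_bootstrap):
        idx = rng.integers(0, P.shape[0], P.shape[0])
        boot[b] = profiles[idx].mean(axis=0)
    band = np.percentile(boot, [2.5, 97.5], axis=0)
    return lags, mean, band


def derivative_match(pred: np.ndarray, target: np.ndarray, order: int = 1) -> float:
    """Pearson cc between the order-th finite differences of two traces.

    Differencing removes offsets and slow trends, so this emphasizes how
    well the fast dynamics of a prediction track the data.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    return pearson_cc(
        np.diff(np.asarray(pred, dtype=float), n=order),
        np.diff(np.asarray(target, dtype=float), n=order),
    )
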