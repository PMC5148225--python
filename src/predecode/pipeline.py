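"""End-to-end prediction pipeline: PFs from data, model vs baselines.

The workflow this package was built around: extract each neuron's
frequency-only decoding filter (PF) from a training segment, plug the
PFs into the Bayesian inference model as the feature-to-receptor
weights, and treat each detector's rectified firing rate as the
prediction for its paired neuron.  Baselines are the same model with
explaining away removed and a rectified SRF (frequency-only encoding
filter) convolution.  Per-neuron response delays are fixed on training
data; accuracies (Pearson cc, derivative cc, stimulus-reconstruction
cc) are averaged over contiguous outer cross-validation folds.

Three global free parameters shape the Bayesian predictions: the
switching rates r_on, r_off (Hz) shared by all neurons, and a gain
restoring the intensity scale of the unit-max normalized PFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import (
    DEFAULT_LAMBDA_GRID,
    channel_averaged_cc,
    contiguous_folds,
    estimate_decoding_filters,
    estimate_srf,
    extract_pf,
    optimal_response_delay,
    pearson_cc,
    pf_matrix,
    reconstruct_stimulus,
)
from .generative import GenerativeParams, ReceptorObservations, Spectrogram
from .inference import InferenceConfig, run_inference, run_no_inhibition
from .response_analysis import derivative_match


@dataclass
class RunConfig:
    """Settings for :func:`run_predict`.

    r_on, r_off : feature switching rates in Hz, shared by all neurons.
    gain : global scale applied to the unit-max extracted PFs before
        they enter the model (the PFs are fit to a normalized shape; the
        gain restores their intensity scale relative to the stimulus).
        When ``gain_grid`` is set the gain is chosen once, on the first
        training fold, to maximize the intact model's mean prediction
        cc, then held fixed ("globally optimized").
    q0_baseline : the model's assumed baseline intensity per channel;
        ``None`` estimates it from the stimulus as the per-channel 10th
        percentile.
    n_outer_folds / n_inner_folds : contiguous-block CV; the outer loop
        scores predictions, the inner loop picks ridge penalties.
    pf_delay_scan / response_delay_scan : delay grids in bins for PF
        extraction and for aligning predictions with responses.
    """

    r_on: float = 1.0
    r_off: float = 20.0
    gain: float = 1.0
    gain_grid: tuple | None = None
    q0_baseline: float | None = None
    lambda_grid: tuple = tuple(DEFAULT_LAMBDA_GRID)
    n_outer_folds: int = 10
    n_inner_folds: int = 5
    pf_delay_scan: tuple = tuple(range(0, 11, 2))
    response_delay_scan: tuple = tuple(range(0, 21))
    decoding_delays: tuple = tuple(range(0, 11, 2))
    seed: int = 0

    def inference_config(self, gain: float | None = None) -> InferenceConfig:
        return InferenceConfig(gain=self.gain if gain is None else gain)


def _bayesian_predictions(
    S: np.ndarray,
    Q: np.ndarray,
    config: RunConfig,
    gain: float,
    dt: float,
    no_inhibition: bool,
    q0: np.ndarray,
) -> np.ndarray:
    params = GenerativeParams(
        Q=gain * Q,
        q0=q0,
        r_on=config.r_on,
        r_off=config.r_off,
        dt=dt,
    )
    obs = ReceptorObservations(S=S, dt=dt)
    runner = run_no_inhibition if no_inhibition else run_inference
    return runner(obs, params, config.inference_config(1.0)).F


def _scored_cc(pred: np.ndarray, target: np.ndarray, delay: int) -> float:
    if delay:
        pred, target = pred[:-delay], target[delay:]
    return pearson_cc(pred, target)


def _scored_deriv(pred: np.ndarray, target: np.ndarray, delay: int, order: int) -> float:
    if delay:
        pred, target = pred[:-delay], target[delay:]
    return derivative_match(pred, target, order)


def run_predict(S, R, config: RunConfig | None = None) -> dict:
    """Predict neural responses from extracted PFs, fold by fold.

    ``S`` is the stimulus (Spectrogram or channels x time array), ``R``
    the trial-averaged responses (neurons x time).  Returns a dict with
    mean test-set prediction cc, first/second-derivative cc, and
    stimulus-reconstruction cc for the intact model, the no-inhibition
    ablation, the SRF encoding baseline, and (for reconstruction) the
    recorded responses themselves, plus the chosen global parameters.
    """
    config = config or RunConfig()
    dt = S.dt if isinstance(S, Spectrogram) else 0.01
    S_mat = S.S if isinstance(S, Spectrogram) else np.asarray(S, dtype=float)
    R_mat = np.asarray(R, dtype=float)
    if R_mat.size == 0:
        raise ValueError("empty response matrix")
    if S_mat.shape[1] != R_mat.shape[1]:
        raise ValueError("stimulus and responses must be aligned in time")
    T = S_mat.shape[1]
    max_delay = max(config.response_delay_scan)
    if T // config.n_outer_folds <= max_delay:
        raise ValueError(
            f"outer folds of {T // config.n_outer_folds} bins are too short for "
            f"the {max_delay}-bin delay scan; need > {max_delay} bins per fold"
        )

    if config.q0_baseline is None:
        q0 = np.maximum(np.percentile(S_mat, 10, axis=1), 1e-3)
    else:
        q0 = np.full(S_mat.shape[0], config.q0_baseline)

    folds = contiguous_folds(T, config.n_outer_folds)
    models = ("intact", "no_inhibition", "srf")
    cc = {m: [] for m in models}
    d1 = {m: [] for m in models}
    d2 = {m: [] for m in models}
    recon = {m: [] for m in ("data",) + models}
    gain = config.gain
    gain_chosen = False

    for k, test_idx in enumerate(folds):
        train_mask = np.ones(T, dtype=bool)
        train_mask[test_idx] = False
        S_tr, R_tr = S_mat[:, train_mask], R_mat[:, train_mask]
        S_te, R_te = S_mat[:, test_idx], R_mat[:, test_idx]

        pf_bank, _, _ = extract_pf(
            R_tr,
            S_tr,
            lambda_grid=config.lambda_grid,
            n_folds=config.n_inner_folds,
            delay_scan=config.pf_delay_scan,
            seed=config.seed,
        )
        Q, _ = pf_matrix(pf_bank)  # (channels, neurons), unit max

        if config.gain_grid and not gain_chosen:
            best = (-np.inf, gain)
            for g in config.gain_grid:
                F_tr = _bayesian_predictions(S_tr, Q, config, g, dt, False, q0)
                score = np.mean(
                    [
                        _scored_cc(F_tr[n], R_tr[n],
                                   optimal_response_delay(
                                       F_tr[n], R_tr[n],
                                       config.response_delay_scan)[0])
                        for n in range(R_mat.shape[0])
                    ]
                )
                if score > best[0]:
                    best = (score, g)
            gain = best[1]
            gain_chosen = True

        preds_full = {
            "intact": _bayesian_predictions(S_mat, Q, config, gain, dt, False, q0),
            "no_inhibition": _bayesian_predictions(S_mat, Q, config, gain, dt, True, q0),
        }
        srf_bank, _ = estimate_srf(
            S_tr, R_tr, 0, config.lambda_grid, config.n_inner_folds, config.seed
        )
        preds_full["srf"] = np.maximum(
            srf_bank.reduced @ S_mat + srf_bank.intercepts[:, None], 0.0
        )

        dec_bank, _ = estimate_decoding_filters(
            R_tr, S_tr, config.decoding_delays,
            config.lambda_grid, config.n_inner_folds, config.seed,
        )

        for m in models:
            P_tr = preds_full[m][:, train_mask]
            P_te = preds_full[m][:, test_idx]
            fold_cc, fold_d1, fold_d2 = [], [], []
            for n in range(R_mat.shape[0]):
                d, _ = optimal_response_delay(
                    P_tr[n], R_tr[n], config.response_delay_scan
                )
                fold_cc.append(_scored_cc(P_te[n], R_te[n], d))
                fold_d1.append(_scored_deriv(P_te[n], R_te[n], d, 1))
                fold_d2.append(_scored_deriv(P_te[n], R_te[n], d, 2))
            cc[m].append(np.mean(fold_cc))
            d1[m].append(np.mean(fold_d1))
            d2[m].append(np.mean(fold_d2))
            recon[m].append(
                channel_averaged_cc(
                    reconstruct_stimulus(P_te, dec_bank), S_te
                )
            )
        recon["data"].append(
            channel_averaged_cc(reconstruct_stimulus(R_te, dec_bank), S_te)
        )

    return {
        "prediction_cc": {m: float(np.mean(cc[m])) for m in models},
        "derivative1_cc": {m: float(np.mean(d1[m])) for m in models},
        "derivative2_cc": {m: float(np.mean(d2[m])) for m in models},
        "reconstruction_cc": {m: float(np.mean(v)) for m, v in recon.items()},
        "chosen": {
            "gain": float(gain),
            "r_on": config.r_on,
            "r_off": config.r_off,
            "n_outer_folds": config.n_outer_folds,
        },
    }
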