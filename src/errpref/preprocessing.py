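"""From continuous/raw EEG to clean labeled epochs.

Order of operations mirrors standard acquisition practice: power-line notch,
1-Hz zero-phase high-pass, EOG regression (coefficients from the calibration
recording's autocovariance), epoching at [-0.2, 0.6] s around the onset, a
reaction-time trial filter, and artifact rejection by channel-wise joint log
probabilities of the epoch amplitude values
(``J_c(i) = -sum_{x in A_i} log p_{D_c}(x)``, flag when any channel's J
exceeds its mean + 3 SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .synthetic import EEG_CHANNELS, SFREQ, TrialRecord

__all__ = [
    "EpochSet",
    "highpass_filter",
    "notch_filter",
    "eog_regression_coefficients",
    "remove_eog",
    "assign_onsets",
    "reaction_time_filter",
    "joint_log_probability",
    "crop_epochs",
]


@dataclass
class EpochSet:
    """Per-trial multi-channel EEG segments with labels and rejection flags.

    ``data`` is (n_trials, n_channels, n_samples) in uV; ``labels`` is True
    for erroneous (released) trials; ``rejected`` marks artifactual trials.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float = SFREQ
    ch_names: Sequence[str] = tuple(EEG_CHANNELS)
    labels: Optional[np.ndarray] = None
    rejected: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.labels is None:
            self.labels = np.zeros(self.data.shape[0], dtype=bool)
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if len(self.labels) != self.data.shape[0] or len(self.rejected) != self.data.shape[0]:
            raise ValueError("labels/rejected must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _butter_zero_phase(data, sfreq, cutoff, btype, order=2):
    nyq = sfreq / 2.0
    if np.max(cutoff) >= nyq:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, np.asarray(cutoff) / nyq, btype=btype, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def highpass_filter(data: np.ndarray, sfreq: float = SFREQ, cutoff: float = 1.0,
                    order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass; removes DC/drift."""
    return _butter_zero_phase(data, sfreq, cutoff, "highpass", order)


def notch_filter(data: np.ndarray, sfreq: float = SFREQ, freq: float = 50.0,
                 quality: float = 30.0) -> np.ndarray:
    """Zero-phase power-line notch (IIR, applied forward-backward)."""
    if freq >= sfreq / 2.0:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(freq, quality, fs=sfreq)
    return signal.filtfilt(b, a, data, axis=-1)


def eog_regression_coefficients(eeg: np.ndarray, eog: np.ndarray,
                                ridge: float = 0.0) -> np.ndarray:
    """EOG-removal coefficients from the calibration autocovariance.

    ``b = Cov(EOG, EOG)^{-1} Cov(EOG, EEG)``, shape (n_eog, n_eeg); corrected
    EEG is ``eeg - b.T @ eog``. A singular EOG autocovariance falls back to a
    small ridge (reported via the returned matrix being computed with it).
    """
    eog = eog - eog.mean(axis=1, keepdims=True)
    eeg = eeg - eeg.mean(axis=1, keepdims=True)
    n = eog.shape[1]
    cov_oo = eog @ eog.T / n
    cov_oe = eog @ eeg.T / n
    if ridge == 0.0 and np.linalg.cond(cov_oo) > 1e12:
        ridge = 1e-10 * np.trace(cov_oo) / cov_oo.shape[0]
    if ridge:
        cov_oo = cov_oo + ridge * np.eye(cov_oo.shape[0])
    return np.linalg.solve(cov_oo, cov_oe)


def remove_eog(eeg: np.ndarray, eog: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Subtract the regressed EOG contribution from the EEG channels."""
    return eeg - coeffs.T @ eog


def assign_onsets(trials: Sequence[TrialRecord]) -> np.ndarray:
    """Per-trial epoching onsets relative to trajectory start.

    Erroneous trials: the joystick release time. Correct trials: the
    subject's mean release time over erroneous trials (the participant gave
    no behavioral response, so the average evaluation latency stands in).
    """
    releases = [t.release_time for t in trials if t.released]
    if not releases:
        raise ValueError("onset assignment needs at least one erroneous trial")
    mean_rt = float(np.mean(releases))
    return np.array([t.release_time if t.released else mean_rt for t in trials])


def reaction_time_filter(trials: Sequence[TrialRecord], trial_lengths,
                         min_rt: float = 0.5) -> np.ndarray:
    """Keep-mask removing erroneous trials with RT < 0.5 s or > half the trial.

    Too-early releases cannot reflect an evaluation of the avoidance, and
    too-late ones occur after the robot has overtaken the obstacle. Correct
    trials are always retained. Idempotent on the retained set.
    """
    trial_lengths = np.broadcast_to(np.asarray(trial_lengths, dtype=float), (len(trials),))
    keep = np.ones(len(trials), dtype=bool)
    for i, t in enumerate(trials):
        if t.released and (t.release_time < min_rt or t.release_time > trial_lengths[i] / 2.0):
            keep[i] = False
    return keep


def joint_log_probability(data: np.ndarray, n_bins: int = 100,
                          threshold_sd: float = 3.0):
    """Channel-wise joint log probabilities and artifact flags.

    Per channel, the empirical amplitude density over all trials is estimated
    with a fixed-bin histogram (``n_bins`` over the pooled min-max); the
    joint log probability of trial i is ``J_c(i) = -sum log p(x)`` over its
    samples. A trial is flagged when J on at least one channel exceeds that
    channel's mean + ``threshold_sd`` * SD. Zero-density bins are floored at
    a machine-epsilon-scaled minimum.

    Returns ``(J, flags)`` with J of shape (n_trials, n_channels).
    """
    n_trials, n_ch, n_samp = data.shape
    if n_trials < 20:
        raise ValueError("joint-log-probability rejection needs >= 20 trials")
    J = np.empty((n_trials, n_ch))
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        hist, edges = np.histogram(pooled, bins=n_bins, density=True)
        floor = np.finfo(float).eps * max(hist.max(), 1.0)
        hist = np.maximum(hist, floor)
        idx = np.clip(np.searchsorted(edges, data[:, c, :], side="right") - 1,
                      0, n_bins - 1)
        J[:, c] = -np.sum(np.log(hist[idx]), axis=-1)
    thresh = J.mean(axis=0) + threshold_sd * J.std(axis=0)
    flags = np.any(J > thresh, axis=1)
    return J, flags


def crop_epochs(data: np.ndarray, times: np.ndarray, window):
    """Crop epochs (…, n_samples) to a time window; returns (data, times)."""
    mask = (times >= window[0] - 1e-9) & (times < window[1] - 1e-9)
    if not mask.any():
        raise ValueError("crop window outside epoch extent")
    return data[..., mask], times[mask]
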