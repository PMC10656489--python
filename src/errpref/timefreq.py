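"""Stockwell S-transform and event-related spectral perturbation (ERSP).

The S-transform localises the Fourier spectrum with a Gaussian window whose
width scales inversely with frequency,

    S(tau, f) = |f|/sqrt(2 pi) * integral x(t) exp(-(tau-t)^2 f^2 / 2)
                                        exp(-2 i pi f t) dt,

combining wavelet-like locality with absolutely referenced Fourier phase.
Here it is evaluated as an FFT-based convolution of x(t) e^{-2 i pi f t}
with the frequency-scaled Gaussian — exact linear convolution, so it matches
direct numerical quadrature of the defining integral to rounding error.

The ERSP expresses average erroneous-trial power relative to the correct-
trial baseline spectrum mu(f) (mean power over [-0.1, 0.4] s) in dB:
ERSP(f, t) = 10 log10(ERS(f, t) / mu(f)).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _sig

__all__ = [
    "s_transform",
    "trial_power",
    "baseline_spectrum",
    "ersp",
    "compute_ersp",
    "band_power_map",
]

DEFAULT_FREQS = np.arange(1.0, 31.0)  # 1 Hz steps over [1, 30] Hz


def s_transform(x: np.ndarray, sfreq: float, freqs=DEFAULT_FREQS) -> np.ndarray:
    """S-transform of a single-channel epoch.

    Parameters
    ----------
    x : ndarray, shape (n_samples,)
    sfreq : sampling rate in Hz.
    freqs : analysis frequencies in Hz; a frequency of exactly 0 yields the
        signal mean by convention.

    Returns
    -------
    S : complex ndarray, shape (n_freqs, n_samples).
    """
    x = np.asarray(x, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(np.abs(freqs) > sfreq / 2.0):
        raise ValueError("requested frequency above Nyquist")
    n = x.size
    dt = 1.0 / sfreq
    t = np.arange(n) * dt
    # kernel support centered at zero lag, long enough for exact linear conv
    kt = (np.arange(2 * n - 1) - (n - 1)) * dt
    S = np.empty((freqs.size, n), dtype=complex)
    for i, f in enumerate(freqs):
        if f == 0:
            S[i] = x.mean()
            continue
        h = x * np.exp(-2j * np.pi * f * t)
        g = np.abs(f) / np.sqrt(2 * np.pi) * np.exp(-0.5 * (kt * f) ** 2)
        S[i] = _sig.fftconvolve(h, g, mode="full")[n - 1:2 * n - 1] * dt
    return S


def trial_power(epochs: np.ndarray, sfreq: float, freqs=DEFAULT_FREQS) -> np.ndarray:
    """Mean |S|^2 across trials for one channel: (n_trials, n_samples) input,
    (n_freqs, n_samples) output."""
    acc = None
    for ep in epochs:
        p = np.abs(s_transform(ep, sfreq, freqs)) ** 2
        acc = p if acc is None else acc + p
    return acc / len(epochs)


def baseline_spectrum(power: np.ndarray, times: np.ndarray,
                      window=(-0.1, 0.4)) -> np.ndarray:
    """Per-frequency baseline mu(f): power averaged over the window."""
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    mu = power[:, mask].mean(axis=1)
    if np.any(mu <= 0):
        raise ValueError("baseline spectrum must be strictly positive")
    return mu


def ersp(error_power: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """ERSP(f, t) = 10 log10(ERS(f, t) / mu(f)) in dB."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline spectrum must be strictly positive")
    return 10.0 * np.log10(error_power / baseline[:, None])


def compute_ersp(data: np.ndarray, labels: np.ndarray, times: np.ndarray,
                 sfreq: float, freqs=DEFAULT_FREQS,
                 baseline_window=(-0.1, 0.4)) -> np.ndarray:
    """Per-channel ERSP of erroneous trials against the correct-trial baseline.

    ``data`` is (n_trials, n_channels, n_samples); ``labels`` True for
    erroneous trials. Returns (n_channels, n_freqs, n_samples) in dB; the
    baseline mu(f) is channel-specific.
    """
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both erroneous and correct trials are required")
    out = []
    for c in range(data.shape[1]):
        err = trial_power(data[labels, c], sfreq, freqs)
        corr = trial_power(data[~labels, c], sfreq, freqs)
        mu = baseline_spectrum(corr, times, baseline_window)
        out.append(ersp(err, mu))
    return np.stack(out)


def band_power_map(ersp_maps: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                   band, window=(-0.1, 0.4)) -> np.ndarray:
    """Mean ERSP over a frequency band x time window, per channel.

    ``ersp_maps`` is (n_channels, n_freqs, n_samples); returns (n_channels,).
    """
    fmask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    tmask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not fmask.any() or not tmask.any():
        raise ValueError("empty band/window intersection")
    return ersp_maps[:, fmask][:, :, tmask].mean(axis=(1, 2))
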