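"""Synthetic subjects, behavior, and EEG with the structure the analysis assumes.

The generator emulates the study conditions end to end so every downstream
stage can be exercised without recorded data:

* trials: controller parameters drawn uniformly, rho ~ U[1, 8], s ~ U[1.0, 1.5],
  ~400 trials per subject;
* behavior: each synthetic subject holds a linear evaluation criterion in
  (efficiency, comfort) space; the probability of releasing the joystick
  (rejecting the trajectory) is a logistic function of the criterion score,
  with a decision temperature for trial-to-trial noise. Release latencies are
  truncated-Gaussian around 1.08 s (SD 0.14 s);
* EEG: 16 channels (frontocentral 10/10 montage) plus 3 EOG channels at
  512 Hz. Background activity is AR(1)-colored Gaussian noise. Rejected
  (erroneous) trials carry an error-related potential: a negative deflection
  (ERN) at the response, a positive deflection (Pe) near 0.25 s, plus theta
  (4-8 Hz) and mu (8-12 Hz) oscillatory bursts, all with a frontocentral
  spatial profile peaking at FCz. Accepted trials carry background only;
* calibration: a 90-s recording in three 30-s segments of stereotyped eye
  activity, with a known EOG-to-EEG mixing matrix kept as ground truth;
* artifacts: a configurable fraction of epochs scaled to gross amplitude
  outliers, with ground-truth flags, to exercise the joint-log-probability
  rejection stage.

Every operation is deterministic under its seed / Generator argument.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EEG_CHANNELS",
    "EOG_CHANNELS",
    "SFREQ",
    "SubjectProfile",
    "TrialRecord",
    "ErrPTemplate",
    "CalibrationRecording",
    "sample_trials",
    "behavioral_response",
    "generate_epoch",
    "generate_epochs",
    "generate_calibration",
    "inject_artifacts",
    "background_noise",
    "generate_cohort_profiles",
    "calibrate_bias",
]

SFREQ = 512.0

EEG_CHANNELS = ["Fz", "FC3", "FC1", "FCz", "FC2", "FC4", "C3", "C1", "Cz",
                "C2", "C4", "CP3", "CP1", "CPz", "CP2", "CP4"]
EOG_CHANNELS = ["EOG1", "EOG2", "EOG3"]

# Approximate planar 10/10 coordinates (left-right, posterior-anterior) used
# only to shape the frontocentral spatial falloff of the ErrP.
_CHANNEL_XY = {
    "Fz": (0, 2),
    "FC3": (-1.5, 1), "FC1": (-0.5, 1), "FCz": (0, 1), "FC2": (0.5, 1), "FC4": (1.5, 1),
    "C3": (-1.5, 0), "C1": (-0.5, 0), "Cz": (0, 0), "C2": (0.5, 0), "C4": (1.5, 0),
    "CP3": (-1.5, -1), "CP1": (-0.5, -1), "CPz": (0, -1), "CP2": (0.5, -1), "CP4": (1.5, -1),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Generative description of one synthetic participant.

    The criterion score of a trial is
    ``z = weight_efficiency * efficiency + weight_comfort * comfort + bias``
    and the release (rejection) probability is ``sigmoid(z / temperature)``;
    ``decision_temperature -> 0`` recovers a deterministic threshold.
    """

    weight_efficiency: float
    weight_comfort: float
    bias: float = 0.0
    decision_temperature: float = 1.0
    errp_gain: float = 5.5          # uV scale of the ERN/Pe complex
    noise_sd: float = 8.0           # uV, background EEG standard deviation
    mean_release_latency: float = 1.08
    latency_sd: float = 0.14
    seed: int = 0

    def __post_init__(self):
        if self.decision_temperature < 0:
            raise ValueError("decision_temperature must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def score(self, efficiency, comfort):
        return (self.weight_efficiency * np.asarray(efficiency)
                + self.weight_comfort * np.asarray(comfort) + self.bias)

    @property
    def boundary_slope(self) -> float:
        """Slope d(comfort)/d(efficiency) of the decision boundary: -w_e/w_c."""
        return -self.weight_efficiency / self.weight_comfort


@dataclass(frozen=True)
class TrialRecord:
    """One trial: controller parameters, costs, and the behavioral outcome."""

    trial_id: int
    rho: float
    s: float
    efficiency: float
    comfort: float
    released: bool
    release_time: Optional[float] = None

    def __post_init__(self):
        if self.released != (self.release_time is not None):
            raise ValueError("release_time must be present iff released")


@dataclass(frozen=True)
class ErrPTemplate:
    """Morphology of the synthetic error-related potential.

    Two Gaussian-windowed half-waves — a negative deflection (ERN) at the
    response and a positive one (Pe) at +0.25 s — plus theta and mu
    oscillatory bursts in their characteristic windows, all scaled by a
    frontocentral spatial profile peaking at FCz. Amplitudes are relative;
    the subject's ``errp_gain`` sets the uV scale.
    """

    ern_latency: float = 0.0
    pe_latency: float = 0.25
    ern_width: float = 0.04
    pe_width: float = 0.06
    ern_amplitude: float = -1.0
    pe_amplitude: float = 0.8
    theta_freq: float = 6.0
    theta_window: tuple = (-0.1, 0.4)
    theta_amplitude: float = 0.5
    mu_freq: float = 10.0
    mu_window: tuple = (-0.1, 0.1)
    mu_amplitude: float = 0.3

    def spatial_profile(self, channels: Sequence[str] = tuple(EEG_CHANNELS)) -> np.ndarray:
        """Cosine-tapered falloff with distance from FCz; peak weight at FCz."""
        fcz = np.array(_CHANNEL_XY["FCz"])
        w = np.empty(len(channels))
        for i, ch in enumerate(channels):
            d = np.linalg.norm(np.array(_CHANNEL_XY[ch]) - fcz)
            w[i] = max(np.cos(np.pi * d / 4.0), 0.0)
        return w

    def waveform(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Unit-gain ErrP time course on ``times`` (s, 0 = event onset)."""
        t = np.asarray(times)
        wave = (self.ern_amplitude * np.exp(-0.5 * ((t - self.ern_latency) / self.ern_width) ** 2)
                + self.pe_amplitude * np.exp(-0.5 * ((t - self.pe_latency) / self.pe_width) ** 2))
        for freq, (lo, hi), amp in ((self.theta_freq, self.theta_window, self.theta_amplitude),
                                    (self.mu_freq, self.mu_window, self.mu_amplitude)):
            mask = (t >= lo) & (t <= hi)
            if not mask.any():
                continue
            phase = rng.uniform(0, 2 * np.pi)
            taper = np.hanning(mask.sum())
            burst = np.zeros_like(t)
            burst[mask] = taper * np.sin(2 * np.pi * freq * t[mask] + phase)
            wave = wave + amp * burst
        return wave


@dataclass
class CalibrationRecording:
    """90-s EOG calibration with ground-truth mixing (for recovery tests)."""

    eeg: np.ndarray       # (16, n_samples), already EOG-contaminated
    eog: np.ndarray       # (3, n_samples)
    mixing: np.ndarray    # (3, 16) ground-truth EOG -> EEG weights
    sfreq: float = SFREQ


# ---------------------------------------------------------------------------
# Trials and behavior
# ---------------------------------------------------------------------------

def sample_trials(n: int, seed=None) -> np.ndarray:
    """Draw n controller-parameter pairs: rho ~ U[1, 8], s ~ U[1.0, 1.5].

    Returns an (n, 2) array of (rho, s); reproducible under ``seed`` (an int
    or a Generator).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rho = rng.uniform(1.0, 8.0, n)
    s = rng.uniform(1.0, 1.5, n)
    return np.column_stack([rho, s])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def release_probability(profile: SubjectProfile, efficiency, comfort):
    """P(release | costs) under the subject's logistic criterion."""
    z = profile.score(efficiency, comfort)
    if profile.decision_temperature == 0:
        return (z > 0).astype(float)
    return _sigmoid(z / profile.decision_temperature)


def behavioral_response(profile: SubjectProfile, costs, rng: np.random.Generator,
                        *, trial_id: int = 0, rho: float = np.nan,
                        s: float = np.nan) -> TrialRecord:
    """Simulate the accept/release decision (and latency) for one trial.

    ``costs`` is anything with ``efficiency`` and ``comfort`` attributes (or a
    2-sequence). Release times are Gaussian around the subject's mean latency,
    truncated positive.
    """
    if hasattr(costs, "efficiency"):
        eff, comf = costs.efficiency, costs.comfort
    else:
        eff, comf = costs
    p = release_probability(profile, eff, comf)
    released = bool(rng.uniform() < p)
    release_time = None
    if released:
        release_time = -1.0
        while release_time <= 0:
            release_time = rng.normal(profile.mean_release_latency, profile.latency_sd)
    return TrialRecord(trial_id=trial_id, rho=rho, s=s, efficiency=float(eff),
                       comfort=float(comf), released=released, release_time=release_time)


def calibrate_bias(profile: SubjectProfile, efficiency, comfort,
                   target_rate: float) -> SubjectProfile:
    """Return a copy of ``profile`` with bias set so that the expected release
    rate over the given cost ensemble is ``target_rate`` (quantile matching)."""
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must be in (0, 1)")
    z = (profile.weight_efficiency * np.asarray(efficiency)
         + profile.weight_comfort * np.asarray(comfort))
    bias = -float(np.quantile(z, 1.0 - target_rate))
    return dataclasses.replace(profile, bias=bias)


def generate_cohort_profiles(n_subjects: int = 17, seed: int = 0, *,
                             errp_gain: float = 5.5, noise_sd: float = 8.0,
                             decision_temperature: float = 0.5,
                             rate_mean: float = 0.27, rate_sd: float = 0.07,
                             angle_range=(10.0, 80.0)):
    """Draw a cohort of distinct subject profiles (biases still uncalibrated).

    Criterion directions are spread over ``angle_range`` degrees (default 10-80) in the
    (efficiency, comfort) plane so that subjects genuinely differ (the
    condition for intra-subject transfer to beat inter-subject transfer), and
    target rejection rates are drawn around the study-scale 27 +/- 7%.

    Returns ``(profiles, target_rates)``; use :func:`calibrate_bias` with each
    subject's simulated costs to fix the bias.
    """
    rng = np.random.default_rng(seed)
    angles = np.deg2rad(rng.permutation(np.linspace(*angle_range, n_subjects)))
    magnitude = 60.0  # criterion steepness relative to unit temperature
    profiles = []
    rates = np.clip(rng.normal(rate_mean, rate_sd, n_subjects), 0.10, 0.45)
    for i in range(n_subjects):
        # negative weights: short (efficient) and low-clearance paths are rejected
        w_e = -magnitude * np.cos(angles[i])
        w_c = -magnitude * np.sin(angles[i])
        profiles.append(SubjectProfile(
            weight_efficiency=w_e, weight_comfort=w_c, bias=0.0,
            decision_temperature=decision_temperature,
            errp_gain=errp_gain, noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31))))
    return profiles, rates


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

def background_noise(shape, noise_sd: float, rng: np.random.Generator,
                     ar_coeff: float = 0.95, spatial_corr: float = 0.5) -> np.ndarray:
    """AR(1)-filtered Gaussian noise with stationary SD ``noise_sd``.

    ``shape`` is (..., n_channels, n_samples); the AR recursion runs along
    the last axis. ``spatial_corr`` sets a uniform inter-channel correlation
    (volume conduction makes neighbouring EEG channels share most of their
    background); it is realised by mixing a common source into every channel
    and applies across the second-to-last axis when present.
    """
    innov_sd = noise_sd * np.sqrt(1.0 - ar_coeff ** 2)
    white = rng.standard_normal(shape) * innov_sd
    noise = signal.lfilter([1.0], [1.0, -ar_coeff], white, axis=-1)
    if spatial_corr > 0 and len(shape) >= 2:
        common_shape = shape[:-2] + (1, shape[-1])
        common = rng.standard_normal(common_shape) * innov_sd
        common = signal.lfilter([1.0], [1.0, -ar_coeff], common, axis=-1)
        noise = np.sqrt(1 - spatial_corr) * noise + np.sqrt(spatial_corr) * common
    return noise


def generate_epoch(profile: SubjectProfile, record: TrialRecord,
                   template: ErrPTemplate, rng: np.random.Generator,
                   window=(-0.5, 1.0), sfreq: float = SFREQ) -> np.ndarray:
    """One 16-channel EEG epoch (channels x samples), t=0 at the event onset.

    Released (erroneous) trials carry the ErrP complex scaled by
    ``profile.errp_gain``; accepted trials are background noise only.
    """
    n = int(round((window[1] - window[0]) * sfreq))
    times = window[0] + np.arange(n) / sfreq
    data = background_noise((len(EEG_CHANNELS), n), profile.noise_sd, rng)
    if record.released:
        wave = template.waveform(times, rng)
        data += profile.errp_gain * np.outer(template.spatial_profile(), wave)
    return data


def generate_epochs(profile: SubjectProfile, records, template: ErrPTemplate,
                    rng: np.random.Generator, window=(-0.5, 1.0),
                    sfreq: float = SFREQ):
    """Batch epoch generation; returns ``(data (n, 16, samples), times)``."""
    n = int(round((window[1] - window[0]) * sfreq))
    times = window[0] + np.arange(n) / sfreq
    data = np.stack([generate_epoch(profile, r, template, rng, window, sfreq)
                     for r in records])
    return data, times


def generate_calibration(profile: SubjectProfile, rng: np.random.Generator,
                         mixing: Optional[np.ndarray] = None,
                         duration: float = 90.0,
                         sfreq: float = SFREQ) -> CalibrationRecording:
    """Synthesize the 90-s eye-movement calibration recording.

    Three 30-s segments: (i) eye rolling (quadrature slow sinusoids on the
    horizontal/vertical sources), (ii) alternating horizontal and vertical
    saccade-like square waves, (iii) repeated blinks (sharp positive bumps).
    EEG channels are AR(1) background plus ``mixing.T @ eog``; the mixing
    matrix is stored as ground truth.
    """
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    seg = n // 3
    horiz = np.zeros(n)
    vert = np.zeros(n)
    blink = np.zeros(n)
    # (i) rolling: circular motion of the eyes
    horiz[:seg] = np.cos(2 * np.pi * 0.4 * t[:seg])
    vert[:seg] = np.sin(2 * np.pi * 0.4 * t[:seg])
    # (ii) saccades: alternating slow square waves
    sq = signal.square(2 * np.pi * 0.5 * t[seg:2 * seg])
    horiz[seg:2 * seg] = sq * (np.arange(seg) % (2 * seg // 4) < seg // 4)
    vert[seg:2 * seg] = sq * (np.arange(seg) % (2 * seg // 4) >= seg // 4)
    # (iii) instructed repeated blinking: a bump every ~0.75 s
    for t0 in np.arange(0.75, duration / 3 - 0.3, 0.75):
        blink[2 * seg:] += np.exp(-0.5 * ((t[:n - 2 * seg] - t0) / 0.08) ** 2)
    sources = np.vstack([horiz, vert, blink])
    sources *= np.array([[100.0], [100.0], [300.0]])  # uV-scale eye activity
    if mixing is None:
        mixing = rng.uniform(0.05, 0.5, size=(3, len(EEG_CHANNELS)))
    eog = sources + background_noise((3, n), 2.0, rng)
    eeg = background_noise((len(EEG_CHANNELS), n), profile.noise_sd, rng)
    eeg = eeg + mixing.T @ eog
    return CalibrationRecording(eeg=eeg, eog=eog, mixing=np.asarray(mixing, float),
                                sfreq=sfreq)


def inject_artifacts(data: np.ndarray, fraction: float, amplitude_factor: float,
                     rng: np.random.Generator):
    """Scale a random fraction of epochs into gross amplitude outliers.

    Returns ``(contaminated_copy, ground_truth_flags)``; exactly
    ``round(fraction * n)`` epochs are marked.
    """
    if not 0 <= fraction <= 0.2:
        raise ValueError("fraction must be within [0, 0.2]")
    data = np.array(data, copy=True)
    n = data.shape[0]
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    if k:
        idx = rng.choice(n, size=k, replace=False)
        data[idx] *= amplitude_factor
        flags[idx] = True
    return data, flags
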