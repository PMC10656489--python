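"""End-to-end cohort pipeline: trajectories -> behavior -> EEG -> decoding.

``run_subject`` carries one synthetic participant through the full chain:
sample (rho, s) controller parameters, simulate the obstacle-avoiding
trajectories and their costs, draw the behavioral accept/release responses
from the subject's criterion, synthesise the EEG epochs, preprocess
(high-pass, reaction-time filter, joint-log-probability artifact rejection),
and cross-validate the ErrP decoder to obtain an out-of-fold error posterior
for every retained trial. ``run_cohort`` repeats this for a cohort of
distinct subjects, yielding the tidy per-trial table the criteria-inference
analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from . import synthetic as syn
from .decoding import DecodingResults, ErrPDecoder
from .preprocessing import (
    crop_epochs,
    highpass_filter,
    joint_log_probability,
    reaction_time_filter,
)
from .trajectory import default_workspace, simulate_costs

__all__ = ["SubjectData", "run_subject", "run_cohort", "simulate_trial_table",
           "cohort_table"]


@dataclass
class SubjectData:
    """One synthetic participant's profile, per-trial table, and decoder output."""

    subject: int
    profile: syn.SubjectProfile
    trials: pd.DataFrame
    decoding: Optional[DecodingResults] = None

    @property
    def error_rate(self) -> float:
        return float(self.trials["released"].mean())


def simulate_trial_table(n_trials: int, rng: np.random.Generator,
                         workspace=None, start_jitter_sd: float = 0.03) -> pd.DataFrame:
    """Sample (rho, s) pairs and simulate their trajectory costs.

    ``start_jitter_sd`` models trial-to-trial execution variability in where
    each reach pass begins (the arm returns near, not exactly to, its home
    pose); it decorrelates the two costs the way real kinematic variability
    does.
    """
    obstacle, nominal, start = workspace or default_workspace()
    params = syn.sample_trials(n_trials, rng)
    starts = np.tile(np.asarray(start, dtype=float), (n_trials, 1))
    if start_jitter_sd > 0:
        starts += rng.normal(0.0, start_jitter_sd, starts.shape)
    eff, comfort, min_gamma, completed = simulate_costs(
        params[:, 0], params[:, 1], nominal, obstacle, starts)
    return pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "rho": params[:, 0],
        "s": params[:, 1],
        "efficiency": eff,
        "comfort": comfort,
        "min_gamma": min_gamma,
        "completed": completed,
        "collision": comfort <= 0,
    })


def run_subject(subject_id: int, profile: syn.SubjectProfile, n_trials: int = 400,
                target_rate: float = 0.27, *, trials: Optional[pd.DataFrame] = None,
                template: Optional[syn.ErrPTemplate] = None,
                decode: bool = True, n_folds: int = 10,
                trial_length: float = 5.0, workspace=None) -> SubjectData:
    """Full single-subject pipeline; deterministic under ``profile.seed``.

    The subject's bias is calibrated on their own simulated cost ensemble so
    that the expected rejection rate matches ``target_rate``. The returned
    table holds, per trial, the controller parameters, costs, behavioral
    response, retention flags, and (if ``decode``) the out-of-fold ErrP
    posterior and its binary label.
    """
    rng = np.random.default_rng(profile.seed)
    template = template or syn.ErrPTemplate()
    if trials is None:
        trials = simulate_trial_table(n_trials, rng, workspace)
    trials = trials.copy()
    profile = syn.calibrate_bias(profile, trials["efficiency"], trials["comfort"],
                                 target_rate)
    records = [
        syn.behavioral_response(profile, (e, c), rng, trial_id=i, rho=r, s=s)
        for i, (e, c, r, s) in enumerate(zip(trials["efficiency"], trials["comfort"],
                                             trials["rho"], trials["s"]))
    ]
    if not any(t.released for t in records):  # degenerate draw; force one error
        raise RuntimeError("cohort must contain at least one erroneous trial")
    trials["released"] = [t.released for t in records]
    trials["release_time"] = [t.release_time if t.released else np.nan
                              for t in records]
    keep_rt = reaction_time_filter(records, trial_length)

    data, times = syn.generate_epochs(profile, records, template, rng,
                                      window=(-0.5, 1.0))
    data = highpass_filter(data)
    data, times = crop_epochs(data, times, (-0.2, 0.6))
    _, artifact_flags = joint_log_probability(data)
    retained = keep_rt & ~artifact_flags
    trials["rt_removed"] = ~keep_rt
    trials["artifact"] = artifact_flags
    trials["retained"] = retained

    decoding = None
    trials["errp_posterior"] = np.nan
    trials["errp_label"] = pd.array([pd.NA] * len(trials), dtype="boolean")
    if decode:
        labels = trials["released"].to_numpy()[retained]
        dec = ErrPDecoder(data[retained], labels, times)
        decoding = dec.fit(n_folds=n_folds, random_state=profile.seed % (2 ** 31))
        trials.loc[retained, "errp_posterior"] = decoding.posteriors
        trials.loc[retained, "errp_label"] = decoding.predictions
    return SubjectData(subject=subject_id, profile=profile, trials=trials,
                       decoding=decoding)


def run_cohort(n_subjects: int = 17, n_trials: int = 400, seed: int = 0, *,
               errp_gain: float = 5.5, noise_sd: float = 8.0,
               decision_temperature: float = 0.5, decode: bool = True,
               workspace=None) -> List[SubjectData]:
    """Simulate and analyse a cohort of subjects with distinct criteria."""
    profiles, rates = syn.generate_cohort_profiles(
        n_subjects, seed, errp_gain=errp_gain, noise_sd=noise_sd,
        decision_temperature=decision_temperature)
    out = []
    for i, (profile, rate) in enumerate(zip(profiles, rates)):
        out.append(run_subject(i, profile, n_trials, target_rate=rate,
                               decode=decode, workspace=workspace))
    return out


def cohort_table(subjects: List[SubjectData], retained_only: bool = True) -> pd.DataFrame:
    """Stack per-subject trial tables into one tidy DataFrame."""
    frames = []
    for s in subjects:
        t = s.trials.copy()
        t.insert(0, "subject", s.subject)
        if retained_only:
            t = t[t["retained"]]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
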