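"""Particle-filtered latent beliefs conditioned on an observed response
sequence.

The observer's inference noise makes its belief trajectory latent even when
the stimuli are known.  A sequential importance resampling (SIR) filter
propagates particles through the noisy-inference dynamics and weights them
by the probability of the observed choice (optionally also the observed
confidence) on each trial, extracting belief trajectories consistent with
the response sequence.  Two per-trial summaries are reported:

* ``prior_belief`` — the absolute pre-sequence belief |L_prior| (after
  hazard propagation), a measure of how committed the observer is before
  seeing the trial's stimuli;
* ``evidence_direction`` — the trial's noiseless evidence sum signed by the
  prior's direction: positive when evidence agrees with the prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .observer import ModelParams, _per_trial_params, propagate_prior
from .task import C_MINUS, C_PLUS, Session


@dataclass
class ParticleSet:
    """Per-trial filter bookkeeping."""

    ess: np.ndarray               # effective sample size per trial
    resampled: np.ndarray         # bool per trial
    rejuvenated: np.ndarray       # bool per trial (weight collapse handled)
    n_particles: int


@dataclass
class LatentTrajectory:
    prior_belief: np.ndarray       # weighted posterior mean of |L_prior|
    evidence_direction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.prior_belief)),
                "prior_belief": self.prior_belief,
                "evidence_direction": self.evidence_direction,
            }
        )


def _systematic_resample(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(w)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions)


def particle_filter(
    session: Session,
    responses: pd.DataFrame,
    params: ModelParams | dict[str, ModelParams],
    n_particles: int = 1000,
    rng: np.random.Generator | None = None,
    condition_on: str = "choice_confidence",
    resample_threshold: float = 0.5,
    resampling: str = "systematic",
) -> tuple[ParticleSet, LatentTrajectory]:
    """SIR filter over the noisy-inference latent path.

    Per trial the particle belief is hazard-propagated, a noisy evidence
    sum is sampled, and importance weights are multiplied by the
    likelihood of the observed choice (an indicator, since choices are a
    deterministic sign readout) and, with
    ``condition_on='choice_confidence'``, the Gaussian probability of the
    observed confidence report.  Systematic (or stratified) resampling is
    triggered when the effective sample size falls below
    ``resample_threshold * n_particles``.  If every particle is
    inconsistent with the observed response the weights are rejuvenated to
    uniform with a warning.

    Summaries use the weights *after* the trial's observation update.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if condition_on not in ("choice", "choice_confidence"):
        raise ValueError("condition_on must be 'choice' or 'choice_confidence'")
    h, si, thr, sm, gain = _per_trial_params(session, params)
    n = session.n_trials
    base = session.base_llr
    seq_len = session.seq_len
    block_start = session.block_start
    choice = responses["choice"].to_numpy()
    conf = responses["confidence"].to_numpy()
    sw = responses["is_switch"].to_numpy().astype(float)

    L = np.zeros(n_particles)
    w = np.full(n_particles, 1.0 / n_particles)
    ess = np.empty(n)
    resampled = np.zeros(n, dtype=bool)
    rejuvenated = np.zeros(n, dtype=bool)
    prior_belief = np.empty(n)
    evidence_direction = np.empty(n)

    for t in range(n):
        if block_start[t]:
            L = np.zeros(n_particles)
            w = np.full(n_particles, 1.0 / n_particles)
        else:
            L = propagate_prior(L, float(h[t]))
        L_pre = L
        noise = np.sqrt(seq_len[t]) * si[t] * rng.standard_normal(n_particles)
        L_post = L_pre + base[t] + noise

        # observation likelihood
        c = choice[t]
        sign_match = np.sign(L_post) == c
        tie = L_post == 0.0
        lik = sign_match.astype(float) + 0.5 * tie
        if condition_on == "choice_confidence":
            g = gain[t] if sw[t] == 1 else 1.0
            readout_mean = np.abs(L_post) * g
            if sm[t] > 0:
                p_high = sps.norm.sf(thr[t], loc=readout_mean, scale=sm[t])
            else:
                p_high = (readout_mean > thr[t]).astype(float)
            lik = lik * np.where(conf[t] == 1, p_high, 1.0 - p_high)

        w_new = w * lik
        total = w_new.sum()
        if total <= 0.0 or not np.isfinite(total):
            warnings.warn(
                f"particle weight collapse at trial {t}; rejuvenating to uniform"
            )
            rejuvenated[t] = True
            w_new = np.full(n_particles, 1.0 / n_particles)
        else:
            w_new = w_new / total
        w = w_new
        ess[t] = 1.0 / np.sum(w**2)
        prior_belief[t] = float(np.sum(w * np.abs(L_pre)))
        sign_pre = np.sign(L_pre)
        evidence_direction[t] = float(np.sum(w * base[t] * sign_pre))
        L = L_post
        if ess[t] < resample_threshold * n_particles:
            if resampling == "systematic":
                idx = _systematic_resample(w, rng)
            elif resampling == "stratified":
                positions = (rng.random(n_particles) + np.arange(n_particles)) / n_particles
                idx = np.searchsorted(np.cumsum(w), positions)
            else:
                raise ValueError("resampling must be 'systematic' or 'stratified'")
            L = L[idx]
            w = np.full(n_particles, 1.0 / n_particles)
            resampled[t] = True

    particles = ParticleSet(
        ess=ess, resampled=resampled, rejuvenated=rejuvenated, n_particles=n_particles
    )
    return particles, LatentTrajectory(prior_belief, evidence_direction)


def summarize_latents(
    latents: LatentTrajectory, responses: pd.DataFrame
) -> pd.DataFrame:
    """Cell means of the latent summaries by response type x condition.

    Returns a tidy frame (condition, response_type, prior_belief,
    evidence_direction, n); cells without trials carry NaN means.  Feeds
    the 2x2 repeated-measures ANOVA across participants.
    """
    if len(responses) != len(latents.prior_belief):
        raise ValueError("latents and responses are not aligned")
    sw = responses["is_switch"].to_numpy().astype(float)
    cond = responses["condition"].to_numpy()
    rows = []
    for c in (C_MINUS, C_PLUS):
        for label, mask_sw in (("repeat", sw == 0), ("switch", sw == 1)):
            m = (cond == c) & mask_sw
            rows.append(
                {
                    "condition": c,
                    "response_type": label,
                    "prior_belief": float(np.mean(latents.prior_belief[m])) if m.any() else np.nan,
                    "evidence_direction": float(np.mean(latents.evidence_direction[m])) if m.any() else np.nan,
                    "n": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


def write_latents(latents: LatentTrajectory, path) -> None:
    latents.to_frame().to_csv(path, index=False)
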