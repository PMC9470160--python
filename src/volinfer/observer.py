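"""Normative Bayesian observer with confidence for volatile reversal tasks.

The observer tracks the log-odds L of the hidden state.  Between trials the
belief is discounted toward zero by a hazard-rate propagation (the standard
normative recursion for a symmetric two-state world that reverses with
probability h per trial); within a trial the per-stimulus log-likelihood
ratios are accumulated, each corrupted by i.i.d. Gaussian inference noise so
that total noise variance scales with sequence length.  The choice is the
sign of the posterior log-odds (no selection noise); confidence is a binary
high/low report obtained by thresholding a noisy readout of the absolute
posterior, with a multiplicative gain applied on change-of-mind (switch)
trials only.

Five parameters: hazard rate h, inference noise sigma_inf, confidence
threshold, metacognitive noise sigma_meta, and switch confidence gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .task import C_MINUS, C_PLUS, Session, TaskConfig

#: Fitting bounds for the five model parameters.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "hazard": (1e-6, 1.0 - 1e-6),
    "sigma_inf": (0.0, 10.0),
    "conf_threshold": (-10.0, 10.0),
    "sigma_meta": (0.0, 10.0),
    "conf_gain": (0.0, 10.0),
}

PARAM_NAMES = tuple(PARAM_BOUNDS)


@dataclass(frozen=True)
class ModelParams:
    """The five observer parameters; defaults are the bound midpoints."""

    hazard: float = 0.5
    sigma_inf: float = 5.0
    conf_threshold: float = 0.0
    sigma_meta: float = 5.0
    conf_gain: float = 5.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ModelParams":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in x))))

    def to_json(self, path: str | Path) -> None:
        d = {"schema": "volinfer.ModelParams/1", **{n: getattr(self, n) for n in PARAM_NAMES}}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        d = json.loads(Path(path).read_text())
        d.pop("schema", None)
        return cls(**d)


@dataclass
class BeliefTrace:
    """Per-trial belief variables of one simulated agent."""

    L_prior: np.ndarray      # log-odds entering the trial (post-propagation)
    llr_samples: list[np.ndarray]  # per-stimulus LLRs incl. inference noise
    L_post: np.ndarray       # log-odds after the sequence


def stimulus_llr(theta, cfg: TaskConfig):
    """Log-likelihood ratio of orientation(s) under the two categories.

    Densities are axial von Mises on the doubled angle 2*theta; with the
    category means spaced pi/2 on the half-circle this reduces to
    2*kappa*cos(2*(theta - mu_plus)).  Antisymmetric under category swap.
    """
    theta = np.asarray(theta, dtype=float)
    mu = cfg.mu
    return cfg.kappa * (
        np.cos(2.0 * theta - 2.0 * mu[+1]) - np.cos(2.0 * theta - 2.0 * mu[-1])
    )


def propagate_prior(L, h: float):
    """Hazard-rate discounting of a log-odds belief between trials.

    phi(L) = L + log((1-h)/h + exp(-L)) - log((1-h)/h + exp(L)).  Odd in L,
    strictly increasing for h < 1/2, and bounded by log((1-h)/h); computed
    in the log domain so it is stable for large |L|.
    """
    if not (0.0 < h < 1.0):
        raise ValueError(f"hazard must lie strictly inside (0, 1), got {h}")
    L = np.asarray(L, dtype=float)
    a = np.log((1.0 - h) / h)
    return L + np.logaddexp(a, -L) - np.logaddexp(a, L)


def accumulate_sequence(
    L_prior,
    llrs,
    sigma_inf: float,
    rng: np.random.Generator | None = None,
):
    """Accumulate a sequence of stimulus LLRs onto a (propagated) prior.

    Each sample is corrupted by independent N(0, sigma_inf^2) inference
    noise, so accumulated noise variance equals seq_len * sigma_inf^2.
    Hazard propagation is applied separately (see :func:`propagate_prior`);
    the prior passed here is the belief entering the sequence.
    """
    if sigma_inf < 0:
        raise ValueError("sigma_inf must be >= 0")
    llrs = np.asarray(llrs, dtype=float)
    if sigma_inf > 0:
        if rng is None:
            raise ValueError("rng required when sigma_inf > 0")
        llrs = llrs + rng.normal(0.0, sigma_inf, size=llrs.shape)
    return L_prior + llrs.sum(axis=-1), llrs


def decide(L_post: float, prev_choice: int | None = None,
           rng: np.random.Generator | None = None) -> int:
    """Deterministic choice: sign of the posterior log-odds.

    Exact ties are broken toward repeating the previous choice; a tie with
    no previous choice (block start) is resolved at random.
    """
    if L_post > 0:
        return 1
    if L_post < 0:
        return -1
    if prev_choice is not None:
        return int(prev_choice)
    if rng is None:
        raise ValueError("tie with no previous choice requires an rng")
    return 1 if rng.random() < 0.5 else -1


def rate_confidence(
    L_post,
    is_switch,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    noise_stage: str = "post_abs",
):
    """Binary high/low confidence from a noisy readout of the belief.

    readout = |L_post| * (conf_gain on switch trials) + eta,
    eta ~ N(0, sigma_meta^2); the report is high iff readout exceeds the
    confidence threshold.  ``noise_stage='pre_abs'`` instead corrupts the
    signed belief before the absolute value is taken (alternative readout
    convention; the default applies noise after rectification).
    """
    L_post = np.asarray(L_post, dtype=float)
    is_switch = np.asarray(is_switch, dtype=bool)
    gain = np.where(is_switch, params.conf_gain, 1.0)
    if params.sigma_meta > 0:
        if rng is None:
            raise ValueError("rng required when sigma_meta > 0")
        eta = rng.normal(0.0, params.sigma_meta, size=np.broadcast(L_post, gain).shape)
    else:
        eta = 0.0
    if noise_stage == "pre_abs":
        readout = np.abs(L_post + eta) * gain
    else:
        readout = np.abs(L_post) * gain + eta
    return readout > params.conf_threshold


# ---------------------------------------------------------------------------
# Vectorized closed-loop simulation core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate_core(block_start, base, seq_len, h, si, thr, sm, gain, z, eta, u):
    """Simulate n_sims independent agents over one session.

    All stochastic inputs (z: inference noise, eta: metacognitive noise,
    u: tie-break uniforms) are standard draws supplied by the caller, so a
    fixed noise bundle yields a deterministic map from parameters to
    behavior (common random numbers across parameter evaluations).
    """
    n_trials, n_sims = z.shape
    choice = np.zeros((n_trials, n_sims), dtype=np.int8)
    conf = np.zeros((n_trials, n_sims), dtype=np.int8)
    switch = np.full((n_trials, n_sims), -1, dtype=np.int8)
    L_pre = np.zeros((n_trials, n_sims))
    L_post = np.zeros((n_trials, n_sims))
    # per-trial constants: evidence-noise scale and hazard odds ratio
    sn = np.empty(n_trials)
    r = np.empty(n_trials)
    for t in range(n_trials):
        sn[t] = np.sqrt(seq_len[t]) * si[t]
        r[t] = (1.0 - h[t]) / h[t]
    for j in range(n_sims):
        L = 0.0
        prev = 0
        for t in range(n_trials):
            if block_start[t]:
                L = 0.0
                prev = 0
            else:
                # phi(L) = sign(L) * [log(r + e^{-|L|}) - log1p(r e^{-|L|})]
                aL = np.abs(L)
                e = np.exp(-aL)
                mag = np.log(r[t] + e) - np.log1p(r[t] * e)
                L = mag if L > 0.0 else (-mag if L < 0.0 else 0.0)
            L_pre[t, j] = L
            Lp = L + base[t] + sn[t] * z[t, j]
            if Lp > 0.0:
                c = 1
            elif Lp < 0.0:
                c = -1
            elif prev != 0:
                c = prev
            else:
                c = 1 if u[t, j] < 0.5 else -1
            if prev == 0:
                sw = -1
            elif c != prev:
                sw = 1
            else:
                sw = 0
            g = gain[t] if sw == 1 else 1.0
            conf[t, j] = 1 if np.abs(Lp) * g + sm[t] * eta[t, j] > thr[t] else 0
            choice[t, j] = c
            switch[t, j] = sw
            L_post[t, j] = Lp
            L = Lp
            prev = c
    return choice, conf, switch, L_pre, L_post


def draw_noise_bundle(
    n_trials: int, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard-normal/uniform draws consumed by :func:`_simulate_core`."""
    z = rng.standard_normal((n_trials, n_sims))
    eta = rng.standard_normal((n_trials, n_sims))
    u = rng.random((n_trials, n_sims))
    return z, eta, u


def _per_trial_params(
    session: Session, params: ModelParams | dict[str, ModelParams]
) -> tuple[np.ndarray, ...]:
    """Expand (possibly per-condition) parameters to per-trial arrays."""
    cond = session.condition
    if isinstance(params, ModelParams):
        p = {C_MINUS: params, C_PLUS: params}
    else:
        p = params
    out = []
    for name in PARAM_NAMES:
        vals = np.where(
            cond == 0, getattr(p[C_MINUS], name), getattr(p[C_PLUS], name)
        ).astype(float)
        out.append(vals)
    return tuple(out)


def simulate_cohort_matrix(
    session: Session,
    params: ModelParams | dict[str, ModelParams],
    noise: tuple[np.ndarray, np.ndarray, np.ndarray],
):
    """Low-level entry: simulate many agents on one session.

    Returns (choice, conf, switch, L_pre, L_post) matrices of shape
    (n_trials, n_sims); ``switch`` is -1 on block-start trials (undefined),
    else 0/1.
    """
    h, si, thr, sm, gain = _per_trial_params(session, params)
    z, eta, u = noise
    return _simulate_core(
        np.ascontiguousarray(session.block_start),
        np.ascontiguousarray(session.base_llr),
        np.ascontiguousarray(session.seq_len),
        h, si, thr, sm, gain, z, eta, u,
    )


def responses_frame(session: Session, choice, conf, switch) -> pd.DataFrame:
    """Tidy per-trial response records for a single simulated agent."""
    choice = np.asarray(choice).ravel()
    conf = np.asarray(conf).ravel()
    switch = np.asarray(switch).ravel().astype(float)
    switch[switch < 0] = np.nan
    n = len(choice)
    block = session.block
    confirmed = np.full(n, np.nan)
    for t in range(n - 1):
        if switch[t] == 1 and block[t + 1] == block[t]:
            confirmed[t] = 1.0 if choice[t + 1] == choice[t] else 0.0
    df = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": block,
            "condition": np.where(session.condition == 0, C_MINUS, C_PLUS),
            "choice": choice.astype(int),
            "confidence": conf.astype(int),
            "is_switch": switch,
            "is_confirmed": confirmed,
            "correct": (choice == session.s).astype(int),
        }
    )
    return df


def simulate_agent(
    session: Session,
    params: ModelParams | dict[str, ModelParams],
    rng: np.random.Generator,
) -> tuple[BeliefTrace, pd.DataFrame]:
    """Simulate one agent closed-loop over a session.

    In C+ blocks the agent's own actions drive the realized categories;
    because evidence is recoded against the previous action, the belief
    dynamics over the hidden state are shared across conditions and the
    realized categories can be recovered afterwards from the choices.
    Deterministic given the rng state.
    """
    if session.n_trials == 0:
        return (
            BeliefTrace(np.empty(0), [], np.empty(0)),
            responses_frame(session, np.empty(0, int), np.empty(0, int), np.empty(0, int)),
        )
    noise = draw_noise_bundle(session.n_trials, 1, rng)
    choice, conf, switch, L_pre, L_post = simulate_cohort_matrix(session, params, noise)
    h, si, thr, sm, gain = _per_trial_params(session, params)
    llr_samples = []
    for t, trial in enumerate(session.trials):
        base_i = trial.hidden_state * 2.0 * session.config.kappa * np.cos(trial.deviations)
        # the aggregated trial noise redistributed evenly is equivalent in sum
        noise_total = np.sqrt(trial.seq_len) * si[t] * noise[0][t, 0]
        llr_samples.append(base_i + noise_total / trial.seq_len)
    trace = BeliefTrace(L_pre[:, 0].copy(), llr_samples, L_post[:, 0].copy())
    return trace, responses_frame(session, choice[:, 0], conf[:, 0], switch[:, 0])


def realize_closed_loop(session: Session, responses: pd.DataFrame) -> None:
    """Fill C+ trials' generated categories/orientations from an agent's
    (or participant's) choice stream, in place."""
    from .task import realize_orientations, realize_trial_category

    prev_by_block: dict[int, int] = {}
    choices = responses["choice"].to_numpy()
    for t, trial in enumerate(session.trials):
        if trial.condition == C_PLUS:
            # the action driving trial t is the previous trial's choice in
            # the same block; the block-initial probe uses the first choice
            prev = prev_by_block.get(trial.block, int(choices[t]))
            cat = realize_trial_category(trial.hidden_state, C_PLUS, prev)
            trial.gen_category = cat
            trial.orientations = realize_orientations(cat, trial.deviations, session.config)
        prev_by_block[trial.block] = int(choices[t])


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
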