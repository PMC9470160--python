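"""Reversal- and repetition-aligned psychometric curves and their fits.

Four curve families characterize behavior around hidden-state reversals and
as a function of decision evidence:

* choice reversal curve — fraction of responses matching the post-reversal
  hidden state, by trial position relative to the reversal; fitted with a
  saturating-exponential recovery (asymptote, reversal time constant);
* confidence reversal curve — fraction of high-confidence reports by
  position; fitted with an exponential learning curve (pmin, pmax, time
  constant) from which a "confidence drop" statistic is derived;
* repetition curve — probability of repeating the previous choice as a
  function of evidence signed in favor of repetition; fitted with a
  logistic whose x-intercept at p=0.5 is the choice point of subjective
  equivalence (choice-PSE) and whose slope is evidence sensitivity;
* confidence-by-evidence curves — one logistic per response type (repeat /
  switch); the evidence level where the two fitted curves cross is the
  confidence-PSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .task import C_MINUS, Session


class EmptyCurveError(ValueError):
    """No reversals (or no usable events) in the data."""


@dataclass
class CurveSet:
    """Binned event counts along a reversal or evidence axis."""

    axis: str  # "trials-from-reversal" | "signed-evidence-bin"
    bin_centers: np.ndarray
    n_total: np.ndarray
    n_event: np.ndarray
    condition: str | None = None
    bin_edges: np.ndarray | None = None

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_event / self.n_total, np.nan)


@dataclass
class PsychFit:
    model: str
    params: dict[str, float]
    loss: float = np.nan
    converged: bool = False
    degenerate: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: (None if v is None or not np.isfinite(v) else float(v))
                       for k, v in self.params.items()},
            "loss": None if not np.isfinite(self.loss) else float(self.loss),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# Reversal alignment
# ---------------------------------------------------------------------------

def reversal_alignment(
    session: Session, window: tuple[int, int] = (-4, 8)
) -> pd.DataFrame:
    """Map trials to positions relative to each within-block reversal.

    Position k >= 1 is the k-th trial of the new episode; k <= -1 counts
    back into the previous episode.  Positions that would cross a block
    boundary or overlap beyond the neighboring episode's extent are
    excluded; ``target`` is the post-reversal hidden state.  A trial may
    align to several reversals (short episodes), producing several rows.
    """
    lo, hi = window
    if lo > -1 or hi < 4:
        raise ValueError("window must span at least 1 pre and 4 post trials")
    block = session.block
    ep = session.episode_id
    s = session.s
    n = session.n_trials
    rows = []
    for t in range(1, n):
        if block[t] != block[t - 1] or ep[t] == ep[t - 1]:
            continue
        # reversal at t: first trial of a new episode
        for k in range(lo, 0):
            u = t + k
            if u < 0 or block[u] != block[t] or ep[u] != ep[t - 1]:
                continue
            rows.append((u, k, int(s[t])))
        for k in range(1, hi + 1):
            u = t + k - 1
            if u >= n or block[u] != block[t] or ep[u] != ep[t]:
                continue
            rows.append((u, k, int(s[t])))
    if not rows:
        raise EmptyCurveError("no reversals found in session")
    return pd.DataFrame(rows, columns=["trial", "position", "target"])


def build_reversal_curve(
    responses: pd.DataFrame,
    session: Session,
    window: tuple[int, int] = (-4, 8),
    event: str = "correct",
    condition: str | None = None,
) -> CurveSet:
    """Fraction of post-reversal-state reports (or high confidence) by
    position relative to reversal, pooled over reversals."""
    align = reversal_alignment(session, window)
    if condition is not None:
        cond_code = 0 if condition == C_MINUS else 1
        align = align[session.condition[align["trial"].to_numpy()] == cond_code]
        if align.empty:
            raise EmptyCurveError(f"no reversals in condition {condition}")
    t_idx = align["trial"].to_numpy()
    if event == "correct":
        ev = responses["choice"].to_numpy()[t_idx] == align["target"].to_numpy()
    elif event == "high_conf":
        ev = responses["confidence"].to_numpy()[t_idx] == 1
    else:
        raise ValueError("event must be 'correct' or 'high_conf'")
    positions = np.arange(window[0], window[1] + 1)
    positions = positions[positions != 0]
    pos = align["position"].to_numpy()
    n_total = np.array([(pos == k).sum() for k in positions])
    n_event = np.array([int(ev[pos == k].sum()) for k in positions])
    return CurveSet(
        axis="trials-from-reversal",
        bin_centers=positions.astype(float),
        n_total=n_total,
        n_event=n_event,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Bounded multi-start least squares on binned fractions
# ---------------------------------------------------------------------------

def _logit(p, lo, hi):
    p = np.clip((np.asarray(p, float) - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-np.clip(np.asarray(x, float), -700, 700)))


def _amplitude_floor(curve: CurveSet, mask) -> float:
    """Smallest curve amplitude distinguishable from binomial bin noise
    (four standard errors of a bin fraction at the mean bin count)."""
    n = curve.n_total[mask & (curve.n_total > 0)]
    return 4.0 * np.sqrt(0.25 / max(float(n.mean()), 1.0))


def _multistart_minimize(loss, bounds, rng, n_starts=5, x0=None):
    """Nelder-Mead in a logit-transformed box; best of n_starts starts."""
    los = np.array([b[0] for b in bounds])
    his = np.array([b[1] for b in bounds])

    def wrapped(z):
        return loss(_expit(z, los, his))

    best = None
    starts = []
    if x0 is not None:
        starts.append(_logit(np.asarray(x0, float), los, his))
    while len(starts) < n_starts:
        starts.append(rng.normal(0.0, 1.5, size=len(bounds)))
    for z0 in starts:
        res = optimize.minimize(
            wrapped, z0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxfev": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = _expit(best.x, los, his)
    return x, float(best.fun), bool(best.success)


def _binomial_weighted_sse(curve: CurveSet, predict, mask=None):
    k = curve.bin_centers
    n = curve.n_total.astype(float)
    f = curve.fraction
    use = (n > 0) if mask is None else mask & (n > 0)

    def loss(x):
        p = predict(x, k[use])
        return float(np.sum(n[use] * (f[use] - p) ** 2))

    return loss


def fit_reversal_exponential(
    curve: CurveSet, rng: np.random.Generator | None = None
) -> PsychFit:
    """Saturating-exponential recovery of the post-reversal choice curve.

    p(k) = asym - (2*asym - 1) * exp(-k / tau) on post-reversal positions
    k >= 1: starts at the pre-reversal mirror level (1 - asym) at k=0 and
    recovers toward the asymptote with time constant tau (trials).
    Binomial-weighted least squares, 5-start bounded Nelder-Mead.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    post = curve.bin_centers >= 1
    if int((curve.n_total[post] > 0).sum()) < 4:
        raise EmptyCurveError("need at least 4 post-reversal bins")
    tau_lo, tau_hi = 1e-3, 100.0

    def predict(x, k):
        asym, tau = x
        return asym - (2 * asym - 1) * np.exp(-k / tau)

    loss = _binomial_weighted_sse(curve, predict, mask=post)
    x, fval, ok = _multistart_minimize(
        loss, [(0.0, 1.0), (tau_lo, tau_hi)], rng, x0=[0.8, 2.0]
    )
    asym, tau = x
    # tau is unidentifiable when the fitted modulation is within bin noise
    # (flat curve) or sits at a bound (step-like curve)
    degenerate = (
        abs(2 * asym - 1) < _amplitude_floor(curve, post)
        or tau <= tau_lo * 1.5
        or tau >= tau_hi * 0.95
    )
    return PsychFit(
        model="trunc-exponential",
        params={"asymptote": asym, "tau": tau},
        loss=fval,
        converged=ok,
        degenerate=degenerate,
        message="tau unidentifiable or at bound" if degenerate else "",
    )


def confidence_drop(
    pmin: float, pmax: float, tau: float, reading: str = "at-first-trial"
) -> float:
    """Confidence-drop statistic of the exponential learning curve.

    Default reading: the gap between the upper asymptote and the curve's
    value one trial after the reversal,
    drop = pmax - [pmin + (pmax - pmin) * (1 - e^{-1/tau})]
         = (pmax - pmin) * e^{-1/tau}.
    ``reading='literal'`` applies the alternative left-to-right
    parenthesization (pmax - pmin) + (pmax - pmin) * (1 - e^{-1/tau}) of
    the same printed expression.
    """
    if reading == "at-first-trial":
        return (pmax - pmin) * np.exp(-1.0 / tau)
    if reading == "literal":
        return (pmax - pmin) + (pmax - pmin) * (1.0 - np.exp(-1.0 / tau))
    raise ValueError("reading must be 'at-first-trial' or 'literal'")


def fit_confidence_reversal(
    curve: CurveSet,
    rng: np.random.Generator | None = None,
    drop_reading: str = "at-first-trial",
) -> PsychFit:
    """Exponential learning fit of post-reversal confidence,
    p(k) = pmin + (pmax - pmin) * (1 - e^{-k/tau}), plus the drop statistic."""
    rng = rng if rng is not None else np.random.default_rng(0)
    post = curve.bin_centers >= 1
    if int((curve.n_total[post] > 0).sum()) < 4:
        raise EmptyCurveError("need at least 4 post-reversal bins")
    tau_lo, tau_hi = 1e-3, 100.0

    def predict(x, k):
        pmin, pmax, tau = x
        return pmin + (pmax - pmin) * (1.0 - np.exp(-k / tau))

    loss = _binomial_weighted_sse(curve, predict, mask=post)
    x, fval, ok = _multistart_minimize(
        loss, [(0.0, 1.0), (0.0, 1.0), (tau_lo, tau_hi)], rng, x0=[0.4, 0.8, 2.0]
    )
    pmin, pmax, tau = x
    degenerate = (
        abs(pmax - pmin) < _amplitude_floor(curve, post)
        or tau <= tau_lo * 1.5
        or tau >= tau_hi * 0.95
    )
    drop = np.nan if degenerate else confidence_drop(pmin, pmax, tau, drop_reading)
    return PsychFit(
        model="exp-learning",
        params={"pmin": pmin, "pmax": pmax, "tau_conf": tau, "drop": drop},
        loss=fval,
        converged=ok,
        degenerate=degenerate,
        message="drop undefined for degenerate fit" if degenerate else "",
    )


# ---------------------------------------------------------------------------
# Evidence-aligned (repetition) analyses
# ---------------------------------------------------------------------------

def signed_evidence_series(session: Session, responses: pd.DataFrame) -> np.ndarray:
    """Per-trial decision evidence signed in favor of repeating the
    previous choice (noiseless LLR sum); NaN on block-start trials."""
    base = session.base_llr
    choice = responses["choice"].to_numpy().astype(float)
    ev = np.full(session.n_trials, np.nan)
    ev[1:] = choice[:-1] * base[1:]
    ev[session.block_start] = np.nan
    return ev


def repeat_flags(responses: pd.DataFrame) -> np.ndarray:
    """1 = repeat, 0 = switch, NaN at block starts."""
    sw = responses["is_switch"].to_numpy().astype(float)
    return np.where(np.isnan(sw), np.nan, 1.0 - sw)


def equal_count_bins(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-count bin edges over finite values (for display curves)."""
    x = x[np.isfinite(x)]
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(x, qs)
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def build_repetition_curve(
    evidence: np.ndarray,
    event: np.ndarray,
    n_bins: int = 8,
    edges: np.ndarray | None = None,
    condition: str | None = None,
) -> CurveSet:
    """Binned fraction of events (repeats or high confidence) by signed
    evidence; equal-count bins by default."""
    ok = np.isfinite(evidence) & np.isfinite(event)
    ev, y = evidence[ok], event[ok].astype(float)
    if edges is None:
        edges = equal_count_bins(ev, n_bins)
    idx = np.clip(np.searchsorted(edges, ev, side="right") - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    n_total = np.bincount(idx, minlength=nb)
    n_event = np.bincount(idx, weights=y, minlength=nb).astype(int)
    centers = np.array([
        np.median(ev[idx == b]) if (idx == b).any() else np.nan for b in range(nb)
    ])
    return CurveSet(
        axis="signed-evidence-bin",
        bin_centers=centers,
        n_total=n_total,
        n_event=n_event,
        condition=condition,
        bin_edges=edges,
    )


def _ml_logistic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, str]:
    """ML logistic fit of y on [1, x]; falls back to a Gaussian-prior MAP
    fit (prior SD 2) under separation/divergence, with a warning."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        beta = np.asarray(res.params)
        if np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < 50:
            return beta, False, ""
    except Exception:  # noqa: BLE001 - any statsmodels failure falls back
        pass
    from .stats import map_logistic_regression

    warnings.warn("separation detected; ridge-stabilized (MAP) logistic fit used")
    beta = map_logistic_regression(X, y, prior_sd=2.0).coefficients
    return beta, True, "ridge-stabilized (separation)"


def fit_repetition_logistic(
    evidence: np.ndarray, repeats: np.ndarray
) -> PsychFit:
    """Trial-level ML logistic of P(repeat | signed evidence).

    choice_PSE is the evidence level at which repeating and switching are
    equally likely (-intercept/slope); slope is evidence sensitivity.
    """
    ok = np.isfinite(evidence) & np.isfinite(repeats)
    x, y = evidence[ok], repeats[ok].astype(float)
    if len(np.unique(y)) < 2:
        return PsychFit(
            model="logistic",
            params={"choice_PSE": np.nan, "slope": np.nan},
            degenerate=True,
            message="single-class data",
        )
    beta, stabilized, msg = _ml_logistic(x, y)
    b0, b1 = beta
    pse = -b0 / b1 if b1 != 0 else np.nan
    pad = 0.25 * (x.max() - x.min())
    degenerate = not np.isfinite(pse) or not (x.min() - pad <= pse <= x.max() + pad)
    eta = np.clip(b0 + b1 * x, -30, 30)
    nll = float(np.sum(np.log1p(np.exp(eta)) - y * eta))
    return PsychFit(
        model="logistic",
        params={"choice_PSE": pse, "slope": b1, "intercept": b0},
        loss=nll,
        converged=True,
        degenerate=degenerate,
        message=msg or ("PSE outside padded evidence range" if degenerate else ""),
    )


def fit_confidence_dual_sigmoid(
    evidence: np.ndarray, confidence: np.ndarray, repeats: np.ndarray
) -> PsychFit:
    """Separate confidence-by-evidence logistics for repeat and switch
    trials; confidence_PSE is the evidence where the two curves cross."""
    ok = np.isfinite(evidence) & np.isfinite(confidence) & np.isfinite(repeats)
    x, c, r = evidence[ok], confidence[ok].astype(float), repeats[ok].astype(bool)
    if (np.unique(x[r]).size < 2) or (np.unique(x[~r]).size < 2):
        return PsychFit(
            model="dual-logistic",
            params={"confidence_PSE": np.nan},
            degenerate=True,
            message="a response class lacks evidence spread",
        )
    beta_rep, _, m1 = _ml_logistic(x[r], c[r])
    beta_sw, _, m2 = _ml_logistic(x[~r], c[~r])

    def diff(e):
        return (beta_rep[0] + beta_rep[1] * e) - (beta_sw[0] + beta_sw[1] * e)

    lo, hi = x.min(), x.max()
    pad = 0.25 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    d = diff(grid)
    pse = np.nan
    sign_change = np.where(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
    if len(sign_change):
        i = sign_change[0]
        pse = float(optimize.brentq(diff, grid[i], grid[i + 1]))
    params = {
        "confidence_PSE": pse,
        "offset_repeat": beta_rep[0],
        "slope_repeat": beta_rep[1],
        "offset_switch": beta_sw[0],
        "slope_switch": beta_sw[1],
    }
    degenerate = not np.isfinite(pse)
    return PsychFit(
        model="dual-logistic",
        params=params,
        converged=True,
        degenerate=degenerate,
        message="; ".join(filter(None, [m1, m2]))
        or ("curves do not intersect in padded range" if degenerate else ""),
    )


def conditioned_pse(
    session: Session,
    responses: pd.DataFrame,
    condition_on: str,
) -> PsychFit:
    """Choice-PSE refitted on a subsample conditioned on the previous
    trial's response properties.

    condition_on: 'prev-repeat' | 'prev-switch' | 'prev-high-conf' |
    'prev-low-conf'.
    """
    ev = signed_evidence_series(session, responses)
    rep = repeat_flags(responses)
    sw = responses["is_switch"].to_numpy().astype(float)
    conf = responses["confidence"].to_numpy().astype(float)
    prev_sw = np.full(len(sw), np.nan)
    prev_conf = np.full(len(sw), np.nan)
    prev_sw[1:] = sw[:-1]
    prev_conf[1:] = conf[:-1]
    prev_sw[session.block_start] = np.nan
    prev_conf[session.block_start] = np.nan
    masks = {
        "prev-repeat": prev_sw == 0,
        "prev-switch": prev_sw == 1,
        "prev-high-conf": prev_conf == 1,
        "prev-low-conf": prev_conf == 0,
    }
    if condition_on not in masks:
        raise ValueError(f"unknown conditioning {condition_on!r}")
    m = masks[condition_on]
    fit = fit_repetition_logistic(ev[m], rep[m])
    fit.message = (fit.message + f" [conditioned on {condition_on}]").strip()
    return fit
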