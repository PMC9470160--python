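"""Change-of-mind statistics and group-level inference.

Per-participant switch/confirmation metrics, 2x2 repeated-measures ANOVAs
(factors such as response type x controllability condition), logistic
regressions regularized by independent Gaussian priors on the coefficients
(MAP estimation; stabilizes participants with few events per cell), and
paired/one-sample group tests with rank-based alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import C_MINUS, C_PLUS


@dataclass
class CellTable:
    """Tidy per-cell event fractions and counts for one participant."""

    table: pd.DataFrame  # columns: measure, condition, level, fraction, n_event, n_total
    diagnostics: dict

    def cell(self, measure: str, condition: str, level: str) -> float:
        t = self.table
        m = (t["measure"] == measure) & (t["condition"] == condition) & (t["level"] == level)
        if not m.any():
            return np.nan
        return float(t.loc[m, "fraction"].iloc[0])


@dataclass
class MapLogisticResult:
    coefficients: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int
    deviance_path: np.ndarray


@dataclass
class RegressionResult:
    """Per-participant coefficient matrix plus group-level t-tests."""

    coefficients: pd.DataFrame  # participants x named coefficients
    group_t: pd.Series
    group_p: pd.Series


def _frac(mask_event: np.ndarray, mask_total: np.ndarray) -> tuple[float, int, int]:
    n_total = int(np.nansum(mask_total))
    n_event = int(np.nansum(mask_event & mask_total))
    return (n_event / n_total if n_total else np.nan), n_event, n_total


def change_of_mind_metrics(responses: pd.DataFrame) -> CellTable:
    """Switch, confirmation and confidence fractions per condition.

    Measures per condition: switch rate, fraction of switches confirmed,
    fraction high-confidence by response type (repeat/switch), by switch
    outcome (confirmed/aborted), and fraction of switches confirmed by
    switch confidence (high/low).  Cells with no events carry NaN
    fractions; diagnostics report the starved cells.
    """
    sw = responses["is_switch"].to_numpy().astype(float)
    conf = responses["confidence"].to_numpy().astype(float)
    confirmed = responses["is_confirmed"].to_numpy().astype(float)
    cond = responses["condition"].to_numpy()
    rows = []
    diagnostics: dict = {"empty_cells": []}
    if not np.nansum(sw == 1):
        diagnostics["no_switches"] = True
    for c in (C_MINUS, C_PLUS):
        in_c = cond == c
        defined = in_c & np.isfinite(sw)
        f, ne, nt = _frac(sw == 1, defined)
        rows.append(("switch_rate", c, "all", f, ne, nt))
        sw_def = in_c & (sw == 1) & np.isfinite(confirmed)
        f, ne, nt = _frac(confirmed == 1, sw_def)
        rows.append(("confirmed_fraction", c, "all", f, ne, nt))
        for level, mask in (("repeat", sw == 0), ("switch", sw == 1)):
            f, ne, nt = _frac(conf == 1, in_c & mask)
            rows.append(("high_conf", c, level, f, ne, nt))
        for level, mask in (("confirmed", confirmed == 1), ("aborted", confirmed == 0)):
            f, ne, nt = _frac(conf == 1, in_c & (sw == 1) & mask)
            rows.append(("high_conf_by_outcome", c, level, f, ne, nt))
        for level, mask in (("high", conf == 1), ("low", conf == 0)):
            f, ne, nt = _frac(confirmed == 1, sw_def & mask)
            rows.append(("confirmed_by_confidence", c, level, f, ne, nt))
    table = pd.DataFrame(
        rows, columns=["measure", "condition", "level", "fraction", "n_event", "n_total"]
    )
    diagnostics["empty_cells"] = table.loc[table["n_total"] == 0, ["measure", "condition", "level"]].to_dict("records")
    return CellTable(table=table, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_2x2(
    cells: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("A", "B"),
    subject: str = "participant",
    method: str = "listwise",
) -> pd.DataFrame:
    """Two-way fully-within 2x2 ANOVA via the contrast decomposition.

    For 1-df within factors the F statistic of each effect equals the
    squared one-sample t of the corresponding within-participant contrast
    (effect MS over its subject-by-effect interaction MS).  Participants
    with incomplete cells are dropped listwise (``method='listwise'``); the
    jackknife alternative imputes each missing cell with the cell mean of
    the remaining participants before the contrast step
    (``method='jackknife'``).

    Returns a DataFrame indexed by effect (A, B, A*B) with columns
    F, p, df1, df2, n.
    """
    fa, fb = within
    wide = cells.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if wide.shape[1] != 4:
        raise ValueError("expected exactly 2 levels per within factor")
    if method == "listwise":
        wide = wide.dropna()
    elif method == "jackknife":
        wide = wide.apply(lambda col: col.fillna(col.mean()))
        wide = wide.dropna()  # cells empty for everyone stay undefined
    else:
        raise ValueError("method must be 'listwise' or 'jackknife'")
    n = len(wide)
    if n < 2:
        raise ValueError("need at least 2 participants with complete cells")
    y = wide.to_numpy().reshape(n, 2, 2)  # participant x A-level x B-level
    contrasts = {
        fa: (y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)),
        fb: (y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1)),
        f"{fa}*{fb}": (y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1]) / 2.0,
    }
    rows = {}
    for name, c in contrasts.items():
        m = c.mean()
        v = c.var(ddof=1)
        if v == 0:
            F = np.inf if m != 0 else 0.0
        else:
            F = n * m * m / v
        p = float(sps.f.sf(F, 1, n - 1)) if np.isfinite(F) else (1.0 if F == 0 else 0.0)
        rows[name] = {"F": float(F), "p": p, "df1": 1, "df2": n - 1, "n": n}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# MAP-regularized logistic regression
# ---------------------------------------------------------------------------

def map_logistic_regression(
    X: np.ndarray,
    y: np.ndarray,
    prior_sd: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MapLogisticResult:
    """MAP logistic regression with independent N(0, prior_sd^2) priors.

    Maximizes the Bernoulli log-likelihood plus the Gaussian log-prior on
    every coefficient (including the intercept column of X) by damped
    Newton iterations; the prior makes the objective strictly concave, so
    the optimum is unique and finite even under complete separation.
    Convergence: gradient norm below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    lam = 1.0 / (prior_sd**2)
    beta = np.zeros(p)

    def objective(b):
        eta = X @ b
        # -loglik + penalty (deviance scale up to constant)
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * lam * b @ b)

    path = [objective(beta)]
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (mu - y) + lam * beta
        grad_norm = float(np.linalg.norm(g))
        if grad_norm < tol:
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + lam * np.eye(p)
        step = np.linalg.solve(H, g)
        # step-halving guarantees monotone decrease of the MAP objective
        t = 1.0
        f0 = path[-1]
        while objective(beta - t * step) > f0 and t > 1e-8:
            t *= 0.5
        beta = beta - t * step
        path.append(objective(beta))
    return MapLogisticResult(
        coefficients=beta,
        converged=grad_norm < tol,
        grad_norm=grad_norm,
        n_iter=it,
        deviance_path=np.array(path),
    )


def confidence_regression(
    per_participant: list[pd.DataFrame],
    outcome: str = "confidence",
    response_col: str = "is_switch",
    prior_sd: float = 2.0,
) -> RegressionResult:
    """Cohort MAP logistic regression of confidence on response type,
    condition, their interaction and evidence strength.

    Design matrix per participant: intercept; response type (effects coded
    +1 repeat / -1 switch, or +1 confirmed / -1 aborted when
    ``response_col='is_confirmed'``); condition (+1 C- / -1 C+);
    interaction; evidence strength in favor of the previous response,
    standardized within participant.  Group-level significance by
    one-sample t-tests across participants.
    """
    names = ["intercept", "response_type", "condition", "interaction", "evidence"]
    coefs = []
    for df in per_participant:
        d = df.dropna(subset=[response_col, "signed_evidence"])
        if response_col == "is_confirmed":
            d = d[d["is_switch"] == 1]
        if len(d) < 10:
            coefs.append([np.nan] * 5)
            continue
        rtype = 1.0 - 2.0 * d[response_col].to_numpy()  # +1 repeat/confirmed
        cond = np.where(d["condition"].to_numpy() == C_MINUS, 1.0, -1.0)
        ev = d["signed_evidence"].to_numpy().astype(float)
        sd = ev.std()
        ev = (ev - ev.mean()) / (sd if sd > 0 else 1.0)
        X = np.column_stack([np.ones(len(d)), rtype, cond, rtype * cond, ev])
        y = d[outcome].to_numpy().astype(float)
        coefs.append(map_logistic_regression(X, y, prior_sd=prior_sd).coefficients)
    cdf = pd.DataFrame(coefs, columns=names)
    t, p = {}, {}
    for name in names:
        vals = cdf[name].dropna().to_numpy()
        res = sps.ttest_1samp(vals, 0.0)
        t[name], p[name] = float(res.statistic), float(res.pvalue)
    return RegressionResult(coefficients=cdf, group_t=pd.Series(t), group_p=pd.Series(p))


# ---------------------------------------------------------------------------
# Group-level tests
# ---------------------------------------------------------------------------

def group_level_tests(
    values: np.ndarray, paired_with: np.ndarray | None = None, popmean: float = 0.0
) -> dict:
    """One-sample (or paired) t-test plus Wilcoxon signed-rank alternative.

    Degenerate inputs (zero variance, all-zero differences) are handled:
    identical paired samples yield t=NaN / p=1 and a Wilcoxon p of 1.
    """
    values = np.asarray(values, dtype=float)
    d = values - (np.asarray(paired_with, dtype=float) if paired_with is not None else popmean)
    out: dict = {"n": int(len(d))}
    if len(d) < 2:
        raise ValueError("need at least 2 participants")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            out.update(t=np.nan, t_p=1.0, wilcoxon_z=np.nan, wilcoxon_p=1.0)
        else:
            out.update(t=np.inf * np.sign(d.mean()), t_p=0.0)
            out.update(_wilcoxon(d))
        return out
    res = sps.ttest_1samp(d, 0.0)
    out.update(t=float(res.statistic), t_p=float(res.pvalue))
    out.update(_wilcoxon(d))
    return out


def _wilcoxon(d: np.ndarray) -> dict:
    nz = d[d != 0]
    if len(nz) == 0:
        return {"wilcoxon_z": np.nan, "wilcoxon_p": 1.0}
    res = sps.wilcoxon(nz, method="approx")
    # signed z from the normal approximation
    z = float(sps.norm.isf(res.pvalue / 2.0) * np.sign(np.median(nz)))
    return {"wilcoxon_z": z, "wilcoxon_p": float(res.pvalue)}
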