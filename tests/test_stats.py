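"""Change-of-mind metrics, repeated-measures ANOVA, MAP logistic, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from volinfer.stats import (
    change_of_mind_metrics,
    confidence_regression,
    group_level_tests,
    map_logistic_regression,
    rm_anova_2x2,
)


def stream_responses(choices, confidences=None, condition="C-"):
    n = len(choices)
    choices = np.asarray(choices)
    conf = np.asarray(confidences) if confidences is not None else np.zeros(n, int)
    sw = np.full(n, np.nan)
    sw[1:] = (choices[1:] != choices[:-1]).astype(float)
    confirmed = np.full(n, np.nan)
    for t in range(n - 1):
        if sw[t] == 1:
            confirmed[t] = float(choices[t + 1] == choices[t])
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": 0,
            "condition": condition,
            "choice": choices,
            "confidence": conf,
            "is_switch": sw,
            "is_confirmed": confirmed,
            "correct": 1,
        }
    )


class TestChangeOfMindMetrics:
    def test_alternating_stream(self):
        resp = stream_responses([1, -1, 1, -1, 1, -1])
        cells = change_of_mind_metrics(resp)
        assert cells.cell("switch_rate", "C-", "all") == 1.0
        assert cells.cell("confirmed_fraction", "C-", "all") == 0.0

    def test_constant_stream(self):
        resp = stream_responses([1] * 8)
        cells = change_of_mind_metrics(resp)
        assert cells.cell("switch_rate", "C-", "all") == 0.0

    def test_hand_enumerated_toy(self):
        """10-trial worked example with hand-labeled switches and
        confirmations."""
        choices = [1, 1, -1, -1, 1, 1, 1, -1, 1, 1]
        conf = [1, 1, 0, 1, 0, 1, 1, 0, 1, 1]
        resp = stream_responses(choices, conf)
        cells = change_of_mind_metrics(resp)
        # switches at t=2,4,7,8 -> 4 of 9 defined trials
        assert cells.cell("switch_rate", "C-", "all") == pytest.approx(4 / 9)
        # confirmed: t=2 (next -1) yes, t=4 yes, t=7 no, t=8 yes
        assert cells.cell("confirmed_fraction", "C-", "all") == pytest.approx(3 / 4)
        # high confidence on switches: t=2:0, t=4:0, t=7:0, t=8:1
        assert cells.cell("high_conf", "C-", "switch") == pytest.approx(1 / 4)
        # high confidence on repeats (t=1,3,5,6,9): all high -> 5/5
        assert cells.cell("high_conf", "C-", "repeat") == pytest.approx(1.0)
        # switches confirmed with high confidence: t=8 only (confirmed)
        assert cells.cell("confirmed_by_confidence", "C-", "high") == pytest.approx(1.0)
        assert cells.cell("confirmed_by_confidence", "C-", "low") == pytest.approx(2 / 3)

    def test_no_switches_diagnostic(self):
        cells = change_of_mind_metrics(stream_responses([1] * 5))
        assert cells.diagnostics.get("no_switches")
        assert np.isnan(cells.cell("confirmed_fraction", "C-", "all"))


def cells_frame(y):
    """participants x 2 x 2 array -> tidy frame for rm_anova_2x2."""
    n = y.shape[0]
    rows = []
    for i in range(n):
        for a in range(2):
            for b in range(2):
                rows.append({"participant": i, "A": f"a{a}", "B": f"b{b}",
                             "value": y[i, a, b]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_additive_effects_zero_interaction(self):
        rng = np.random.default_rng(0)
        # integer-valued cells so the additive structure is float-exact
        subj = rng.integers(-5, 5, (20, 1, 1)).astype(float)
        a_eff = np.array([2.0, -2.0]).reshape(1, 2, 1)
        b_eff = np.array([1.0, -1.0]).reshape(1, 1, 2)
        y = subj + a_eff + b_eff
        res = rm_anova_2x2(cells_frame(y))
        assert res.loc["A*B", "F"] == 0.0 and res.loc["A*B", "p"] == 1.0
        assert res.loc["A", "p"] < 1e-10

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, (12, 2, 2)) + np.array([[0.4, 0.0], [0.1, -0.2]])
        df = cells_frame(y)
        res = rm_anova_2x2(df)
        orc = pingouin.rm_anova(
            data=df, dv="value", within=["A", "B"], subject="participant", detailed=True
        ).set_index("Source")
        assert res.loc["A", "F"] == pytest.approx(orc.loc["A", "F"], rel=1e-6)
        assert res.loc["B", "F"] == pytest.approx(orc.loc["B", "F"], rel=1e-6)
        assert res.loc["A*B", "F"] == pytest.approx(orc.loc["A * B", "F"], rel=1e-6)
        assert res.loc["A", "p"] == pytest.approx(orc.loc["A", "p_unc"], rel=1e-6)

    def test_invariant_to_participant_constant(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, (10, 2, 2))
        shifted = y + rng.normal(0, 5, (10, 1, 1))
        a = rm_anova_2x2(cells_frame(y))
        b = rm_anova_2x2(cells_frame(shifted))
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_destroys_effect(self):
        """Within-participant label permutation yields uniform p-values for
        a constructed main effect."""
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (14, 2, 2))
        y[:, 0, :] += 1.0  # strong A effect
        assert rm_anova_2x2(cells_frame(y)).loc["A", "p"] < 1e-4
        pvals = []
        for _ in range(200):
            yp = y.copy()
            flip = rng.random(14) < 0.5
            yp[flip] = yp[flip][:, ::-1, :]
            pvals.append(rm_anova_2x2(cells_frame(yp)).loc["A", "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_jackknife_retains_incomplete_participants(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (10, 2, 2))
        y[:, 0, :] += 0.8
        df = cells_frame(y)
        df = df.drop(df[(df.participant == 0) & (df.A == "a1") & (df.B == "b1")].index)
        listwise = rm_anova_2x2(df, method="listwise")
        jack = rm_anova_2x2(df, method="jackknife")
        assert listwise.loc["A", "n"] == 9 and jack.loc["A", "n"] == 10
        # both detect the constructed effect
        assert listwise.loc["A", "p"] < 0.01 and jack.loc["A", "p"] < 0.01

    def test_listwise_drop_and_errors(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, (5, 2, 2))
        df = cells_frame(y)
        df = df.drop(df[(df.participant == 0) & (df.A == "a0") & (df.B == "b0")].index)
        res = rm_anova_2x2(df)
        assert (res["n"] == 4).all()
        with pytest.raises(ValueError):
            rm_anova_2x2(cells_frame(y[:1]))


class TestMapLogistic:
    def test_independent_outcome_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20000), rng.normal(size=(20000, 2))])
        y = rng.random(20000) < 0.5
        res = map_logistic_regression(X, y)
        assert res.converged
        assert np.all(np.abs(res.coefficients[1:]) < 0.05)

    def test_separable_data_stays_finite(self):
        x = np.linspace(-2, 2, 40)
        X = np.column_stack([np.ones_like(x), x])
        y = (x > 0).astype(float)
        res = map_logistic_regression(X, y, prior_sd=2.0)
        assert res.converged
        assert np.all(np.abs(res.coefficients) < 10)

    def test_matches_irls_oracle(self):
        """On well-conditioned data the MAP estimate is within 5% of the
        unpenalized ML estimate from statsmodels' IRLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(10**4), rng.normal(size=(10**4, 2))])
        beta = np.array([0.3, 0.8, -0.5])
        y = (rng.random(10**4) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        ours = map_logistic_regression(X, y).coefficients
        irls = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        np.testing.assert_allclose(ours, irls, rtol=0.05)

    def test_monotone_objective_path(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(500), rng.normal(size=(500, 3))])
        y = (rng.random(500) < 0.3).astype(float)
        res = map_logistic_regression(X, y)
        assert np.all(np.diff(res.deviance_path) <= 1e-10)
        assert res.grad_norm < 1e-6


class TestConfidenceRegression:
    def test_recovers_response_type_effect(self):
        """A cohort whose confidence is driven by response type (and
        evidence) yields the corresponding significant group-level
        coefficients, while the null condition coefficient stays flat."""
        rng = np.random.default_rng(6)
        cohort = []
        for _ in range(12):
            n = 400
            sw = rng.integers(0, 2, n).astype(float)
            cond = np.where(rng.random(n) < 0.5, "C-", "C+")
            ev = rng.normal(0, 2, n)
            rtype = 1.0 - 2.0 * sw
            logit = 0.3 + 0.8 * rtype + 0.5 * (ev - ev.mean()) / ev.std()
            conf = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            cohort.append(pd.DataFrame({
                "is_switch": sw, "condition": cond, "signed_evidence": ev,
                "confidence": conf,
            }))
        res = confidence_regression(cohort)
        assert res.group_p["response_type"] < 1e-4
        assert res.group_p["evidence"] < 1e-4
        assert res.group_p["condition"] > 0.01


class TestGroupLevel:
    def test_identical_pairs(self):
        out = group_level_tests(np.ones(8), paired_with=np.ones(8))
        assert out["t_p"] == 1.0 and out["wilcoxon_p"] == 1.0

    def test_constant_shift(self):
        out = group_level_tests(np.arange(8.0) + 1.0, paired_with=np.arange(8.0))
        assert out["t_p"] == 0.0

    def test_textbook_closed_form(self):
        d = np.array([2.0, 1.0, 3.0, -1.0, 2.0, 4.0, 0.0, 1.0, 2.0, 1.0])
        out = group_level_tests(d)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["t"] == pytest.approx(t_manual)
        assert out["t_p"] == pytest.approx(2 * sps.t.sf(abs(t_manual), len(d) - 1))
        ref = sps.wilcoxon(d[d != 0], method="approx")
        assert out["wilcoxon_p"] == pytest.approx(ref.pvalue)
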