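"""Curve construction and psychometric fits."""

import numpy as np
import pandas as pd
import pytest

from volinfer import psychometrics as psy
from volinfer.observer import ModelParams, simulate_agent
from volinfer.task import TaskConfig, generate_session

from conftest import make_toy_session


def toy_responses(session, choices, confidences=None):
    n = len(choices)
    conf = confidences if confidences is not None else np.zeros(n, int)
    block = session.block
    choices = np.asarray(choices)
    sw = np.full(n, np.nan)
    for t in range(1, n):
        if block[t] == block[t - 1]:
            sw[t] = float(choices[t] != choices[t - 1])
    confirmed = np.full(n, np.nan)
    for t in range(n - 1):
        if sw[t] == 1 and block[t + 1] == block[t]:
            confirmed[t] = float(choices[t + 1] == choices[t])
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": block,
            "condition": np.where(session.condition == 0, "C-", "C+"),
            "choice": choices,
            "confidence": np.asarray(conf),
            "is_switch": sw,
            "is_confirmed": confirmed,
            "correct": (choices == session.s).astype(int),
        }
    )


class TestReversalCurve:
    def test_group_by_oracle_on_toy(self):
        """Curve equals a hand-rolled group-by on a 20-trial toy session."""
        states = [1] * 6 + [-1] * 8 + [1] * 6
        session = make_toy_session(states)
        choices = np.array([1] * 7 + [-1] * 7 + [1] * 6)  # adapts 1 trial late
        resp = toy_responses(session, choices)
        curve = psy.build_reversal_curve(resp, session, window=(-4, 4))
        # two reversals: at trial 6 (target -1) and trial 14 (target +1)
        expect = {}
        for k in [-4, -3, -2, -1, 1, 2, 3, 4]:
            events, total = 0, 0
            for r, tgt in [(6, -1), (14, 1)]:
                u = r + k if k < 0 else r + k - 1
                ep_ok = (
                    (states[u] == states[r - 1]) if k < 0 else (states[u] == states[r])
                )
                if 0 <= u < 20 and ep_ok:
                    total += 1
                    events += int(choices[u] == tgt)
            expect[k] = (events, total)
        for i, k in enumerate(curve.bin_centers):
            ev, tot = expect[int(k)]
            assert curve.n_total[i] == tot
            assert curve.n_event[i] == ev

    def test_perfect_and_random_agents(self):
        states = ([1] * 8 + [-1] * 8) * 4
        session = make_toy_session(states)
        resp = toy_responses(session, np.array(states))
        curve = psy.build_reversal_curve(resp, session)
        post = curve.bin_centers >= 1
        assert np.all(curve.fraction[post] == 1.0)
        rng = np.random.default_rng(0)
        big_states = ([1] * 8 + [-1] * 8) * 40
        big = make_toy_session(big_states)
        rand = toy_responses(big, rng.choice([-1, 1], size=len(big_states)))
        c2 = psy.build_reversal_curve(rand, big)
        frac = c2.fraction[c2.n_total > 0]
        assert np.all(np.abs(frac - 0.5) < 0.15)

    def test_no_reversals_raises(self):
        session = make_toy_session([1] * 12)
        resp = toy_responses(session, np.ones(12, int))
        with pytest.raises(psy.EmptyCurveError):
            psy.build_reversal_curve(resp, session)


class TestReversalFits:
    @staticmethod
    def synthetic_curve(predict, n_per_bin=500, seed=0, window=(-4, 8)):
        rng = np.random.default_rng(seed)
        ks = np.arange(window[0], window[1] + 1)
        ks = ks[ks != 0].astype(float)
        p = predict(ks)
        n = np.full(len(ks), n_per_bin)
        return psy.CurveSet(
            axis="trials-from-reversal",
            bin_centers=ks,
            n_total=n,
            n_event=rng.binomial(n, np.clip(p, 0, 1)),
        )

    def test_recovery_from_known_parameters(self):
        curve = self.synthetic_curve(
            lambda k: np.where(k >= 1, 0.85 - (2 * 0.85 - 1) * np.exp(-k / 2.0), 0.15)
        )
        fit = psy.fit_reversal_exponential(curve)
        assert not fit.degenerate
        assert fit.params["asymptote"] == pytest.approx(0.85, abs=0.04)
        assert fit.params["tau"] == pytest.approx(2.0, rel=0.4)

    def test_flat_curve_degenerate(self):
        curve = self.synthetic_curve(lambda k: np.full_like(k, 0.5), seed=1)
        fit = psy.fit_reversal_exponential(curve)
        assert fit.degenerate

    def test_step_curve_instant_adaptation(self):
        curve = self.synthetic_curve(lambda k: (k >= 1).astype(float), n_per_bin=1000)
        fit = psy.fit_reversal_exponential(curve)
        assert fit.params["tau"] < 0.3
        assert fit.degenerate  # tau at its lower bound is flagged

    def test_confidence_drop_formula(self):
        assert psy.confidence_drop(0.4, 0.4, 3.0) == pytest.approx(0.0)
        assert psy.confidence_drop(0.4, 0.8, 3.0) == pytest.approx(
            0.8 - (0.4 + 0.4 * (1 - np.exp(-1 / 3.0)))
        )
        assert psy.confidence_drop(0.4, 0.8, 1e-9) == pytest.approx(0.0, abs=1e-12)
        literal = psy.confidence_drop(0.4, 0.8, 3.0, reading="literal")
        assert literal == pytest.approx(0.4 + 0.4 * (1 - np.exp(-1 / 3.0)))

    def test_confidence_reversal_fit(self):
        curve = self.synthetic_curve(
            lambda k: np.where(k >= 1, 0.4 + 0.4 * (1 - np.exp(-k / 3.0)), 0.7),
            n_per_bin=2000,
        )
        fit = psy.fit_confidence_reversal(curve)
        assert not fit.degenerate
        assert fit.params["pmax"] == pytest.approx(0.8, abs=0.05)
        assert fit.params["drop"] == pytest.approx(
            psy.confidence_drop(0.4, 0.8, 3.0), abs=0.08
        )


class TestSignedEvidence:
    def test_summation_oracle(self):
        dev = [[0.3, -0.2], [0.1, 0.5], [-0.4, 0.2]]
        session = make_toy_session([1, 1, 1], deviations=dev)
        resp = toy_responses(session, np.array([1, -1, 1]))
        ev = psy.signed_evidence_series(session, resp)
        assert np.isnan(ev[0])
        base1 = 2 * 0.5 * (np.cos(0.1) + np.cos(0.5))
        base2 = 2 * 0.5 * (np.cos(-0.4) + np.cos(0.2))
        assert ev[1] == pytest.approx(1 * base1)  # prev choice +1
        assert ev[2] == pytest.approx(-1 * base2)

    def test_flip_prev_choice_flips_sign(self, default_session, agent_run):
        _, resp = agent_run
        ev = psy.signed_evidence_series(default_session, resp)
        flipped = resp.copy()
        flipped["choice"] = -flipped["choice"]
        ev2 = psy.signed_evidence_series(default_session, flipped)
        ok = np.isfinite(ev)
        np.testing.assert_allclose(ev2[ok], -ev[ok], atol=1e-12)


class TestRepetitionLogistic:
    def test_generator_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 5000)
        pse, slope = -1.5, 1.0
        p = 1.0 / (1.0 + np.exp(-slope * (x - pse)))
        y = rng.random(5000) < p
        fit = psy.fit_repetition_logistic(x, y.astype(float))
        assert fit.params["choice_PSE"] == pytest.approx(pse, abs=0.2)
        assert fit.params["slope"] == pytest.approx(slope, rel=0.15)

    def test_symmetric_data_pse_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 4000)
        p = 1.0 / (1.0 + np.exp(-x))
        y = (rng.random(4000) < p).astype(float)
        x, y = np.concatenate([x, -x]), np.concatenate([y, 1 - y])
        fit = psy.fit_repetition_logistic(x, y)
        assert abs(fit.params["choice_PSE"]) < 0.15

    def test_single_class_degenerate(self):
        fit = psy.fit_repetition_logistic(np.linspace(-1, 1, 50), np.ones(50))
        assert fit.degenerate

    def test_separation_is_stabilized(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        with pytest.warns(UserWarning):
            fit = psy.fit_repetition_logistic(x, y)
        assert np.isfinite(fit.params["slope"]) and abs(fit.params["slope"]) < 50

    def test_hazard_ordering_of_pse(self):
        """A low-hazard observer requires more contradicting evidence to
        switch: its choice-PSE is more negative than a high-hazard one."""
        lows, highs = [], []
        for seed in range(5):
            session = generate_session(TaskConfig(n_blocks=4, seed=seed))
            for h, store in [(0.05, lows), (0.35, highs)]:
                p = ModelParams(hazard=h, sigma_inf=1.0, conf_threshold=1.0,
                                sigma_meta=0.5, conf_gain=1.0)
                _, resp = simulate_agent(session, p, np.random.default_rng(100 + seed))
                ev = psy.signed_evidence_series(session, resp)
                rep = psy.repeat_flags(resp)
                store.append(psy.fit_repetition_logistic(ev, rep).params["choice_PSE"])
        assert np.mean(lows) < np.mean(highs)


class TestDualSigmoid:
    def test_constructed_crossing(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-6, 6, 8000)
        rep = rng.random(8000) < 0.5
        # repeat curve: logistic centered at 0 slope 1; switch curve:
        # steeper, crossing the repeat curve at exactly x = -2
        def p_rep(v):
            return 1 / (1 + np.exp(-(0.5 + 0.8 * v)))
        def p_sw(v):
            c_rep = 0.5 + 0.8 * -2.0
            return 1 / (1 + np.exp(-(c_rep + 2.0 * (v + 2.0))))
        p = np.where(rep, p_rep(x), p_sw(x))
        conf = (rng.random(8000) < p).astype(float)
        fit = psy.fit_confidence_dual_sigmoid(x, conf, rep.astype(float))
        assert fit.params["confidence_PSE"] == pytest.approx(-2.0, abs=0.35)

    def test_identical_curves_no_intersection(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-4, 4, 4000)
        rep = rng.random(4000) < 0.5
        p = 1 / (1 + np.exp(-x))
        conf = (rng.random(4000) < p).astype(float)
        fit = psy.fit_confidence_dual_sigmoid(x, conf, rep.astype(float))
        # same generating curve for both classes: any crossing is spurious
        # and slopes are equal; either no PSE or offsets nearly identical
        if not fit.degenerate:
            assert abs(fit.params["slope_repeat"] - fit.params["slope_switch"]) < 0.3

    def test_flat_switch_curve_slope_zero(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-4, 4, 6000)
        rep = rng.random(6000) < 0.5
        p = np.where(rep, 1 / (1 + np.exp(-x)), 0.5)
        conf = (rng.random(6000) < p).astype(float)
        fit = psy.fit_confidence_dual_sigmoid(x, conf, rep.astype(float))
        assert abs(fit.params["slope_switch"]) < 0.12


class TestConditionedPSE:
    def test_null_conditioning_matches_unconditioned(self, default_session):
        """Conditioning on a coin-flip confidence label leaves the PSE
        unchanged within sampling error."""
        p = ModelParams(hazard=0.12, sigma_inf=1.0, conf_threshold=0.0,
                        sigma_meta=10.0, conf_gain=1.0)  # confidence = coin
        _, resp = simulate_agent(default_session, p, np.random.default_rng(0))
        ev = psy.signed_evidence_series(default_session, resp)
        rep = psy.repeat_flags(resp)
        base = psy.fit_repetition_logistic(ev, rep).params["choice_PSE"]
        hi = psy.conditioned_pse(default_session, resp, "prev-high-conf")
        lo = psy.conditioned_pse(default_session, resp, "prev-low-conf")
        assert hi.params["choice_PSE"] == pytest.approx(base, abs=0.6)
        assert lo.params["choice_PSE"] == pytest.approx(base, abs=0.6)

    def test_orderings_on_simulation(self):
        """After a repeat (or a high-confidence response) more evidence is
        needed to switch than after a switch (or low confidence)."""
        d_rep, d_conf = [], []
        for seed in range(6):
            session = generate_session(TaskConfig(seed=seed))
            p = ModelParams(hazard=0.1, sigma_inf=1.0, conf_threshold=1.5,
                            sigma_meta=0.8, conf_gain=1.0)
            _, resp = simulate_agent(session, p, np.random.default_rng(50 + seed))
            pse = {
                k: psy.conditioned_pse(session, resp, k).params["choice_PSE"]
                for k in ("prev-repeat", "prev-switch", "prev-high-conf", "prev-low-conf")
            }
            d_rep.append(pse["prev-repeat"] - pse["prev-switch"])
            d_conf.append(abs(pse["prev-low-conf"]) - abs(pse["prev-high-conf"]))
        assert np.mean(d_rep) < 0  # more negative PSE after a repeat
        assert np.mean(d_conf) < 0  # low confidence -> PSE closer to zero
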