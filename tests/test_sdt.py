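import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from ulvfit import (ModelSpec, SDTModel, fit_sdt, inv_pc_mafc, loglik, pc_mafc,
                    score_responses, standard_errors)
from ulvfit._jmle import split_block_se
from ulvfit.sdt import ScoreTable, _SDTLink


def make_scores(K, N, persons=None, items=None):
    P, I = np.asarray(K).shape
    persons = persons or [f"p{i}" for i in range(P)]
    items = items or [f"i{j}" for j in range(I)]
    rows = [dict(person_id=persons[p], item_id=items[i], k=K[p][i], n=N[p][i])
            for p in range(P) for i in range(I)]
    return ScoreTable(pd.DataFrame(rows))


class TestPsychometricFunction:
    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_chance_at_origin(self, m):
        assert pc_mafc(0.0, m) == pytest.approx(1.0 / m, abs=1e-12)

    def test_m2_closed_form(self):
        d = np.linspace(-4, 4, 161)
        assert np.max(np.abs(pc_mafc(d, 2) - norm.cdf(d / np.sqrt(2)))) < 1e-8

    @given(st.integers(2, 6))
    @settings(deadline=None, max_examples=5)
    def test_strictly_increasing_with_limits(self, m):
        d = np.linspace(-8, 8, 200)
        p = pc_mafc(d, m)
        assert np.all(np.diff(p) > 0)
        assert pc_mafc(-30.0, m) < 1e-6 and pc_mafc(30.0, m) > 1 - 1e-6

    def test_below_chance_for_negative_d(self):
        assert pc_mafc(-1.0, 3) < 1 / 3

    def test_rejects_m_below_2(self):
        with pytest.raises(ValueError):
            pc_mafc(0.5, 1)

    @pytest.mark.parametrize("p,m,expected", [
        (0.5, 2, 0.0),
        (1 / 3, 3, 0.0),
        (float(norm.cdf(1 / np.sqrt(2))), 2, 1.0),
    ])
    def test_inverse_known_points(self, p, m, expected):
        assert inv_pc_mafc(p, m) == pytest.approx(expected, abs=1e-8)

    @given(st.floats(0.05, 0.95), st.integers(2, 4))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_inverse_roundtrip(self, p, m):
        if p <= 1e-6 or p >= 1 - 1e-6:
            return
        assert pc_mafc(inv_pc_mafc(p, m), m) == pytest.approx(p, abs=1e-8)

    def test_inverse_rejects_degenerate_p(self):
        with pytest.raises(ValueError):
            inv_pc_mafc(0.0, 2)

    def test_link_derivatives_match_finite_differences(self):
        link = _SDTLink(np.array([2, 3, 4]))
        D = np.array([[-1.0, 0.3, 1.7]])
        h = 1e-5
        p, dp, d2p = link.evaluate(D)
        p_hi, _, _ = link.evaluate(D + h)
        p_lo, _, _ = link.evaluate(D - h)
        assert dp == pytest.approx((p_hi - p_lo) / (2 * h), abs=1e-7)
        assert d2p == pytest.approx((p_hi - 2 * p + p_lo) / h**2, abs=1e-5)


class TestScoring:
    @pytest.mark.parametrize("trials,expected", [((1, 1, 1), 3), ((0, 0, 0), 0), ((1, 0, 1), 2)])
    def test_summed_scores(self, trials, expected):
        df = pd.DataFrame(dict(person_id="p", item_id="i",
                               trial=[1, 2, 3], correct=list(trials)))
        table = score_responses(df)
        assert table.frame["k"].iloc[0] == expected
        assert table.frame["n"].iloc[0] == 3

    def test_duplicate_trial_key_rejected(self):
        df = pd.DataFrame(dict(person_id="p", item_id="i", trial=[1, 1], correct=[1, 0]))
        with pytest.raises(ValueError, match="duplicate"):
            score_responses(df)

    def test_nonbinary_correct_rejected(self):
        df = pd.DataFrame(dict(person_id="p", item_id="i", trial=[1], correct=[2]))
        with pytest.raises(ValueError):
            score_responses(df)

    def test_full_dataset_scores_bounded(self, default_dataset):
        table = score_responses(default_dataset.records)
        assert table.frame["k"].between(0, 3).all()
        assert (table.frame["n"] == 3).all()


class TestLoglik:
    def test_single_chance_cell(self):
        scores = make_scores([[1]], [[1]])
        val = loglik(scores, pd.Series({"p0": 0.0}), pd.Series({"i0": 0.0}), {"i0": 2})
        assert val == pytest.approx(np.log(0.5), abs=1e-10)

    def test_three_correct_at_d1(self):
        scores = make_scores([[3]], [[3]])
        val = loglik(scores, pd.Series({"p0": 1.0}), pd.Series({"i0": 0.0}), {"i0": 2})
        assert val == pytest.approx(3 * np.log(norm.cdf(1 / np.sqrt(2))), abs=1e-8)

    @given(st.floats(-1.5, 1.5))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_translation_invariance(self, c):
        scores = make_scores([[2, 1], [3, 0]], [[3, 3], [3, 3]])
        m = {"i0": 2, "i1": 4}
        th = pd.Series({"p0": 0.4, "p1": -0.2})
        b = pd.Series({"i0": -0.5, "i1": 0.3})
        assert loglik(scores, th + c, b + c, m) == pytest.approx(
            loglik(scores, th, b, m), abs=1e-9)

    def test_missing_parameter_raises(self):
        scores = make_scores([[2]], [[3]])
        with pytest.raises(KeyError):
            loglik(scores, pd.Series({"p0": 0.0}), pd.Series({"other": 0.0}), {"other": 2})


class TestFit:
    def test_anchoring_mean_theta_zero(self, default_fit):
        _, res = default_fit
        assert abs(res.theta.mean()) < 1e-6
        assert res.converged

    def test_chance_item_lands_at_origin(self, bank):
        # balanced cohort with mean ability zero answering one m=2 item at chance
        rng = np.random.default_rng(5)
        nP, T = 500, 30
        theta = np.linspace(-1, 1, nP)
        K = np.column_stack([
            rng.binomial(T, norm.cdf(theta / np.sqrt(2))),          # anchor item, b=0
            rng.binomial(T, norm.cdf((theta - (-0.8)) / np.sqrt(2))),
            rng.binomial(T, 0.5 * np.ones(nP)),                      # pure chance item
        ])
        N = np.full_like(K, T)
        scores = make_scores(K.tolist(), N.tolist())
        res = fit_sdt(scores, {"i0": 2, "i1": 2, "i2": 2})
        assert abs(res.b["i2"]) < 2 * res.se_b["i2"]

    def test_monotone_in_success_count(self):
        K = [[2, 1, 2], [1, 2, 0], [3, 1, 1]]
        N = [[3, 3, 3]] * 3
        m = {"i0": 2, "i1": 3, "i2": 4}
        base = fit_sdt(make_scores(K, N), m).theta["p0"]
        K2 = [row[:] for row in K]
        K2[0][1] += 1
        bumped = fit_sdt(make_scores(K2, N), m).theta["p0"]
        assert bumped >= base - 1e-8

    def test_perfect_scorer_capped_and_flagged(self):
        K = [[3, 3, 3], [1, 2, 1], [2, 1, 0]]
        N = [[3, 3, 3]] * 3
        res = fit_sdt(make_scores(K, N), {"i0": 2, "i1": 2, "i2": 2})
        # an all-correct person drifts to the cap once items settle below
        assert res.theta["p0"] == res.theta.max()
        assert res.at_bound_theta["p0"] or res.theta["p0"] < 5.0

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            SDTModel(ScoreTable(pd.DataFrame(columns=["person_id", "item_id", "k", "n"])), {})

    def test_init_independence(self, default_fit, m_map):
        scores, res = default_fit
        rng = np.random.default_rng(0)
        start = (rng.normal(0, 1, len(res.theta)), rng.normal(0, 1, len(res.b)))
        res2 = SDTModel(scores, m_map).fit(start=start)
        keep = ~res.at_bound_theta
        assert np.max(np.abs(res.theta[keep] - res2.theta[keep])) < 1e-4
        keep_b = ~res.at_bound_b
        assert np.max(np.abs(res.b[keep_b] - res2.b[keep_b])) < 1e-4

    def test_results_table_and_summary(self, default_fit):
        _, res = default_fit
        frame = res.to_frame()
        assert set(frame["kind"]) == {"person", "item"}
        assert len(frame) == 37 + 57
        np.testing.assert_allclose(frame["ci_high"] - frame["ci_low"],
                                   2 * 1.96 * frame["se"], rtol=1e-12)
        assert "relative d'" in res.summary()


class TestStandardErrors:
    def test_doubling_trials_shrinks_se_by_sqrt2(self):
        K = [[2, 1, 3], [1, 2, 0], [2, 3, 1], [0, 1, 2]]
        N = [[3, 3, 3]] * 4
        m = {"i0": 2, "i1": 3, "i2": 4}
        res1 = fit_sdt(make_scores(K, N), m)
        K2 = [[2 * k for k in row] for row in K]
        N2 = [[6, 6, 6]] * 4
        res2 = fit_sdt(make_scores(K2, N2), m)
        keep = ~(res1.se_unreliable_b | res2.se_unreliable_b)
        ratio = (res2.se_b[keep] / res1.se_b[keep]).to_numpy()
        assert np.allclose(ratio, 1 / np.sqrt(2), atol=0.02)

    def test_se_at_chance_matches_binomial_information(self):
        # person at exactly chance on every m=2 item: observed info reduces to
        # n * Pc'(0)^2 / (Pc (1-Pc)) per item with Pc'(0;2) = 1/(2 sqrt(pi))
        nI, n = 6, 4
        K = np.full((2, nI), n // 2)
        N = np.full((2, nI), n)
        scores = make_scores(K.tolist(), N.tolist())
        link = _SDTLink(np.full(nI, 2))
        se_t, _, _, _ = split_block_se(K.astype(float), N.astype(float), link,
                                       np.zeros(2), np.zeros(nI), 1e-6)
        dp0 = 1.0 / (2.0 * np.sqrt(np.pi))
        info = nI * n * dp0**2 / 0.25
        assert se_t[0] == pytest.approx(1.0 / np.sqrt(info), rel=1e-9)

    def test_joint_se_close_to_block_se_when_well_determined(self, bank, m_map):
        from ulvfit import SimulationConfig, simulate_responses

        ds = simulate_responses(bank, SimulationConfig(n_persons=60, trials_per_item=10, seed=9))
        scores = score_responses(ds.records)
        res_block = fit_sdt(scores, m_map)
        res_joint = standard_errors(scores, fit_sdt(scores, m_map), m_map, method="joint")
        keep = ~res_block.se_unreliable_b
        ratio = (res_joint.se_b[keep] / res_block.se_b[keep]).to_numpy()
        # joint information never reports less uncertainty than split-block
        assert np.all(ratio > 0.99)
        assert np.median(ratio) < 1.5
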