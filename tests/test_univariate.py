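"""Univariate prognostic layer: z-scores, landmark tests, CI, Noether, FDR."""

import numpy as np
import pandas as pd
import pytest

from recurrad.univariate import (
    bh_fdr,
    concordance_index,
    event_status_at,
    noether_pvalue,
    run_univariate,
    spearman_cross,
    wilcoxon_association,
    zscore_normalize,
)
from oracles import bh_brute, concordance_brute


def make_clinical(time, event, endpoint="dm"):
    n = len(time)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            f"time_{endpoint}": time,
            f"event_{endpoint}": event,
        }
    )


class TestZscore:
    def test_hand_example(self):
        out = zscore_normalize(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["f"], [-1, 0, 1])

    def test_idempotent(self, rng):
        t = pd.DataFrame({"f": rng.standard_normal(40)})
        once = zscore_normalize(t)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once["f"], twice["f"], atol=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="flat"):
            zscore_normalize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestEventStatusAt:
    def test_rules(self):
        clin = make_clinical([5.0, 12.0, 8.0], [1, 0, 0])
        s = event_status_at(clin, "dm", 10.0)
        assert list(s) == ["event", "no_event", "excluded"]

    def test_partition_property(self, rng):
        time = rng.exponential(15, 200)
        event = rng.integers(0, 2, 200)
        s = event_status_at(make_clinical(time, event), "dm", 10.0)
        assert s.isin(["event", "no_event", "excluded"]).all()
        assert len(s) == 200

    def test_invalid_inputs(self):
        clin = make_clinical([5.0], [1])
        with pytest.raises(ValueError):
            event_status_at(clin, "dm", 0.0)
        with pytest.raises(ValueError):
            event_status_at(make_clinical([-1.0], [1]), "dm", 5.0)


class TestWilcoxon:
    def test_exact_p_three_vs_three(self):
        statuses = np.array(["event"] * 3 + ["no_event"] * 3)
        values = np.array([1.0, 2, 3, 4, 5, 6])
        diff, p = wilcoxon_association(values, statuses)
        assert p == pytest.approx(0.1)
        assert diff == pytest.approx(2 - 5)

    def test_identical_groups(self, rng):
        vals = np.concatenate([np.arange(5.0), np.arange(5.0)])
        statuses = np.array(["event"] * 5 + ["no_event"] * 5)
        diff, _ = wilcoxon_association(vals, statuses)
        assert diff == 0.0

    def test_empty_group_flagged(self, rng):
        diff, p = wilcoxon_association(rng.standard_normal(4), np.array(["event"] * 4))
        assert np.isnan(diff) and np.isnan(p)

    def test_planted_shift_recovers_sign(self):
        rng = np.random.default_rng(8)
        ev = rng.standard_normal(40) + 1.0
        ne = rng.standard_normal(60)
        vals = np.concatenate([ev, ne])
        statuses = np.array(["event"] * 40 + ["no_event"] * 60)
        diff, p = wilcoxon_association(vals, statuses)
        assert diff > 0 and p < 0.05


class TestConcordanceIndex:
    def test_three_subject_enumeration(self):
        assert concordance_index([3, 1, 2], [2, 4, 6], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_perfect_orientation_limits(self):
        # orientation: higher value => earlier event => CI 1
        time = np.array([1.0, 2, 3, 4, 5])
        assert concordance_index(time, time, np.ones(5)) == pytest.approx(0.0)
        assert concordance_index(-time, time, np.ones(5)) == pytest.approx(1.0)

    def test_matches_bruteforce_and_lifelines(self, rng):
        from lifelines.utils import concordance_index as ll_ci

        for _ in range(10):
            n = 30
            x = rng.standard_normal(n)
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            ours = concordance_index(x, time, event)
            assert ours == pytest.approx(concordance_brute(x, time, event), abs=1e-12)
            # lifelines orients CI as "higher prediction, longer survival"
            assert ours == pytest.approx(ll_ci(time, -x, event), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(40)
        time = rng.exponential(10, 40)
        event = rng.integers(0, 2, 40)
        event[0] = 1
        assert concordance_index(np.exp(x), time, event) == pytest.approx(
            concordance_index(x, time, event)
        )

    def test_complement_symmetry(self, rng):
        x = rng.standard_normal(30)  # continuous: no feature ties
        time = rng.exponential(5, 30)
        event = np.ones(30, int)
        assert concordance_index(x, time, event) + concordance_index(
            -x, time, event
        ) == pytest.approx(1.0)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1, 2], [5.0, 6.0], [0, 0])


class TestNoether:
    def test_ci_half_gives_p_one(self):
        # an antisymmetric configuration with CI exactly 0.5
        x = np.array([1.0, 2.0, 2.0, 1.0])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        res = concordance_index(x, time, np.ones(4, int), with_pairs=True)
        assert res.ci == pytest.approx(0.5)
        p = noether_pvalue(res)
        assert np.isnan(p) or p == pytest.approx(1.0)

    def test_strong_signal_small_p(self, rng):
        time = rng.exponential(10, 80)
        x = -time + 0.01 * rng.standard_normal(80)
        res = concordance_index(x, time, np.ones(80, int), with_pairs=True)
        assert noether_pvalue(res) < 1e-6

    def test_null_rejection_rate(self):
        # quick calibration companion to the full 1000-rep acceptance check
        rejections = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(10_000 + rep)
            x = rng.standard_normal(60)
            time = rng.exponential(10, 60)
            res = concordance_index(x, time, np.ones(60, int), with_pairs=True)
            rejections += noether_pvalue(res) < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestBhFdr:
    def test_hand_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_threshold_search_oracle(self, rng):
        for _ in range(30):
            p = rng.random(rng.integers(1, 15))
            q = bh_fdr(p)
            for alpha in (0.01, 0.05, 0.1, 0.3, 0.7):
                np.testing.assert_array_equal(q <= alpha, bh_brute(p, alpha))


class TestSpearmanCross:
    def test_monotone_and_antimonotone(self, rng):
        x = rng.standard_normal(50)
        fb = pd.DataFrame({"f": x})
        aip = pd.DataFrame({"up": np.exp(x), "down": -(x**3)})
        out = spearman_cross(fb, aip)
        rho = out.set_index("aip_feature")["spearman_rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)
        assert out.set_index("aip_feature")["strong"].all()

    def test_independent_noise_weak(self):
        rng = np.random.default_rng(6)
        fb = pd.DataFrame({"f": rng.standard_normal(112)})
        aip = pd.DataFrame({"g": rng.standard_normal(112)})
        out = spearman_cross(fb, aip)
        assert abs(out["spearman_rho"].iloc[0]) < 0.3
        assert not out["strong"].iloc[0]


class TestRunUnivariate:
    def test_end_to_end_table(self):
        rng = np.random.default_rng(7)
        n = 120
        risk = rng.standard_normal(n)
        time = rng.exponential(12 * np.exp(-1.2 * risk))
        event = (time < 30).astype(int)
        time = np.minimum(time, 30)
        clin = make_clinical(time, event)
        feats = pd.DataFrame({"risk": risk, "noise": rng.standard_normal(n)})
        out = run_univariate(feats, clin, "dm", "auto", image_type="FB")
        out = out.set_index("feature")
        assert out.loc["risk", "ci"] > 0.65
        assert out.loc["risk", "noether_q"] < 0.05
        assert abs(out.loc["noise", "ci"] - 0.5) < 0.12
        assert (out["noether_q"] >= out["noether_p"] - 1e-12).all()
        assert out["landmark_months"].iloc[0] == pytest.approx(
            np.median(time[event == 1])
        )

    def test_fdr_calibration_all_noise(self):
        # with a null cohort, q < 0.05 calls are (nearly always) zero
        false_calls = 0
        for seed in range(50):
            rng = np.random.default_rng(20_000 + seed)
            n = 80
            clin = make_clinical(rng.exponential(15, n), rng.integers(0, 2, n))
            feats = pd.DataFrame(
                rng.standard_normal((n, 10)), columns=[f"f{i}" for i in range(10)]
            )
            out = run_univariate(feats, clin, "dm")
            false_calls += int((out["noether_q"] < 0.05).sum())
        # BH controls the false-discovery *rate*; a handful of calls over
        # 500 null tests is within its guarantee
        assert false_calls <= 12
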