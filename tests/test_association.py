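"""Clinical association tests: ANOVA, paired t, Tukey, Pearson, KM/Cox."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmodscore import (
    ClinicalTable,
    group_posthoc,
    matched_comparison,
    proliferation_correlation,
    stage_trend,
    survival_by_quartile,
)
from mirmodscore.association import km_estimate


def _scores(vals, ids=None, col="general_score"):
    ids = ids or [f"s{i}" for i in range(len(vals))]
    return pd.DataFrame({col: vals}, index=pd.Index(ids, name="sample"))


def _clin(**cols):
    n = len(next(iter(cols.values())))
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
    return ClinicalTable(pd.DataFrame(cols, index=idx))


class TestStageTrend:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        scores = _scores(np.concatenate([a, b]))
        clin = _clin(stage_cat=["I"] * 30 + ["II"] * 25)
        rep = stage_trend(scores, clin, stage_field="stage_cat")
        t, _ = stats.ttest_ind(a, b)
        assert rep.statistic == pytest.approx(t ** 2, abs=1e-10)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(300):
            scores = _scores(rng.normal(size=60))
            clin = _clin(stage_cat=["I", "II", "III"] * 20)
            ps.append(stage_trend(scores, clin, stage_field="stage_cat").p)
        # Kolmogorov-Smirnov against uniform
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.001

    def test_small_groups_excluded(self, rng):
        scores = _scores(rng.normal(size=21))
        clin = _clin(stage_cat=["I"] * 10 + ["II"] * 10 + ["III"])
        rep = stage_trend(scores, clin, stage_field="stage_cat")
        assert set(rep.groups.index) == {"I", "II"}


class TestMatched:
    def _paired(self, normal_vals, tumor_vals):
        n = len(normal_vals)
        ids = [f"n{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        scores = pd.DataFrame(
            {"impact_score": list(normal_vals) + list(tumor_vals)},
            index=pd.Index(ids, name="sample"))
        clin = ClinicalTable(pd.DataFrame({
            "tissue": ["normal"] * n + ["tumor"] * n,
            "pair_id": [f"p{i}" for i in range(n)] * 2,
        }, index=scores.index))
        return scores, clin

    def test_zero_differences(self, rng):
        v = rng.normal(size=10)
        scores, clin = self._paired(v, v)
        rep = matched_comparison(scores, clin)
        assert rep.statistic == 0.0 and rep.p == 1.0

    def test_constant_shift_degenerate_flag(self):
        scores, clin = self._paired([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        rep = matched_comparison(scores, clin)
        assert rep.extra["degenerate"]
        assert np.isnan(rep.statistic)

    def test_matches_hand_formula(self, rng):
        normal = rng.normal(1.0, 1.0, size=40)
        tumor = rng.normal(0.0, 1.0, size=40)
        scores, clin = self._paired(normal, tumor)
        rep = matched_comparison(scores, clin)
        d = normal - tumor
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert rep.statistic == pytest.approx(t, abs=1e-10)
        assert rep.p == pytest.approx(p, abs=1e-10)


class TestPosthoc:
    def test_identical_groups_all_adjusted_p_near_one(self, rng):
        base = rng.normal(size=20)
        scores = _scores(np.tile(base, 3))
        clin = _clin(size_cat=["T1"] * 20 + ["T2"] * 20 + ["T3"] * 20)
        rep = group_posthoc(scores, clin, "size_cat", score_col="general_score")
        assert (rep.posthoc["p-adj"].astype(float) > 0.95).all()

    def test_displaced_group_flagged(self, rng):
        vals = np.concatenate([rng.normal(size=20), rng.normal(size=20),
                               rng.normal(5, 1, size=20)])
        clin = _clin(size_cat=["T1"] * 20 + ["T2"] * 20 + ["T3"] * 20)
        rep = group_posthoc(_scores(vals), clin, "size_cat", score_col="general_score")
        ph = rep.posthoc.set_index(["group1", "group2"])
        assert float(ph.loc[("T1", "T3"), "p-adj"]) < 0.01
        assert float(ph.loc[("T2", "T3"), "p-adj"]) < 0.01
        assert float(ph.loc[("T1", "T2"), "p-adj"]) > 0.05

    def test_tukey_no_less_conservative_than_t(self, rng):
        vals = rng.normal(size=45)
        clin = _clin(size_cat=["T1"] * 15 + ["T2"] * 15 + ["T3"] * 15)
        rep = group_posthoc(_scores(vals), clin, "size_cat", score_col="general_score")
        for _, row in rep.posthoc.iterrows():
            g1 = vals[np.array(clin.table["size_cat"] == row["group1"])]
            g2 = vals[np.array(clin.table["size_cat"] == row["group2"])]
            _, p_raw = stats.ttest_ind(g1, g2)
            assert float(row["p-adj"]) >= p_raw - 0.02


class TestProliferation:
    def test_perfect_negative_line(self):
        vals = np.arange(10.0)
        clin = _clin(proliferation=-2 * vals + 3)
        rep = proliferation_correlation(_scores(vals, col="impact_score"),
                                        clin, score_col="impact_score")
        assert rep.statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        clin = _clin(proliferation=y)
        rep = proliferation_correlation(_scores(x, col="impact_score"), clin,
                                        score_col="impact_score")
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum())
            * np.sqrt(((y - y.mean()) ** 2).sum()))
        assert rep.statistic == pytest.approx(r, abs=1e-12)


def km_oracle(times, events):
    """Hand product-limit estimate at each distinct event time."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, {}
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


class TestSurvival:
    def test_km_product_limit_no_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 1, 1]
        sf = km_estimate(times, events)
        for t, s in km_oracle(times, events).items():
            assert sf.loc[t].iloc[0] == pytest.approx(s, abs=1e-12)

    def test_km_matches_oracle_with_censoring(self, rng):
        for _ in range(20):
            times = rng.exponential(5, size=30).round(2)
            events = rng.integers(0, 2, size=30)
            if events.sum() == 0:
                continue
            sf = km_estimate(times, events)
            for t, s in km_oracle(times, events).items():
                assert sf.loc[t].iloc[0] == pytest.approx(s, abs=1e-12)

    def _surv_inputs(self, rng, n=160, effect=0.0):
        score = rng.normal(size=n)
        lam = 0.2 * np.exp(-effect * score)
        t_event = rng.exponential(1 / lam)
        horizon = 10.0
        clin = _clin(os_time=np.minimum(t_event, horizon),
                     os_event=(t_event <= horizon).astype(int),
                     size_cat=rng.choice(["T1", "T2", "T3"], size=n),
                     stage_cat=rng.choice(["I", "II", "III"], size=n))
        return _scores(score), clin

    def test_quartile_split_sizes_and_strictness(self, rng):
        scores, clin = self._surv_inputs(rng)
        rep, km = survival_by_quartile(scores, clin)
        assert rep.extra["n_lq"] <= len(scores) // 4 + 1
        assert set(km) == {"LQ", "UQ"}
        q1 = rep.extra["q1"]
        assert (scores.loc[scores["general_score"] < q1].shape[0]
                == rep.extra["n_lq"])

    def test_planted_effect_detected_and_adjusted_cox(self, rng):
        scores, clin = self._surv_inputs(rng, n=300, effect=0.8)
        rep, _ = survival_by_quartile(scores, clin,
                                      covariates=("size_cat", "stage_cat"))
        assert rep.p < 0.01
        assert rep.extra["cox_log_hr"] < 0  # high score protective
        assert rep.extra["cox_ci_low"] < rep.extra["cox_hr"] < rep.extra["cox_ci_high"]

    def test_event_floor_enforced(self, rng):
        scores, clin = self._surv_inputs(rng, n=40)
        clin.table["os_event"] = 0
        with pytest.raises(ValueError, match="events"):
            survival_by_quartile(scores, clin)

    def test_affine_score_rescaling_invariant(self, rng):
        scores, clin = self._surv_inputs(rng, n=200, effect=0.5)
        rep1, _ = survival_by_quartile(scores, clin)
        rep2, _ = survival_by_quartile(scores * 3.0 + 7.0, clin)
        assert rep1.p == pytest.approx(rep2.p, rel=1e-9)
        assert rep1.extra["cox_log_hr"] == pytest.approx(
            rep2.extra["cox_log_hr"], rel=1e-6)
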