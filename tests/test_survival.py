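"""z-score signature, median split, follow-up handling, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest

import oracles
from mirscreen import (
    CohortSimSpec,
    correlate_score_with_readout,
    gen_cohort,
    gene_zscores,
    km_estimate,
    logrank_test,
    median_split,
    minmax_normalize,
    network_score,
    signature_survival_analysis,
    truncate_followup,
)
from mirscreen.simulate import SIGNATURE_GENES


def _expr(values, genes, samples=None):
    samples = samples or [f"s{i}" for i in range(np.shape(values)[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


class TestZScores:
    def test_two_point_case(self):
        z = gene_zscores(_expr([[1.0, 3.0]], ["g"]), ["g"])
        assert list(z.loc["g"]) == [-1.0, 1.0]  # population SD = 1

    def test_mean_zero_popsd_one(self, rng):
        expr = _expr(rng.normal(8, 2, size=(4, 20)), [f"g{i}" for i in range(4)])
        z = gene_zscores(expr, list(expr.index))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        expr = _expr(rng.normal(size=(4, 20)), [f"g{i}" for i in range(4)])
        z = gene_zscores(expr, list(expr.index))
        for g in expr.index:
            assert np.allclose(z.loc[g], oracles.zscores_brute(list(expr.loc[g])), atol=1e-12)

    def test_probes_averaged_before_standardizing(self, rng):
        vals = rng.normal(size=(2, 6))
        dup = pd.DataFrame(vals, index=["g", "g"], columns=[f"s{i}" for i in range(6)])
        z = gene_zscores(dup, ["g"])
        want = oracles.zscores_brute(list(vals.mean(axis=0)))
        assert np.allclose(z.loc["g"], want, atol=1e-12)

    def test_zero_sd_gene_named(self):
        expr = _expr([[1.0, 1.0, 1.0]], ["flatgene"])
        with pytest.raises(ValueError, match="flatgene"):
            gene_zscores(expr, ["flatgene"])

    def test_affine_invariance(self, rng):
        expr = _expr(rng.normal(8, 2, size=(4, 15)), list(SIGNATURE_GENES))
        transformed = expr.mul(pd.Series([2.0, 0.5, 3.0, 1.5], index=expr.index), axis=0) \
                          .add(pd.Series([1.0, -4.0, 0.0, 7.0], index=expr.index), axis=0)
        z1 = gene_zscores(expr, list(SIGNATURE_GENES))
        z2 = gene_zscores(transformed, list(SIGNATURE_GENES))
        assert np.allclose(z1, z2, atol=1e-10)


class TestNetworkScore:
    def test_single_gene_equals_its_z(self, rng):
        expr = _expr(rng.normal(size=(1, 10)), ["g"])
        z = gene_zscores(expr, ["g"])
        assert np.allclose(network_score(z), z.loc["g"])

    def test_cohort_mean_zero(self, rng):
        expr = _expr(rng.normal(size=(4, 12)), list(SIGNATURE_GENES))
        z = gene_zscores(expr, list(SIGNATURE_GENES))
        assert network_score(z).mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop(self, rng):
        expr = _expr(rng.normal(size=(3, 8)), ["a", "b", "c"])
        z = gene_zscores(expr, ["a", "b", "c"])
        score = network_score(z)
        for j, s in enumerate(z.columns):
            want = sum(z.iloc[i, j] for i in range(3))
            assert score[s] == pytest.approx(want, abs=1e-12)

    def test_empty_gene_set_errors(self, rng):
        expr = _expr(rng.normal(size=(2, 5)), ["a", "b"])
        z = gene_zscores(expr, ["a", "b"])
        with pytest.raises(ValueError):
            network_score(z.iloc[:0])


class TestMinMaxAndSplit:
    def test_minmax_known_values(self):
        assert list(minmax_normalize(np.array([2.0, 4.0, 6.0]))) == [0.0, 0.5, 1.0]

    def test_minmax_constant_errors(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([3.0, 3.0]))

    def test_minmax_order_preserving(self, rng):
        v = pd.Series(rng.normal(size=30))
        assert (minmax_normalize(v).rank() == v.rank()).all()

    def test_median_split_even_cohort(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert list(median_split(s)) == ["low", "low", "high", "high"]

    def test_all_ties_go_low(self):
        s = pd.Series([2.0, 2.0, 2.0])
        assert set(median_split(s)) == {"low"}

    def test_split_balance_up_to_median_ties(self, rng):
        s = pd.Series(rng.normal(size=101))
        groups = median_split(s)
        n_ties = int((s == s.median()).sum())
        assert abs((groups == "high").sum() - (groups == "low").sum()) <= max(n_ties, 1)


class TestFollowup:
    def test_truncation_censors_late_events(self):
        surv = pd.DataFrame({"time": [7.0, 3.0], "event": [1, 1]}, index=["a", "b"])
        out = truncate_followup(surv, horizon=5.0)
        assert out.loc["a", "time"] == 5.0 and out.loc["a", "event"] == 0
        assert out.loc["b", "time"] == 3.0 and out.loc["b", "event"] == 1

    def test_uninformative_records_dropped(self):
        surv = pd.DataFrame({"time": [2.0, np.nan], "event": [1, np.nan]})
        assert len(truncate_followup(surv, 5.0)) == 1

    def test_event_count_never_grows(self, rng):
        surv = pd.DataFrame({"time": rng.uniform(0, 12, 50),
                             "event": rng.integers(0, 2, 50)})
        out = truncate_followup(surv, 5.0)
        assert out["event"].sum() <= surv["event"].sum()


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        km = km_estimate(surv)
        assert np.all(km.survival["all"] == 1.0)

    def test_two_subject_hand_computation(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        km = km_estimate(surv)
        assert km.survival_at("all", 1.0) == pytest.approx(0.5)
        assert km.survival_at("all", 2.0) == pytest.approx(0.0)

    def test_matches_brute_force_product(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            times = rng.integers(1, 8, size=n).astype(float)  # force ties
            events = rng.integers(0, 2, size=n)
            km = km_estimate(pd.DataFrame({"time": times, "event": events}))
            for t, s in oracles.km_brute(list(times), list(events)).items():
                assert km.survival_at("all", t) == pytest.approx(s, abs=1e-10)

    def test_empty_group_errors(self):
        surv = pd.DataFrame({"time": [1.0], "event": [1]})
        with pytest.raises(ValueError):
            km_estimate(surv.iloc[:0], pd.Series(dtype=object))


class TestLogRank:
    def test_identical_groups_p_one(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0] * 2, "event": [1, 0, 1] * 2})
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.index)
        res = logrank_test(surv, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # events at 1,2 in group a; 4,5 in group b; censored at 3 (a) and 6 (b)
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                             "event": [1, 1, 0, 1, 1, 0]})
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=surv.index)
        res = logrank_test(surv, groups)
        want = oracles.logrank_chi2_brute([1.0, 2.0, 3.0], [1, 1, 0],
                                          [4.0, 5.0, 6.0], [1, 1, 0])
        assert res.chi_square == pytest.approx(want, abs=1e-10)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            times = rng.integers(1, 10, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            labels = rng.permutation(["a"] * (n // 2) + ["b"] * (n - n // 2))
            surv = pd.DataFrame({"time": times, "event": events})
            groups = pd.Series(labels, index=surv.index)
            a, b = surv[groups == "a"], surv[groups == "b"]
            if a["event"].sum() + b["event"].sum() == 0:
                continue
            want = oracles.logrank_chi2_brute(list(a["time"]), list(a["event"]),
                                              list(b["time"]), list(b["event"]))
            assert logrank_test(surv, groups).chi_square == pytest.approx(want, abs=1e-10)


class TestCorrelateScore:
    def test_perfect_correlations(self, rng):
        s = pd.Series(rng.normal(size=10))
        r, _ = correlate_score_with_readout(s, s)
        assert r == pytest.approx(1.0)
        r, _ = correlate_score_with_readout(s, -s)
        assert r == pytest.approx(-1.0)

    def test_matches_formula(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = correlate_score_with_readout(x, y)
        assert r == pytest.approx(oracles.pearson_brute(list(x), list(y)), abs=1e-12)
        assert 0 <= p <= 1

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            correlate_score_with_readout(np.ones(5), np.arange(5.0))


class TestEndToEnd:
    def test_high_group_worse_survival_under_positive_hazard(self):
        """With a strong positive log-hazard on the signature, the high-score
        group must end follow-up with lower survival in nearly every cohort."""
        worse = 0
        n_seeds = 40
        for seed in range(n_seeds):
            expr, surv, _ = gen_cohort(CohortSimSpec(seed=seed, log_hazard_per_unit_score=2.0))
            res = signature_survival_analysis(expr, surv, list(SIGNATURE_GENES), horizon=None)
            km = res["km"]
            end = max(km.times["high"].max(), km.times["low"].max())
            if km.survival_at("high", end) <= km.survival_at("low", end):
                worse += 1
        assert worse >= 0.95 * n_seeds

    def test_logrank_power_increases_with_effect_size(self):
        powers = []
        for loghr in (0.0, 1.0, 2.5):
            rejections = 0
            for seed in range(30):
                expr, surv, _ = gen_cohort(
                    CohortSimSpec(seed=seed, log_hazard_per_unit_score=loghr)
                )
                res = signature_survival_analysis(expr, surv, list(SIGNATURE_GENES),
                                                  horizon=None)
                rejections += res["logrank"].p_value < 0.05
            powers.append(rejections / 30)
        assert powers[0] < powers[1] < powers[2]

    def test_affine_transform_leaves_groups_and_logrank_unchanged(self, rng):
        expr, surv, _ = gen_cohort(CohortSimSpec(n_samples=60, seed=13))
        genes = list(SIGNATURE_GENES)
        scale = pd.Series(rng.uniform(0.5, 3.0, size=len(expr)), index=expr.index)
        shift = pd.Series(rng.normal(size=len(expr)), index=expr.index)
        transformed = expr.mul(scale, axis=0).add(shift, axis=0)
        r1 = signature_survival_analysis(expr, surv, genes)
        r2 = signature_survival_analysis(transformed, surv, genes)
        assert (r1["groups"] == r2["groups"]).all()
        assert r1["logrank"].chi_square == pytest.approx(r2["logrank"].chi_square, abs=1e-9)
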