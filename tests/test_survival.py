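import numpy as np
import pandas as pd
import pytest

from metaboflux.omics import SampleAnnotation
from metaboflux.survival import (CoxTies, SurvivalData, SurvivalError,
                                 build_predictor, cox_multivariate,
                                 cox_univariate, km_logrank, logrank_test,
                                 loocv_permutation, rank_features,
                                 _loocv_classes, _logrank_many)

from conftest import make_matrix


def simulate_cohort(rng, n=60, p=8, beta=None, feature=0, censor_frac=0.3):
    """Gaussian features and exponential PH survival, optionally planted."""
    X = rng.normal(10, 1, size=(p, n))
    eta = np.zeros(n)
    if beta is not None:
        z = (X[feature] - X[feature].mean()) / X[feature].std(ddof=1)
        eta = beta * z
    times = rng.exponential(50.0 / np.exp(eta))
    event = np.ones(n, dtype=bool)
    if censor_frac > 0:
        cens = rng.exponential(50.0 / censor_frac * (1 - censor_frac), n)
        event = times <= cens
        times = np.minimum(times, cens)
    if not event.any():
        event[0] = True
    m = make_matrix(X, feature_ids=[f"f{i:02d}" for i in range(p)])
    data = SurvivalData(m.sample_ids, np.maximum(times, 1e-3), event)
    return m, data


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        # duplicate records relabeled: the two curves coincide
        t = np.array([3.0, 5.0, 8.0, 3.0, 5.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0], dtype=bool)
        g = np.array(["A"] * 3 + ["B"] * 3)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_four_subject_fixture(self):
        # A: events at 1, 2; B: events at 3, 4.  Risk tables by hand:
        # t=1: O-E = 1 - 2/4, V = (2/4)(2/4)(3/3); t=2: 1 - 1/3, V = 2/9
        # t=3, 4: no subjects left in A, O-E = 0, V = 0
        # sum O-E = 7/6, sum V = 17/36, chi2 = (7/6)^2 / (17/36) = 49/17
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=bool)
        g = np.array(["A", "A", "B", "B"])
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(49 / 17, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(50, 40) + 0.1
        e = rng.random(40) < 0.7
        g = np.where(rng.random(40) < 0.5, "A", "B")
        e[g == "A"] |= ~e[g == "A"].any()
        e[g == "B"] |= ~e[g == "B"].any()
        s1, p1 = logrank_test(t, e, g)
        swapped = np.where(g == "A", "B", "A")
        s2, p2 = logrank_test(t, e, swapped)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        for _ in range(5):
            n = 50
            t = np.round(rng.exponential(40, n)) + 1
            e = rng.random(n) < 0.6
            g = rng.random(n) < 0.5
            if not (e[g].any() and e[~g].any()):
                continue
            stat, p = logrank_test(t, e, np.where(g, "A", "B"))
            ref = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_to_monotone_time_rescaling(self, rng):
        t = rng.exponential(30, 50) + 0.5
        e = rng.random(50) < 0.7
        g = np.where(rng.random(50) < 0.5, "A", "B")
        e[np.argmax(g == "A")] = True
        e[np.argmax(g == "B")] = True
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(np.sqrt(t), e, g)  # strictly monotone map
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_all_censored_group_is_an_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0], dtype=bool)
        g = np.array(["A", "A", "B", "B"])
        with pytest.raises(SurvivalError, match="no events"):
            logrank_test(t, e, g)

    def test_km_curves_and_test(self, rng):
        m, data = simulate_cohort(rng)
        groups = np.where(np.arange(data.n) % 2 == 0, "A", "B")
        curves, stat, p = km_logrank(data, groups)
        assert set(curves) == {"A", "B"}
        for c in curves.values():
            vals = c.iloc[:, 0].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()  # survival non-increasing


class TestCox:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        for _ in range(4):
            n = 70
            t = np.round(rng.exponential(40, n)) + 1
            e = rng.random(n) < 0.7
            x = rng.normal(size=n)
            mine = cox_univariate(x, t, e)
            cph = CoxPHFitter().fit(
                pd.DataFrame({"x": x, "t": t, "e": e.astype(int)}), "t", "e")
            assert mine == pytest.approx(float(cph.params_["x"]), abs=1e-4)

    def test_two_group_exponential_closed_form(self, rng):
        # no censoring: the Cox partial-likelihood estimate agrees with the
        # parametric exponential MLE (log event-rate ratio) up to their
        # O(n^-1/2) estimator difference (~0.007 sd at n = 1e4)
        n = 10_000
        x = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        t = np.where(x == 0, rng.exponential(1.0, n), rng.exponential(0.5, n))
        beta = cox_univariate(x, t, np.ones(n, dtype=bool))
        d1, d2 = n // 2, n // 2
        closed_form = np.log((d2 / t[x == 1].sum()) / (d1 / t[x == 0].sum()))
        assert beta == pytest.approx(closed_form, abs=0.03)
        assert beta == pytest.approx(np.log(2.0), abs=0.08)  # true log-HR

    def test_degenerate_covariate_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(SurvivalError):
            cox_univariate(np.ones(4), t, np.ones(4, dtype=bool))

    def test_ties_structure_reusable(self, rng):
        n = 50
        t = np.round(rng.exponential(20, n)) + 1
        e = rng.random(n) < 0.8
        ties = CoxTies(t, e)
        for _ in range(3):
            x = rng.normal(size=n)
            assert ties.fit(x) == pytest.approx(cox_univariate(x, t, e), abs=1e-12)


class TestRankFeatures:
    def test_planted_feature_ranks_first(self, rng):
        m, data = simulate_cohort(rng, n=200, p=20, beta=-1.5, feature=3)
        ranked = rank_features(m, data)
        assert ranked.iloc[0]["feature"] == "f03"

    def test_duplicated_feature_identical_p_adjacent_ranks(self, rng):
        m, data = simulate_cohort(rng, n=80, p=6)
        dup = make_matrix(np.vstack([m.values, m.values[2]]),
                          feature_ids=m.feature_ids + ["f02_copy"])
        ranked = rank_features(dup, data).set_index("feature")
        assert ranked.loc["f02", "p"] == pytest.approx(
            ranked.loc["f02_copy", "p"], rel=1e-12)
        ranks = list(ranked.index)
        assert abs(ranks.index("f02") - ranks.index("f02_copy")) == 1

    def test_constant_feature_skipped(self, rng):
        m, data = simulate_cohort(rng, n=40, p=4)
        vals = m.values.copy()
        vals[1] = 7.0
        m2 = make_matrix(vals, feature_ids=m.feature_ids)
        ranked = rank_features(m2, data)
        assert "f01" not in set(ranked["feature"])
        assert "f01" in ranked.attrs["skipped"]

    def test_null_type_one_rate_plausible(self, rng):
        # 100 pure-noise features: expect ~5 below 0.05, allow generous slack
        m, data = simulate_cohort(rng, n=200, p=100)
        ranked = rank_features(m, data)
        assert ranked.attrs["n_significant"] <= 15


class TestPredictor:
    def test_protective_feature_gets_negative_weight(self, rng):
        m, data = simulate_cohort(rng, n=150, p=10, beta=-1.5, feature=2)
        pred = build_predictor(m, data, k=1)
        assert pred.features == ["f02"]
        assert pred.weights[0] < 0

    def test_even_n_splits_half_high_risk(self, rng):
        m, data = simulate_cohort(rng, n=80, p=8, beta=-1.0)
        pred = build_predictor(m, data, k=3)
        classes = pred.training_classes
        assert (classes == "high").sum() == 40

    def test_feature_rescaling_invariance(self, rng):
        m, data = simulate_cohort(rng, n=100, p=6, beta=-1.2, feature=1)
        pred = build_predictor(m, data, k=2)
        scaled_vals = m.values.copy()
        row = m.feature_ids.index(pred.features[0])
        # doubling a feature's scale must not change risk classes
        scaled_vals[row] = 2.0 * scaled_vals[row]
        m2 = make_matrix(scaled_vals, feature_ids=m.feature_ids)
        pred2 = build_predictor(m2, data, k=2)
        assert (pred2.training_classes == pred.training_classes).all()

    def test_score_reproducible_from_stored_constants(self, rng, tmp_path):
        import json
        m, data = simulate_cohort(rng, n=60, p=6, beta=-1.0)
        pred = build_predictor(m, data, k=2)
        doc = json.loads(pred.to_json(tmp_path / "p.json"))
        z = (m.subset_features(doc["features"]).values
             - np.array(doc["means"])[:, None]) / np.array(doc["sds"])[:, None]
        scores = np.array(doc["weights"]) @ z
        np.testing.assert_allclose(scores, pred.score(m).to_numpy(), atol=1e-12)

    def test_k_exceeding_features_rejected(self, rng):
        m, data = simulate_cohort(rng, n=40, p=3)
        with pytest.raises(SurvivalError, match="exceeds"):
            build_predictor(m, data, k=10)


class TestLoocvPermutation:
    def test_seed_determinism(self, rng):
        m, data = simulate_cohort(rng, n=30, p=6, beta=-1.5, feature=0)
        out1 = loocv_permutation(m, data, k=2, n_perm=50, seed=11)
        out2 = loocv_permutation(m, data, k=2, n_perm=50, seed=11)
        assert out1[2] == out2[2]
        assert (out1[0] == out2[0]).all()

    def test_permutation_p_bounds(self, rng):
        m, data = simulate_cohort(rng, n=24, p=5)
        _, _, p = loocv_permutation(m, data, k=2, n_perm=40, seed=2)
        assert 1 / 41 <= p <= 1.0

    def test_planted_signal_reaches_significance(self, rng):
        m, data = simulate_cohort(rng, n=100, p=10, beta=-1.8, feature=4)
        _, logrank_p, perm_p = loocv_permutation(m, data, k=2, n_perm=100, seed=5)
        assert perm_p <= 0.05

    def test_selection_leakage_inflates_significance(self, rng):
        # honest CV ranks features inside the loop; the leaky variant ranks
        # once on the full data.  On pure-noise data the leaky statistic
        # must be systematically larger.
        from metaboflux.survival import _fit_predictor_arrays

        def leaky_classes(m, data, k):
            rows, w, means, sds, _ = _fit_predictor_arrays(
                m.values, m.feature_ids, data.time, data.event, k)
            n = m.n_samples
            cls = np.zeros(n, dtype=bool)
            for i in range(n):
                keep = np.arange(n) != i
                ties = CoxTies(data.time[keep], data.event[keep])
                w_cv = np.array([ties.fit(m.values[r, keep]) for r in rows])
                mu = m.values[rows][:, keep].mean(axis=1)
                sd = m.values[rows][:, keep].std(axis=1, ddof=1)
                scores = w_cv @ ((m.values[rows][:, keep] - mu[:, None]) / sd[:, None])
                z_i = (m.values[rows, i] - mu) / sd
                cls[i] = float(w_cv @ z_i) > np.median(scores)
            return cls

        honest_stats, leaky_stats = [], []
        for seed in range(8):
            local = np.random.default_rng(seed)
            m, data = simulate_cohort(local, n=40, p=30)
            honest = _loocv_classes(m.values, m.feature_ids,
                                    data.time, data.event, 3)
            leaky = leaky_classes(m, data, 3)
            for cls, dest in ((honest, honest_stats), (leaky, leaky_stats)):
                if cls.any() and not cls.all():
                    stat, _ = _logrank_many(data.time, data.event, cls[None, :])
                    dest.append(float(stat[0]))
        assert np.mean(leaky_stats) > np.mean(honest_stats)


class TestCoxMultivariate:
    def _cohort(self, rng, n=120, class_effect=-1.0):
        cls = np.where(rng.random(n) < 0.5, "high", "low")
        eta = np.where(cls == "high", 0.0, class_effect)
        t = rng.exponential(40 / np.exp(eta))
        e = rng.random(n) < 0.8
        e[:2] = True
        ids = [f"s{i}" for i in range(n)]
        data = SurvivalData(ids, np.maximum(t, 0.1), e)
        classes = pd.Series(cls, index=ids)
        covars = pd.DataFrame({
            "T": rng.choice(["T1", "T2", "T3"], n),
            "G": rng.choice(["G1", "G2"], n),
        }, index=ids)
        return classes, data, covars

    def test_independent_covariates_recover_class_effect(self, rng):
        classes, data, covars = self._cohort(rng, n=400, class_effect=-1.0)
        summary = cox_multivariate(classes, data, covars)
        assert "risk_class_high" in summary.index
        coef = summary.loc["risk_class_high", "coef"]
        assert coef == pytest.approx(1.0, abs=0.35)  # low group is protective
        assert summary.loc["risk_class_high", "p"] < 0.01

    def test_aliased_covariate_raises_singularity(self, rng):
        classes, data, covars = self._cohort(rng, n=60)
        covars["leak"] = np.where(classes == "high", "yes", "no")
        with pytest.raises(SurvivalError, match="singular"):
            cox_multivariate(classes, data, covars)


class TestSurvivalData:
    def test_positive_times_required(self):
        with pytest.raises(SurvivalError, match="positive"):
            SurvivalData(["a", "b"], [0.0, 2.0], [True, True])

    def test_at_least_one_event(self):
        with pytest.raises(SurvivalError, match="event"):
            SurvivalData(["a", "b"], [1.0, 2.0], [False, False])

    def test_round_trip_through_annotation(self):
        ids = ["a", "b", "c"]
        ann = SampleAnnotation(
            ids, pd.Series(["g1", "g1", "g2"], index=ids),
            survival_time=pd.Series([10.0, 20.0, 30.0], index=ids),
            event=pd.Series([True, False, True], index=ids))
        data = SurvivalData.from_annotation(ann)
        assert data.time.tolist() == [10.0, 20.0, 30.0]
        reordered = data.reorder(["c", "a", "b"])
        assert reordered.time.tolist() == [30.0, 10.0, 20.0]


class TestCoxScoreRanking:
    def test_planted_feature_ranks_first_by_cox(self, rng):
        m, data = simulate_cohort(rng, n=150, p=15, beta=-1.5, feature=6)
        ranked = rank_features(m, data, method="cox")
        assert ranked.iloc[0]["feature"] == "f06"

    def test_cox_wald_p_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        m, data = simulate_cohort(rng, n=80, p=3)
        ranked = rank_features(m, data, method="cox").set_index("feature")
        f = m.feature_ids[0]
        cph = CoxPHFitter().fit(pd.DataFrame({
            "x": m.values[0], "t": data.time, "e": data.event.astype(int)}),
            "t", "e")
        assert ranked.loc[f, "p"] == pytest.approx(
            float(cph.summary.loc["x", "p"]), rel=1e-3)

    def test_unknown_method_rejected(self, rng):
        m, data = simulate_cohort(rng, n=30, p=3)
        with pytest.raises(ValueError, match="ranking method"):
            rank_features(m, data, method="wilcoxon")
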