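import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from deltarad.survival import (ConvergenceError, SeparationError,
                               concordance_index, cox_newton, fit_cox,
                               fuse_scores, km_curve, label_at_horizon, logrank,
                               median_stratify)
from deltarad.synthdata import CohortSpec, cohort_to_frame, make_feature_table, \
    simulate_cohort

from _oracles import oracle_concordance


def _sim(n, betas, seed, censor=0.02, h0=0.05, standardize=True):
    feats = make_feature_table(n, max(len(betas), 1), seed=seed)
    names = list(feats.columns)
    bmap = {names[i]: b for i, b in enumerate(betas)}
    rec = cohort_to_frame(simulate_cohort(
        CohortSpec(n_subjects=n, feature_betas=bmap, baseline_hazard=h0,
                   censor_rate=censor, standardize=standardize, seed=seed + 1),
        feats))
    return feats, rec["os_time"].to_numpy(), rec["os_event"].to_numpy()


class TestCoxFit:
    def test_agrees_with_lifelines_on_tied_data(self):
        rng = np.random.default_rng(2)
        n = 150
        X = rng.standard_normal((n, 3))
        t = np.round(rng.exponential(10 / np.exp(X @ [0.6, -0.4, 0.0])), 0) + 1.0
        e = (rng.random(n) < 0.7).astype(int)
        beta, cov = cox_newton(X, t, e)
        df = pd.DataFrame(X, columns=list("abc"))
        df["T"], df["E"] = t, e
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-3)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)),
                                   cph.standard_errors_.to_numpy(), atol=1e-3)

    def test_binary_covariate_recovers_hazard_ratio_three(self):
        hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            x = (np.arange(n) % 2).astype(float)
            t = rng.exponential(1.0 / (0.05 * 3.0 ** x))
            e = np.ones(n, dtype=int)
            beta, _ = cox_newton(x, t, e)
            hrs.append(np.exp(beta[0]))
        assert 2.4 <= float(np.mean(hrs)) <= 3.75

    def test_null_effect_z_scores_behave(self):
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            x = rng.standard_normal(n)
            t = rng.exponential(10, n)
            e = (rng.random(n) < 0.8).astype(int)
            beta, cov = cox_newton(x, t, e)
            if abs(beta[0] / np.sqrt(cov[0, 0])) < 3:
                inside += 1
        assert inside >= 95

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_newton(np.ones(20), np.arange(20.0) + 1, np.ones(20, dtype=int))

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="events"):
            cox_newton(rng.normal(size=10), np.arange(10.0) + 1,
                       np.zeros(10, dtype=int))

    def test_separation_detected(self):
        # perfectly ordered covariate with no censoring diverges
        n = 40
        x = np.arange(n, dtype=float)
        t = np.arange(n, dtype=float) + 1  # larger x -> longer survival, monotone
        e = np.ones(n, dtype=int)
        with pytest.raises((SeparationError, ConvergenceError)):
            cox_newton(x, t, e)

    def test_fit_cox_records_training_distribution(self):
        feats, t, e = _sim(120, [0.8], seed=3)
        model = fit_cox(feats, t, e)
        scores = model.predict_scores(feats)
        assert model.score_median == pytest.approx(np.median(scores))
        assert model.score_mean == pytest.approx(scores.mean())
        d = model.to_dict()
        restored = type(model).from_dict(d)
        np.testing.assert_allclose(restored.coefficients, model.coefficients)


class TestConcordance:
    def test_perfect_and_constant_scores(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        e = np.ones(4, dtype=int)
        assert concordance_index(t, e, -t) == 1.0
        assert concordance_index(t, e, np.zeros(4)) == 0.5

    def test_matches_pairwise_oracle_with_censoring(self):
        rng = np.random.default_rng(7)
        n = 30
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.6).astype(int)
        s = rng.standard_normal(n)
        assert concordance_index(t, e, s) == oracle_concordance(t, e, s)

    def test_invariant_under_monotone_transform_and_flips_under_negation(self):
        rng = np.random.default_rng(8)
        n = 40
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        s = rng.standard_normal(n)
        c = concordance_index(t, e, s)
        assert concordance_index(t, e, np.exp(s)) == c
        assert concordance_index(t, e, -s) == pytest.approx(1 - c)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 1.0], [0, 0], [0.5, 0.3])


class TestFusion:
    def test_identical_streams_preserve_ranking(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=30)
        fused = fuse_scores(a, a)
        assert (np.argsort(fused) == np.argsort(a)).all()

    def test_self_negated_cancels(self):
        a = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(fuse_scores(a, -a, (2.0, 1.0), (-2.0, 1.0)), 0)

    def test_noise_plus_perfect_lands_between(self):
        feats, t, e = _sim(300, [1.5], seed=11, censor=0.0)
        perfect = feats["f00"].to_numpy()
        rng = np.random.default_rng(12)
        noise = rng.standard_normal(300)
        fused = fuse_scores(perfect, noise)
        c_perfect = concordance_index(t, e, perfect)
        c_noise = concordance_index(t, e, noise)
        c_fused = concordance_index(t, e, fused)
        assert min(c_noise, c_perfect) < c_fused < max(c_noise, c_perfect)

    def test_zero_variance_stream_contributes_nothing(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.full(3, 7.0)
        fused = fuse_scores(a, b)
        np.testing.assert_allclose(fused, (a - a.mean()) / a.std() / 2)


class TestStratification:
    def test_median_boundary_goes_low(self):
        train = np.array([1.0, 2.0, 3.0, 4.0])
        thr = float(np.median(train))
        strat = median_stratify(np.array([2.5]), thr)
        assert strat.group[0] == "low"

    def test_symmetric_scores_split_evenly(self):
        s = np.array([-2.0, -1.0, 1.0, 2.0])
        strat = median_stratify(s, float(np.median(s)))
        assert (strat.group == "high").sum() == 2

    def test_prognostic_model_separates_survival(self):
        feats, t, e = _sim(300, [1.5], seed=13)
        scores = feats["f00"].to_numpy()
        strat = median_stratify(scores, float(np.median(scores)))
        hi = strat.group == "high"
        _, p = logrank(t[hi], e[hi], t[~hi], e[~hi])
        assert p < 0.05


class TestHorizonLabels:
    @pytest.mark.parametrize("time,event,expected", [
        (10.0, 1, "event"),
        (20.0, 0, "no_event"),
        (10.0, 0, "excluded"),
        (12.5, 0, "no_event"),
    ])
    def test_one_year_rule(self, time, event, expected):
        assert label_at_horizon([time], [event], 12)[0] == expected


class TestKmLogrank:
    def test_km_no_censoring_closed_form(self):
        times, surv = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        lookup = dict(zip(times, surv))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_identical_groups_null_logrank(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_power_against_hazard_ratio_two(self):
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(10.0, 200)
            tb = rng.exponential(5.0, 200)
            _, p = logrank(ta, np.ones(200, int), tb, np.ones(200, int))
            if p < 0.05:
                hits += 1
        assert hits / n_sims > 0.8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])
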