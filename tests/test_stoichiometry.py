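"""Deviation score construction and survival stratification."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from aneucomp.stoichiometry import (
    PairModel,
    _logrank_z,
    degradation_correlation,
    deviation_scores,
    fit_pair_models,
    km_survival_at,
    maximally_selected_cutpoint,
    select_top30_pairs,
    survival_stratify,
)


def pair_table(rhos, direction=1, cohort="X"):
    return pd.DataFrame({
        "aneuploid_protein": [f"a{i}" for i in range(len(rhos))],
        "partner": [f"b{i}" for i in range(len(rhos))],
        "cohort": cohort, "rho": rhos, "n_samples": 10, "direction": direction,
    })


class TestTopPairs:
    def test_thirty_largest_by_absolute_rho(self, rng):
        rhos = rng.uniform(-1, 1, 50)
        top = select_top30_pairs(pair_table(rhos), cohort="X")
        want = np.sort(np.abs(rhos))[-30:]
        assert np.allclose(np.sort(top["rho"].abs()), want)

    def test_truncation_flagged(self):
        with pytest.warns(UserWarning, match="only 12"):
            top = select_top30_pairs(pair_table([0.5] * 12), cohort="X")
        assert len(top) == 12

    def test_deletion_pairs_excluded(self):
        table = pd.concat([pair_table([0.9] * 10, direction=1),
                           pair_table([0.95] * 10, direction=-1)])
        top = select_top30_pairs(table, cohort="X")
        assert (top["direction"] == 1).all()

    def test_no_amplification_pairs_error(self):
        with pytest.raises(ValueError):
            select_top30_pairs(pair_table([0.5], direction=-1), cohort="X")


class TestPairModels:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        mat = pd.DataFrame([x, 2 * x + 1], index=["a0", "b0"],
                           columns=[f"s{i}" for i in range(10)])
        (model,) = fit_pair_models(pair_table([0.9])[:1], mat)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 20))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            mat = pd.DataFrame([x, y], index=["a0", "b0"],
                               columns=[f"s{i}" for i in range(n)])
            (model,) = fit_pair_models(pair_table([0.5])[:1], mat)
            xm = np.column_stack([x, np.ones(n)])
            beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
            assert model.slope == pytest.approx(beta[0], abs=1e-10)
            assert model.intercept == pytest.approx(beta[1], abs=1e-10)
            resid = y - (model.slope * x + model.intercept)
            assert abs(resid.sum()) < 1e-8

    def test_constant_predictor_skipped(self):
        mat = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["a0", "b0"],
                           columns=[f"s{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="constant predictor"):
            assert fit_pair_models(pair_table([0.5])[:1], mat) == []


class TestDeviationScores:
    def test_spot_values(self):
        # two models with per-sample residuals (+0.4, -0.2) average to 0.3
        models = [PairModel("a0", "b0", 1.0, 0.0, 4),
                  PairModel("a1", "b1", 1.0, 0.0, 4)]
        mat = pd.DataFrame(
            {
                "s0": [1.0, 1.4, 2.0, 1.8],  # residuals +0.4 and -0.2
                "s1": [1.0, 1.0, 2.0, 2.0],  # all residuals zero
            },
            index=["a0", "b0", "a1", "b1"],
        )
        scores = deviation_scores(models, mat)
        assert scores.loc["s0", "score"] == pytest.approx(0.3)
        assert scores.loc["s1", "score"] == 0.0

    def test_order_invariance_and_zero_model_monotonicity(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 20)),
                           index=[f"p{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(20)])
        models = [PairModel("p0", "p1", 0.5, 0.1, 20),
                  PairModel("p2", "p3", -0.3, 0.0, 20)]
        s1 = deviation_scores(models, mat)
        s2 = deviation_scores(models[::-1], mat)
        pd.testing.assert_frame_equal(s1, s2)
        # adding a model with zero residuals everywhere cannot raise scores
        mat2 = mat.copy()
        mat2.loc["z0"] = 1.0
        mat2.loc["z1"] = 2.0  # z1 = 1*z0 + 1 exactly
        s3 = deviation_scores(models + [PairModel("z0", "z1", 1.0, 1.0, 20)], mat2)
        assert (s3["score"] <= s1["score"] + 1e-12).all()

    def test_sample_coverage_guard(self):
        models = [PairModel("a0", "b0", 1.0, 0.0, 3)]
        mat = pd.DataFrame({"s0": [1.0, 1.5], "s1": [np.nan, 1.0]},
                           index=["a0", "b0"])
        with pytest.warns(UserWarning, match="too few models"):
            scores = deviation_scores(models, mat)
        assert list(scores.index) == ["s0"]

    def test_noisier_samples_score_higher(self, rng):
        n = 200
        x = rng.normal(size=n)
        noise = np.where(np.arange(n) < 100, 0.2, 1.0)  # second half doubled+
        mat = pd.DataFrame(
            [x, 1.5 * x + rng.normal(scale=noise)],
            index=["a0", "b0"], columns=[f"s{i}" for i in range(n)],
        )
        models = fit_pair_models(pair_table([0.9])[:1], mat)
        scores = deviation_scores(models, mat)
        lo = scores["score"].iloc[:100]
        hi = scores["score"].iloc[100:]
        p = stats.mannwhitneyu(hi, lo, alternative="greater").pvalue
        assert p < 0.01


class TestSurvival:
    def _survival(self, scores, hr=3.0, seed=0, endpoint="overall"):
        rng = np.random.default_rng(seed)
        lam = np.log(2) / 36 * hr ** scores
        t_event = rng.exponential(1 / lam)
        censor = rng.uniform(24, 96, len(scores))
        return pd.DataFrame({
            "sample": scores.index,
            "time": np.minimum(t_event, censor),
            "event": (t_event <= censor).astype(int),
            "endpoint": endpoint,
        })

    def test_logrank_z_matches_lifelines(self, rng):
        for _ in range(20):
            n = 80
            t = rng.exponential(30, n)
            e = rng.random(n) < 0.7
            g = rng.random(n) < 0.5
            z = _logrank_z(t, e.astype(float), g)
            ref = logrank_test(t[g], t[~g], event_observed_A=e[g],
                               event_observed_B=e[~g])
            assert z**2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame({
            "score": np.concatenate([rng.normal(0.2, 0.03, 60),
                                     rng.normal(0.8, 0.03, 60)]),
            "n_models": 30,
        }, index=[f"s{i}" for i in range(120)])
        # hazard ratio 3 between the two clusters
        surv = self._survival((scores["score"] > 0.5).astype(float), hr=3.0,
                              seed=1008)
        surv["sample"] = scores.index
        res = survival_stratify(scores, surv)
        # the selected split recovers cluster membership almost exactly
        true_low = set(scores.index[scores["score"] < 0.5])
        agreement = len(true_low & set(res.low_samples)) / len(true_low)
        assert agreement >= 0.9
        assert res.logrank_p < 0.05
        # partition exhaustive, disjoint, cutpoint is an observed score
        assert set(res.low_samples) | set(res.high_samples) == set(scores.index)
        assert not set(res.low_samples) & set(res.high_samples)
        assert res.cutpoint in set(scores["score"].tolist())

    def test_low_group_survives_better_with_planted_hazard(self):
        wins = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(
                {"score": rng.uniform(0, 1, 100), "n_models": 30},
                index=[f"s{i}" for i in range(100)],
            )
            surv = self._survival(scores["score"], hr=3.0, seed=seed + 10_000)
            res = survival_stratify(scores, surv)
            med = float(surv["time"].median())
            wins += km_survival_at(res.curves, "low", med) > km_survival_at(
                res.curves, "high", med)
        assert wins >= 23  # >=90% of seeds

    def test_adjusted_p_controls_size_under_null(self):
        hits = 0
        n_sims = 40
        for seed in range(n_sims):
            rng = np.random.default_rng(seed + 1000)
            scores = pd.DataFrame(
                {"score": rng.uniform(0, 1, 60), "n_models": 30},
                index=[f"s{i}" for i in range(60)],
            )
            surv = self._survival(scores["score"] * 0, hr=1.0, seed=seed)
            surv["sample"] = scores.index
            res = survival_stratify(scores, surv, n_permutations=100, seed=seed)
            hits += res.adjusted_p < 0.05
        rate = hits / n_sims
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_guards(self):
        scores = pd.DataFrame({"score": [0.5] * 30, "n_models": 30},
                              index=[f"s{i}" for i in range(30)])
        surv = self._survival(scores["score"])
        with pytest.raises(ValueError, match="identical"):
            survival_stratify(scores, surv)
        with pytest.raises(ValueError, match="no valid cutpoint"):
            maximally_selected_cutpoint(scores["score"], surv["time"][:30],
                                        surv["event"][:30])


class TestDegradationCorrelation:
    def test_planted_coupling_detected(self, rng):
        n = 120
        dev = rng.uniform(0, 1, n)
        scores = pd.DataFrame({"score": dev, "n_models": 30},
                              index=[f"s{i}" for i in range(n)])
        rows = {f"deg{i}": dev * 1.0 + rng.normal(0, 0.3, n) for i in range(10)}
        rows.update({f"p{i}": rng.normal(size=n) for i in range(100)})
        mat = pd.DataFrame(rows, index=scores.index).T
        rho, p = degradation_correlation(scores, mat, {f"deg{i}" for i in range(10)})
        assert p < 0.05
        assert rho[[f"deg{i}" for i in range(10)]].median() > rho.median()

    def test_random_labels_null(self, rng):
        n = 80
        scores = pd.DataFrame({"score": rng.uniform(0, 1, n), "n_models": 30},
                              index=[f"s{i}" for i in range(n)])
        mat = pd.DataFrame(rng.normal(size=(60, n)),
                           index=[f"p{i}" for i in range(60)],
                           columns=scores.index)
        pvals = []
        for _ in range(100):
            labels = set(rng.choice(mat.index, size=10, replace=False))
            _, p = degradation_correlation(scores, mat, labels)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_set_rejected(self, rng):
        scores = pd.DataFrame({"score": [0.1, 0.5, 0.9], "n_models": 1},
                              index=["s0", "s1", "s2"])
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"], columns=scores.index)
        with pytest.raises(ValueError, match="empty degradation"):
            degradation_correlation(scores, mat, set())
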