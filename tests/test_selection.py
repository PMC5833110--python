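"""Brier scoring, cross-validation, KS marginal test and candidate choice."""

import numpy as np
import pytest

import fertgp as fg
from fertgp.selection import (CandidateResult, ModelSelectionReport,
                              bayes_brier, brier_score, cross_validate,
                              ks_age_marginal, select_model)


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        y = np.array([0, 1, 1, 0], dtype=float)
        assert brier_score(y, y) == 0.0

    def test_coin_flip_scores_quarter(self, rng):
        y = rng.integers(0, 2, 50)
        assert brier_score(np.full(50, 0.5), y) == pytest.approx(0.25)

    def test_arithmetic_example(self):
        assert brier_score([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            brier_score([0.5], [1, 0])

    def test_bounds_property(self, rng):
        p = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        s = brier_score(p, y)
        assert 0.0 <= s <= 1.0

    def test_bayes_brier_of_known_rates(self):
        assert bayes_brier([0.5, 0.1]) == pytest.approx((0.25 + 0.09) / 2)


class TestCrossValidate:
    def test_oracle_beats_constant_predictor(self, default_truth, obs_small):
        """Supplying the truth rates scores a lower Brier than the
        best constant-rate predictor on the same rows."""
        p_true = default_truth.rate(obs_small["age"].to_numpy(),
                                    obs_small["ses"].to_numpy(),
                                    obs_small["year"].to_numpy(dtype=float))
        y = obs_small["y"].to_numpy(dtype=float)
        oracle = brier_score(p_true, y)
        const = brier_score(np.full(len(y), y.mean()), y)
        assert oracle < const

    def test_repeated_call_is_deterministic(self, obs_small, small_config):
        a = cross_validate(obs_small, small_config, folds=3, seed=5)
        b = cross_validate(obs_small, small_config, folds=3, seed=5)
        assert np.array_equal(a.fold_scores, b.fold_scores)
        assert a.mean_score == b.mean_score

    def test_pooled_mean_is_size_weighted(self, obs_small, small_config):
        cv = cross_validate(obs_small, small_config, folds=3, seed=5)
        ok = np.isfinite(cv.fold_scores)
        weighted = np.sum(cv.fold_scores[ok] * cv.fold_sizes[ok]) / np.sum(
            cv.fold_sizes[ok])
        assert cv.mean_score == pytest.approx(weighted, rel=1e-9)

    def test_fitted_model_close_to_bayes_score(self, default_truth,
                                               obs_small, small_config):
        """On correctly specified data the CV Brier sits near the
        irreducible score (within combined noise at this desk scale)."""
        cv = cross_validate(obs_small, small_config, folds=3, seed=5)
        p_true = default_truth.rate(obs_small["age"].to_numpy(),
                                    obs_small["ses"].to_numpy(),
                                    obs_small["year"].to_numpy(dtype=float))
        bayes = bayes_brier(p_true)
        assert abs(cv.mean_score / bayes - 1) < 0.10

    def test_group_by_woman_keeps_women_together(self, obs_small,
                                                 small_config):
        cv = cross_validate(obs_small, small_config, folds=3, seed=5,
                            group_by_woman=True)
        assert np.isfinite(cv.mean_score)


class _StubModel:
    """Duck-typed stand-in exposing alpha_beta for the KS construction."""

    def __init__(self, alpha, beta):
        self._a, self._b = alpha, beta

    def alpha_beta(self, ses, year):
        n = np.broadcast(np.asarray(ses), np.asarray(year)).size
        return np.full(n, self._a), np.full(n, self._b)


class TestKS:
    def test_matched_marginal_accepted(self):
        # data generated from a constant (45, 0.6) surface, compared with a
        # stub model carrying exactly those parameters: the two marginals
        # agree up to sampling noise of ~2.2k birth ages
        truth = fg.GroundTruth(
            alpha_fn=lambda s, y: np.full_like(np.asarray(s, float), 45.0),
            beta_fn=lambda s, y: np.full_like(np.asarray(s, float), 0.6),
            cohort_sizes=100_000, years=(2005,))
        obs = fg.simulate_population(truth, seed=8)
        stub = _StubModel(45.0, 0.6)
        stat, p = ks_age_marginal(stub, obs)
        assert stat < 0.04
        assert p > 0.05

    def test_shifted_marginal_rejected(self, obs_small):
        # peak pushed ~12 years late: marginals must diverge
        stub = _StubModel(65.0, 0.6)
        stat, p = ks_age_marginal(stub, obs_small)
        assert stat > 0.3
        assert p < 1e-6

    def test_no_births_raises(self, obs_small):
        none = obs_small.copy()
        none["y"] = 0
        with pytest.raises(ValueError):
            ks_age_marginal(_StubModel(45.0, 0.6), none)


class TestSelect:
    def test_bonferroni_threshold_arithmetic(self, obs_small):
        cands = [fg.FitConfig(age_quantiles=q, ses_quantiles=4, cv_folds=2,
                              gamma_restarts=1, gp_restarts=3, seed=1)
                 for q in (20, 25, 30, 15, 10, 35)]
        report = select_model(obs_small, cands, level=0.05, seed=1, folds=2)
        assert report.threshold == pytest.approx(0.05 / 6)

    def test_single_acceptable_candidate_chosen(self, obs_small):
        cand = fg.FitConfig(age_quantiles=25, ses_quantiles=4, cv_folds=2,
                            gamma_restarts=1, gp_restarts=3, seed=1)
        report = select_model(obs_small, [cand], level=0.05, seed=1, folds=2)
        assert report.chosen_index == 0
        assert not report.candidates[0].rejected

    def test_chosen_minimises_brier_among_non_rejected(self, obs_small):
        cands = [fg.FitConfig(age_quantiles=q, ses_quantiles=4, cv_folds=2,
                              gamma_restarts=1, gp_restarts=3, seed=1)
                 for q in (15, 30)]
        report = select_model(obs_small, cands, level=0.05, seed=1, folds=2)
        ok = [c for c in report.candidates if not c.rejected]
        if report.chosen is not None and ok:
            assert report.chosen.mean_brier == min(c.mean_brier for c in ok)

    def test_all_rejected_yields_no_choice(self):
        report = ModelSelectionReport(
            candidates=[CandidateResult(
                config=fg.FitConfig(), mean_brier=0.1,
                fold_scores=np.array([0.1]), ks_stat=0.5, ks_p=1e-9,
                rejected=True)],
            threshold=0.05, level=0.05, chosen_index=None)
        assert report.chosen is None
        assert report.to_frame()["rejected"].all()

    def test_empty_candidate_list_raises(self, obs_small):
        with pytest.raises(ValueError):
            select_model(obs_small, [], seed=0)
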