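"""Likelihood, simplex weight optimization, Bayesian post-hoc estimates,
fit diagnostics and covariate screening."""

import math

import numpy as np
import pytest

from csfpk import (
    AssayErrorModel,
    DoseEvent,
    NonparametricPrior,
    Observation,
    OutputError,
    PKParameters,
    SubjectRecord,
    SupportPoint,
    covariate_screen,
    diagnostics,
    observation_sd,
    optimize_weights,
    posterior,
    subject_loglik,
)
from csfpk.estimate import DEFAULT_ERROR_MODEL, loglik_matrix
from csfpk.model import PARAM_NAMES, concentrations


def _scaled_error_model(factor: float) -> AssayErrorModel:
    return AssayErrorModel(
        serum=OutputError(0.25 * factor, 0.05 * factor),
        csf=OutputError(0.1 * factor, 0.05 * factor),
        lam=0.2 * factor,
    )


def _toy_subject(params, times=(2.0, 6.0, 10.0), outputs=("serum", "serum", "csf"),
                 perturb=0.0):
    doses = [DoseEvent(0.0, 2000.0, 4.0), DoseEvent(8.0, 2000.0, 4.0)]
    from csfpk.model import Regimen

    prof = concentrations(params, Regimen(tuple(doses)), np.array(times))
    observations = []
    for t, out in zip(times, outputs):
        idx = list(times).index(t)
        value = (prof.serum_conc if out == "serum" else prof.csf_conc)[idx] + perturb
        observations.append(Observation(time=t, value=max(value, 0.0), output=out))
    return SubjectRecord(id="toy", doses=doses, observations=observations)


class TestObservationSd:
    def test_linear_polynomial_plus_lambda(self):
        em = AssayErrorModel(serum=OutputError(0.25, 0.05),
                             csf=OutputError(0.1, 0.05), lam=0.1)
        assert observation_sd(em, 10.0, "serum") == pytest.approx(0.25 + 0.5 + 0.1)

    def test_intercept_at_zero(self):
        assert observation_sd(DEFAULT_ERROR_MODEL, 0.0, "csf") == pytest.approx(0.3)

    def test_strictly_increasing_in_prediction(self):
        sds = [observation_sd(DEFAULT_ERROR_MODEL, y, "serum") for y in (0, 1, 5, 20)]
        assert all(a < b for a, b in zip(sds, sds[1:]))

    def test_rejects_negative_prediction(self):
        with pytest.raises(ValueError):
            observation_sd(DEFAULT_ERROR_MODEL, -1.0, "serum")


class TestSubjectLoglik:
    def test_perfect_predictions_attain_the_maximum(self, median_params):
        subject = _toy_subject(median_params)
        best = subject_loglik(subject, median_params)
        sds = [
            observation_sd(DEFAULT_ERROR_MODEL, 0.0, o.output) for o in subject.observations
        ]
        # at zero residual the density term vanishes except for normalization
        pred = [o.value for o in subject.observations]
        expected = sum(
            -math.log(math.sqrt(2 * math.pi) * observation_sd(DEFAULT_ERROR_MODEL, p, o.output))
            for p, o in zip(pred, subject.observations)
        )
        assert best == pytest.approx(expected, abs=1e-8)
        del sds
        worse = subject_loglik(_toy_subject(median_params, perturb=0.3), median_params)
        assert worse < best

    def test_matches_direct_summation_oracle(self, median_params):
        subject = _toy_subject(median_params, perturb=0.4)
        from csfpk.model import Regimen

        prof = concentrations(
            median_params, Regimen(tuple(subject.doses)),
            np.array([o.time for o in subject.observations]),
        )
        total = 0.0
        for i, obs in enumerate(subject.observations):
            pred = prof.serum_conc[i] if obs.output == "serum" else prof.csf_conc[i]
            sd = observation_sd(DEFAULT_ERROR_MODEL, obs.value, obs.output)
            total += (
                -0.5 * ((obs.value - pred) / sd) ** 2
                - math.log(sd)
                - 0.5 * math.log(2 * math.pi)
            )
        assert subject_loglik(subject, median_params) == pytest.approx(total, abs=1e-10)

    def test_sd_scaling_shifts_loglik_by_n_log_factor(self, median_params):
        subject = _toy_subject(median_params)  # zero residuals
        base = subject_loglik(subject, median_params, _scaled_error_model(1.0))
        wide = subject_loglik(subject, median_params, _scaled_error_model(10.0))
        assert wide - base == pytest.approx(-3 * math.log(10.0), abs=1e-9)

    def test_rejects_empty_observations(self, median_params):
        empty = SubjectRecord(id="x", doses=[DoseEvent(0, 2000, 4)], observations=[])
        with pytest.raises(ValueError):
            subject_loglik(empty, median_params)

    def test_censored_policy_rewards_low_predictions(self, median_params):
        subject = _toy_subject(median_params)
        blq = SubjectRecord(
            id="b",
            doses=subject.doses,
            observations=[Observation(time=80.0, value=0.0, output="csf", blq=True)],
        )
        ll = subject_loglik(blq, median_params, blq_policy="censored")
        assert ll <= 0.0  # a log-probability
        assert math.isfinite(ll)


class TestOptimizeWeights:
    def test_single_support_point(self):
        w, _ = optimize_weights(np.array([[0.3], [0.8]]))
        assert w == pytest.approx([1.0])

    def test_identical_columns_tie_break_to_equal_split(self):
        lik = np.array([[0.2, 0.2], [0.7, 0.7], [0.1, 0.1]])
        w, _ = optimize_weights(lik)
        assert w == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_dense_simplex_grid_search_on_two_points(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lik = rng.uniform(0.01, 1.0, size=(6, 2))
            w, obj = optimize_weights(lik)
            grid = np.linspace(0.0, 1.0, 200001)
            objs = np.log(np.outer(lik[:, 0], grid) + np.outer(lik[:, 1], 1 - grid)).sum(axis=0)
            assert obj == pytest.approx(objs.max(), abs=1e-6)

    def test_objective_never_below_uniform_start(self):
        rng = np.random.default_rng(11)
        lik = rng.uniform(1e-6, 1.0, size=(15, 40))
        w, obj = optimize_weights(lik)
        uniform = np.log(lik.mean(axis=1)).sum()
        assert obj >= uniform - 1e-12
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= 0)

    def test_em_iterations_are_monotone(self):
        rng = np.random.default_rng(5)
        lik = rng.uniform(1e-4, 1.0, size=(10, 8))
        w = np.full(8, 1.0 / 8)
        prev = np.log(lik @ w).sum()
        for _ in range(50):
            w = w * (lik.T @ (1.0 / (lik @ w))) / lik.shape[0]
            w /= w.sum()
            cur = np.log(lik @ w).sum()
            assert cur >= prev - 1e-10
            prev = cur

    def test_rejects_all_zero_row(self):
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            optimize_weights(np.array([[0.5, 0.2], [0.0, 0.0]]))


class TestPosterior:
    def _prior(self, points_weights):
        box = {k: (1e-4, 1e4) for k in PARAM_NAMES}
        return NonparametricPrior(
            points=tuple(SupportPoint(params=p, weight=w) for p, w in points_weights),
            box=box,
        )

    def test_flat_likelihood_returns_prior(self, median_params):
        subject = _toy_subject(median_params)
        prior = self._prior([(median_params, 0.3), (median_params, 0.7)])
        w, _ = posterior(subject, prior)
        assert w == pytest.approx([0.3, 0.7], abs=1e-12)

    def test_single_point_gets_weight_one(self, median_params):
        subject = _toy_subject(median_params)
        prior = self._prior([(median_params, 1.0)])
        w, med = posterior(subject, prior)
        assert w == pytest.approx([1.0])
        assert med == median_params

    def test_three_point_prior_matches_brute_force_bayes_table(self, median_params, two_point_truth):
        (p1, p2), _ = two_point_truth
        subject = _toy_subject(median_params, perturb=0.2)
        prior = self._prior([(median_params, 0.5), (p1, 0.25), (p2, 0.25)])
        w, _ = posterior(subject, prior)
        liks = np.array(
            [math.exp(subject_loglik(subject, p)) for p in (median_params, p1, p2)]
        )
        expected = np.array([0.5, 0.25, 0.25]) * liks
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_posterior_weights_normalize(self, median_params, two_point_truth):
        (p1, p2), _ = two_point_truth
        subject = _toy_subject(p1, perturb=0.1)
        prior = self._prior([(p1, 0.6), (p2, 0.4)])
        w, med = posterior(subject, prior)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        # the generating point should dominate
        assert w[0] > 0.9
        assert med == p1


class TestDiagnostics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, bias, imp = diagnostics(obs, obs, np.ones(4))
        assert (r2, bias, imp) == (pytest.approx(1.0), 0.0, 0.0)

    def test_symmetric_residuals(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = obs + np.array([1.0, -1.0, 1.0, -1.0]) * 0.5
        r2, bias, imp = diagnostics(obs, pred, np.full(4, 0.5))
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert imp == pytest.approx(1.0)

    def test_four_point_hand_example(self):
        obs = np.array([2.0, 4.0, 6.0, 10.0])
        pred = np.array([1.0, 5.0, 5.0, 9.0])
        sd = np.array([1.0, 2.0, 1.0, 2.0])
        e = (obs - pred) / sd
        r2, bias, imp = diagnostics(obs, pred, sd)
        assert bias == pytest.approx(e.mean())
        assert imp == pytest.approx((e**2).mean() - e.mean() ** 2)
        assert r2 == pytest.approx(np.corrcoef(obs, pred)[0, 1] ** 2)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            diagnostics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestCovariateScreen:
    def _frames(self, params_col, cov_col, n):
        import pandas as pd

        ids = [f"S{i}" for i in range(n)]
        med = pd.DataFrame({"id": ids, "cl": params_col})
        cov = pd.DataFrame({"id": ids, "crcl": cov_col})
        return med, cov

    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(1.0, 30.0, 20)
        med, cov = self._frames(x, np.sqrt(x) + 3.0, 20)
        out = covariate_screen(med, cov)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_independent_covariate_rarely_correlates(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            med, cov = self._frames(rng.normal(size=100), rng.normal(size=100), 100)
            out = covariate_screen(med, cov)
            if abs(out.loc[0, "rho"]) < 0.3:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_constant_covariate_flagged_undefined(self):
        med, cov = self._frames(np.arange(5.0), np.ones(5), 5)
        out = covariate_screen(med, cov)
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "rho"])

    def test_requires_three_subjects(self):
        med, cov = self._frames([1.0, 2.0], [3.0, 4.0], 2)
        with pytest.raises(ValueError):
            covariate_screen(med, cov)


class TestLoglikMatrix:
    def test_matrix_rows_match_scalar_loglik(self, median_params, two_point_truth):
        (p1, p2), _ = two_point_truth
        subjects = [_toy_subject(median_params, perturb=0.1)]
        theta = np.array([p.as_array() for p in (median_params, p1, p2)])
        mat = loglik_matrix(subjects, theta)
        for j, p in enumerate((median_params, p1, p2)):
            assert mat[0, j] == pytest.approx(subject_loglik(subjects[0], p), abs=1e-9)
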