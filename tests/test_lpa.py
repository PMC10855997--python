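"""Latent profile analysis: EM correctness, selection, diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oculopheno import (ProfileModel, bic, blrt, classify, entropy, fit_lpa,
                        lpa_sweep, profile_report, sample_from, select_model)
from oculopheno.lpa import _em, _log_density, _random_init


def _model(posteriors, K=None, d=1):
    P = np.asarray(posteriors, dtype=float)
    K = K or P.shape[1]
    return ProfileModel(weights=np.full(K, 1 / K), means=np.zeros((K, d)),
                        variances=np.ones(d), log_likelihood=0.0,
                        posteriors=P, columns=[f"x{j}" for j in range(d)])


class TestFitting:
    def test_single_profile_matches_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(300, 3))
        m = fit_lpa(X, 1)
        assert np.allclose(m.means[0], X.mean(axis=0))
        mu, var = X.mean(axis=0), X.var(axis=0)
        ll = -0.5 * 300 * (3 * np.log(2 * np.pi) + np.sum(np.log(var))) \
            - 0.5 * np.sum((X - mu) ** 2 / var)
        assert m.log_likelihood == pytest.approx(ll, rel=1e-10)

    def test_two_well_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 1, (250, 2)),
                       rng.normal(3, 1, (250, 2))])
        m = fit_lpa(X, 2, n_starts=40, n_final=8, seed=2)
        means = np.sort(m.means[:, 0])
        assert np.allclose(means, [-3, 3], atol=0.2)
        assert np.allclose(m.weights, 0.5, atol=0.05)
        assert np.allclose(m.variances, 1.0, atol=0.2)

    def test_em_log_likelihood_is_monotone(self):
        """Each EM sweep never decreases the log-likelihood."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-1, 1, (150, 3)),
                       rng.normal(1.5, 1, (150, 3))])
        w, mu, var = _random_init(X, 2, rng)
        lls = []
        for _ in range(40):
            from scipy.special import logsumexp
            lls.append(float(logsumexp(
                _log_density(X, w, mu, var, "shared_diagonal"),
                axis=1).sum()))
            w, mu, var, _, _ = _em(X, w, mu, var, "shared_diagonal", 1, 0.0)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            fit_lpa(X, 1)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            fit_lpa(np.zeros((3, 2)), 4)

    def test_canonical_ordering_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-4, 1, (300, 2)),
                       rng.normal(4, 1, (100, 2))])
        a = fit_lpa(X, 2, n_starts=30, n_final=6, seed=5)
        b = fit_lpa(X, 2, n_starts=30, n_final=6, seed=99)
        # profiles sorted by weight descending, so both runs agree
        assert np.all(np.diff(a.weights) <= 1e-12)
        assert np.allclose(a.means, b.means, atol=0.05)
        assert bic(a) == pytest.approx(bic(b), rel=1e-4)


class TestInformationCriteria:
    def test_bic_closed_form(self):
        m = _model(np.ones((100, 1)))
        m.log_likelihood = -100.0
        m = ProfileModel(weights=np.ones(1), means=np.zeros((1, 4)),
                         variances=np.ones(4), log_likelihood=-100.0,
                         posteriors=np.ones((100, 1)), columns=list("abcd"))
        # n_parameters for K=1, d=4: 4 + 4 + 0 = 8
        assert bic(m) == pytest.approx(200 + 8 * np.log(100))

    def test_parameter_count_shared_diagonal(self):
        m = ProfileModel(weights=np.full(4, 0.25), means=np.zeros((4, 12)),
                         variances=np.ones(12), log_likelihood=0.0,
                         posteriors=np.full((10, 4), 0.25),
                         columns=[str(i) for i in range(12)])
        assert m.n_parameters == 4 * 12 + 12 + 3 == 63

    def test_bic_ordering_governs_selection(self):
        fits = {}
        for k, ll in [(1, -500.0), (2, -400.0), (3, -398.0)]:
            fits[k] = ProfileModel(
                weights=np.full(k, 1 / k), means=np.zeros((k, 2)),
                variances=np.ones(2), log_likelihood=ll,
                posteriors=np.full((200, k), 1 / k),
                columns=["a", "b"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, trace = select_model(fits)
        assert best.K == int(trace.BIC.idxmin())


class TestEntropy:
    def test_degenerate_posteriors_give_one(self):
        P = np.zeros((50, 3))
        P[np.arange(50), np.arange(50) % 3] = 1.0
        assert entropy(_model(P)) == pytest.approx(1.0)

    def test_uniform_posteriors_give_zero(self):
        assert entropy(_model(np.full((40, 4), 0.25))) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        e = entropy(_model([[0.9, 0.1], [0.8, 0.2]]))
        assert e == pytest.approx(0.4045, abs=5e-4)

    def test_single_profile_undefined(self):
        with pytest.raises(ValueError):
            entropy(_model(np.ones((10, 1))))


class TestClassification:
    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 1, (100, 2)),
                       rng.normal(2, 1, (100, 2))])
        m = fit_lpa(X, 2, n_starts=20, n_final=4, seed=1)
        assert np.allclose(m.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_average_assigned_probability_at_least_uniform(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))   # no structure at all
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_lpa(X, 3, n_starts=20, n_final=4, seed=2)
        diag = classify(m)
        avg = diag["avg_class_probability"]
        assert np.all(avg[np.isfinite(avg)] >= 1 / 3 - 1e-9)

    def test_well_separated_profiles_clear_point_nine(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(-3, 1, (200, 4)),
                       rng.normal(3, 1, (80, 4))])
        m = fit_lpa(X, 2, n_starts=30, n_final=6, seed=3)
        diag = classify(m)
        assert np.all(diag["avg_class_probability"] > 0.9)
        assert diag["flagged_profiles"] == []


class TestBLRT:
    def test_pvalue_floor_when_observed_exceeds_all(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-4, 1, (150, 2)),
                       rng.normal(4, 1, (150, 2))])
        res = blrt(X, 2, n_boot=19, seed=1, n_starts=8, n_final=2,
                   burn_in=10)
        assert res["p_value"] == pytest.approx(1 / 20)
        assert res["statistic"] > np.max(res["bootstrap_stats"])

    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            blrt(np.zeros((10, 2)), 2, n_boot=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            blrt(np.zeros((10, 2)), 1, n_boot=10)


class TestSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 2))
        m = fit_lpa(X, 1)
        best, trace = select_model({1: m})
        assert best is m

    def test_boundary_warning_when_bic_still_decreasing(self):
        fits = {}
        for k, ll in [(1, -1000.0), (2, -800.0), (3, -600.0)]:
            fits[k] = ProfileModel(
                weights=np.full(k, 1 / k), means=np.zeros((k, 2)),
                variances=np.ones(2), log_likelihood=ll,
                posteriors=np.full((500, k), 1 / k), columns=["a", "b"])
        with pytest.warns(UserWarning, match="decreasing"):
            best, _ = select_model(fits)
        assert best.K == 3


class TestReport:
    def test_severity_labels_follow_thresholds(self):
        rng = np.random.default_rng(10)
        z = pd.DataFrame({
            "AS_ERROR": np.r_[rng.normal(3.68, 0.05, 30),
                              rng.normal(0.0, 0.05, 30)],
            "RNFL": np.r_[rng.normal(-1.5, 0.05, 30),
                          rng.normal(0.0, 0.05, 30)]})
        m = fit_lpa(z, 2, n_starts=20, n_final=4, seed=4)
        rep = profile_report(m, z)
        rep = rep[rep.indicator != "_demographics"]
        by = {(r.profile, r.indicator): r for r in rep.itertuples()}
        # the impaired profile: severe AS error, impaired RNFL
        imp = rep.loc[(rep.indicator == "AS_ERROR") & (rep.mean_z > 3),
                      "profile"].iloc[0]
        assert by[(imp, "AS_ERROR")].severity == "severe"
        assert by[(imp, "RNFL")].severity == "impaired"
        other = [p for p in rep.profile.unique() if p != imp][0]
        assert by[(other, "AS_ERROR")].severity == "none"
        assert by[(other, "RNFL")].severity == "intact"

    def test_profile_sizes_partition_sample(self):
        rng = np.random.default_rng(11)
        z = pd.DataFrame(np.vstack([rng.normal(-2, 1, (120, 2)),
                                    rng.normal(2, 1, (60, 2))]),
                         columns=["a", "b"])
        m = fit_lpa(z, 2, n_starts=20, n_final=4, seed=5)
        rep = profile_report(m, z)
        sizes = rep.groupby("profile")["n"].first()
        assert sizes.sum() == 180

    def test_sampling_roundtrip_preserves_moments(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(-2, 1, (300, 2)),
                       rng.normal(2, 1, (300, 2))])
        m = fit_lpa(X, 2, n_starts=20, n_final=4, seed=6)
        Y = sample_from(m, 20000, np.random.default_rng(0))
        assert np.allclose(Y.mean(axis=0), X.mean(axis=0), atol=0.1)
        assert np.allclose(Y.var(axis=0), X.var(axis=0), atol=0.2)
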