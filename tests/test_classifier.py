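"""Covariate screening, quadratic discriminant model, majority voting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zcbat.classifier import (
    UNKNOWN,
    FeatureMatrix,
    QdfaModel,
    classify_pulse,
    classify_pulses,
    classify_sequence,
    fit_qdfa,
    log_posteriors,
    screen_features,
)
from zcbat.synthetic import gaussian_feature_library, separated_gaussian_means


def _matrix(X, y, species=("A", "B", "C"), seq_per=1):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X, y=np.asarray(y), seq_ids=np.arange(X.shape[0]) // max(seq_per, 1),
        species=tuple(species[: int(np.max(y)) + 1]),
        features=tuple(f"f{j}" for j in range(X.shape[1])),
    )


class TestScreening:
    def test_duplicate_column_dropped(self, rng):
        a = rng.normal(size=200)
        df = pd.DataFrame({"A": a, "B": a, "C": rng.normal(size=200)})
        kept = screen_features(df)
        assert "C" in kept and len(kept) == 2

    def test_independent_columns_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 5)),
                          columns=list("ABCDE"))
        assert screen_features(df) == list("ABCDE")

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame({"A": rng.normal(size=50), "B": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            screen_features(df)

    def test_matches_exhaustive_search(self, rng):
        # A, B = A + noise (R^2 >= 0.5), C independent: the survivors must
        # match the largest subset with all pairwise R^2 < 0.5
        a = rng.normal(size=400)
        df = pd.DataFrame({
            "A": a, "B": a + 0.2 * rng.normal(size=400),
            "C": rng.normal(size=400),
        })
        kept = set(screen_features(df))
        best = max(
            (s for r in range(1, 4) for s in itertools.combinations(df.columns, r)
             if _all_uncorrelated(df[list(s)])),
            key=len,
        )
        assert len(kept) == len(best)
        assert "C" in kept and kept <= {"A", "B", "C"}
        assert _all_uncorrelated(df[list(kept)])


def _all_uncorrelated(sub, r2_max=0.5):
    r2 = sub.corr() ** 2
    np.fill_diagonal(r2.values, 0)
    return bool((r2 < r2_max).all().all())


class TestFitQdfa:
    def test_posterior_matches_closed_form_1d(self, rng):
        # one feature, two Gaussians: compare to the explicit mixture form
        x0 = rng.normal(0.0, 1.0, 60)[:, None]
        x1 = rng.normal(3.0, 2.0, 60)[:, None]
        fm = _matrix(np.vstack([x0, x1]), np.r_[np.zeros(60), np.ones(60)])
        model = fit_qdfa(fm)
        xs = np.linspace(-3, 8, 25)[:, None]
        _, post = classify_pulses(model, xs)
        m0, s0 = x0.mean(), x0.std(ddof=1)
        m1, s1 = x1.mean(), x1.std(ddof=1)
        d0 = stats.norm.pdf(xs[:, 0], m0, s0)
        d1 = stats.norm.pdf(xs[:, 0], m1, s1)
        expected = d0 / (d0 + d1)
        np.testing.assert_allclose(post[:, 0], expected, atol=1e-9)

    def test_class_below_minimum_size_errors(self, rng):
        X = rng.normal(size=(11, 5))
        y = np.r_[np.zeros(8), np.ones(3)]
        with pytest.raises(ValueError, match="B"):
            fit_qdfa(_matrix(X, y))

    def test_singular_covariance_names_species(self):
        X = np.zeros((12, 2))
        X[:, 0] = np.arange(12)
        X[:, 1] = X[:, 0]  # perfectly collinear within both classes
        y = np.r_[np.zeros(6), np.ones(6)]
        with pytest.raises(ValueError, match="singular|pulses"):
            fit_qdfa(_matrix(X, y))

    def test_equal_spherical_covariances_give_midpoint_boundary(self, rng):
        X0 = rng.normal(-2.0, 1.0, size=(500, 2))
        X1 = rng.normal(+2.0, 1.0, size=(500, 2))
        fm = _matrix(np.vstack([X0, X1]), np.r_[np.zeros(500), np.ones(500)])
        model = fit_qdfa(fm)
        lab, post = classify_pulses(model, np.array([[0.0, 0.0]]))
        # near the midpoint the posteriors are close to even
        assert post[0, 0] == pytest.approx(0.5, abs=0.1)

    def test_json_round_trip(self, rng, tmp_path):
        fm = gaussian_feature_library(separated_gaussian_means(3, 5, 4), 4, 8, rng)
        model = fit_qdfa(fm)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = QdfaModel.from_json(path)
        X = rng.normal(size=(20, 5))
        np.testing.assert_allclose(
            log_posteriors(model, X), log_posteriors(back, X), rtol=1e-12,
        )


class TestClassifyPulse:
    def test_mean_of_separated_class_classified_with_high_posterior(self, rng):
        means = separated_gaussian_means(3, 5, 8)
        fm = gaussian_feature_library(means, 10, 10, rng)
        model = fit_qdfa(fm)
        for k in range(3):
            label, post = classify_pulse(model, means[k])
            assert label == model.species[k]
            assert post[k] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        fm = gaussian_feature_library(separated_gaussian_means(4, 5, 3), 6, 8, rng)
        model = fit_qdfa(fm)
        _, post = classify_pulses(model, rng.normal(size=(200, 5)) * 3)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_equal_cov_decisions_match_linear_discriminant(self, rng):
        # force equal covariances: qDFA must reduce to the linear rule
        means = separated_gaussian_means(3, 4, 3.0)
        cov = np.eye(4) * 1.7
        model = QdfaModel(
            species=("A", "B", "C"), features=("f0", "f1", "f2", "f3"),
            means=means, covs=np.broadcast_to(cov, (3, 4, 4)).copy(),
            priors=np.full(3, 1 / 3),
        )
        X = rng.normal(size=(1000, 4)) * 2.5
        qda_labels, _ = classify_pulses(model, X)
        # independent linear-discriminant oracle
        prec = np.linalg.inv(cov)
        scores = X @ prec @ means.T - 0.5 * np.einsum(
            "kd,dD,kD->k", means, prec, means
        )
        lda_labels = np.argmax(scores, axis=1)
        np.testing.assert_array_equal(qda_labels, lda_labels)

    def test_non_finite_input_rejected(self, rng):
        fm = gaussian_feature_library(separated_gaussian_means(2, 5, 4), 5, 8, rng)
        model = fit_qdfa(fm)
        with pytest.raises(ValueError, match="finite"):
            classify_pulse(model, np.array([np.nan] * 5))

    def test_matches_sklearn_qda(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        fm = gaussian_feature_library(separated_gaussian_means(3, 5, 2.0), 12, 10, rng)
        model = fit_qdfa(fm)
        ref = sklearn.QuadraticDiscriminantAnalysis(
            priors=np.full(3, 1 / 3), store_covariance=True,
        ).fit(fm.X, fm.y)
        X = rng.normal(size=(300, 5)) * 2
        np.testing.assert_allclose(
            classify_pulses(model, X)[1], ref.predict_proba(X), atol=1e-8,
        )


class TestClassifySequence:
    def _model_for_votes(self, rng):
        means = separated_gaussian_means(3, 5, 10)
        fm = gaussian_feature_library(means, 6, 8, rng, species=("A", "B", "C"))
        return fit_qdfa(fm), means

    def test_strict_majority_wins(self, rng):
        model, means = self._model_for_votes(rng)
        X = np.vstack([means[0]] * 3 + [means[1]] + [means[2]])  # A,A,A,B,C
        assert classify_sequence(model, X).label == "A"

    def test_plurality_without_majority_is_unknown(self, rng):
        model, means = self._model_for_votes(rng)
        X = np.vstack([means[0]] * 2 + [means[1]] * 2 + [means[2]])
        assert classify_sequence(model, X).label == UNKNOWN

    def test_unanimous(self, rng):
        model, means = self._model_for_votes(rng)
        assert classify_sequence(model, np.vstack([means[1]] * 5)).label == "B"

    def test_permutation_invariant(self, rng):
        model, means = self._model_for_votes(rng)
        X = np.vstack([means[0]] * 3 + [means[1]] * 2) + rng.normal(size=(5, 5))
        base = classify_sequence(model, X).label
        for _ in range(10):
            perm = rng.permutation(5)
            assert classify_sequence(model, X[perm]).label == base

    def test_replacing_minority_vote_never_flips_majority(self, rng):
        model, means = self._model_for_votes(rng)
        X = np.vstack([means[0]] * 3 + [means[1]] * 2)
        assert classify_sequence(model, X).label == "A"
        X2 = np.vstack([means[0]] * 4 + [means[1]] * 1)
        assert classify_sequence(model, X2).label == "A"
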