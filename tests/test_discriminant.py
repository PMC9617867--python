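"""Gaussian LDA, chance-corrected cross-validation, and unknown classification."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pesmorph.discriminant import (
    build_form, chance_criteria, classify_unknowns, cross_validate,
    evaluate_hit_ratio, fit_lda, posterior_probs, predict, press_q,
    typicality_probs,
)
from pesmorph.errors import ComputationError, ValidationError


def gaussian_clusters(rng, means, n_per, sd=1.0):
    X = np.vstack([rng.normal(m, sd, size=(n_per, len(means[0]))) for m in means])
    y = np.repeat([f"g{i}" for i in range(len(means))], n_per)
    cols = [f"x{j}" for j in range(len(means[0]))]
    return pd.DataFrame(X, columns=cols), y


def bayes_posteriors(model, rows):
    """Brute-force oracle: explicit Gaussian densities with pooled covariance."""
    X = rows[model.means.columns].to_numpy(float)
    cov = model.pooled_cov.to_numpy()
    dens = np.column_stack([
        model.priors[c] * multivariate_normal.pdf(X, mean=model.means.loc[c], cov=cov)
        for c in model.classes
    ])
    return dens / dens.sum(axis=1, keepdims=True)


class TestBuildForm:
    def test_exact_log10(self):
        table = pd.DataFrame({"specimen_id": ["S1"], "A": [10.0], "B": [100.0]})
        form = build_form(table, ["A", "B"])
        np.testing.assert_allclose(form.to_numpy(), [[1.0, 2.0]])

    def test_size_acts_as_translation_along_ones(self):
        table = pd.DataFrame({"A": [4.0], "B": [9.0], "C": [2.5]})
        doubled = table * 2
        d = build_form(doubled, list(table)).to_numpy() - build_form(table, list(table)).to_numpy()
        np.testing.assert_allclose(d, np.log10(2.0), atol=1e-12)

    def test_form_equals_log_gm_plus_shape(self, training_table, measurements):
        from pesmorph.size_shape import shape_matrix, size_profile
        form = build_form(training_table, measurements)
        shape = shape_matrix(training_table)
        gm = size_profile(training_table).per_specimen["gm"].to_numpy()
        recon = np.log10(gm)[:, None] + shape.to_numpy()
        np.testing.assert_allclose(form.to_numpy(), recon, atol=1e-9)


class TestFitLDA:
    def test_two_spherical_groups_axis_is_cov_inverse_mean_diff(self):
        rng = np.random.default_rng(0)
        form, y = gaussian_clusters(rng, [(0, 0, 0), (4, 0, 0)], 200)
        model = fit_lda(form, y)
        oracle = np.linalg.solve(model.pooled_cov.to_numpy(),
                                 (model.means.loc["g1"] - model.means.loc["g0"]).to_numpy())
        a = model.scalings.iloc[:, 0].to_numpy()
        cos = abs(a @ oracle) / (np.linalg.norm(a) * np.linalg.norm(oracle))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_midpoint_between_symmetric_groups_is_fifty_fifty(self):
        rng = np.random.default_rng(1)
        dev = rng.normal(0, 1, size=(50, 3))
        shift = np.array([3.0, -1.0, 2.0])
        form = pd.DataFrame(np.vstack([dev, dev + shift]), columns=list("abc"))
        y = ["g0"] * 50 + ["g1"] * 50
        model = fit_lda(form, y, priors="equal")
        midpoint = pd.DataFrame([(model.means.loc["g0"] + model.means.loc["g1"]) / 2])
        post = posterior_probs(model, midpoint)
        np.testing.assert_allclose(post.to_numpy(), [[0.5, 0.5]], atol=1e-10)

    def test_invariant_to_specimen_order(self):
        rng = np.random.default_rng(2)
        form, y = gaussian_clusters(rng, [(0, 0), (3, 1)], 30)
        perm = rng.permutation(len(y))
        m1 = fit_lda(form, y)
        m2 = fit_lda(form.iloc[perm].reset_index(drop=True), y[perm])
        pd.testing.assert_frame_equal(m1.means, m2.means)
        pd.testing.assert_frame_equal(m1.pooled_cov, m2.pooled_cov)
        np.testing.assert_allclose(m1.scalings, m2.scalings, atol=1e-10)

    def test_single_genus_rejected(self):
        form = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                            columns=["a", "b"])
        with pytest.raises(ValidationError):
            fit_lda(form, ["g0"] * 10)

    def test_singular_covariance_rejected_with_advice(self):
        rng = np.random.default_rng(3)
        form, y = gaussian_clusters(rng, [(0, 0), (3, 0)], 20)
        form["dup"] = form["x0"]  # exactly collinear
        with pytest.raises(ComputationError, match="singular|rank"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_lda(form, y)


class TestPosteriors:
    @pytest.mark.parametrize("priors", ["proportional", "equal"])
    @pytest.mark.parametrize("seed,k,p", [(0, 3, 4), (1, 5, 6), (2, 2, 2)])
    def test_match_bruteforce_gaussian_bayes(self, seed, k, p, priors):
        rng = np.random.default_rng(seed)
        means = rng.normal(0, 2, size=(k, p))
        form, y = gaussian_clusters(rng, means, 25)
        model = fit_lda(form, y, priors=priors)
        query = pd.DataFrame(rng.normal(0, 2, size=(40, p)), columns=form.columns)
        np.testing.assert_allclose(
            posterior_probs(model, query).to_numpy(),
            bayes_posteriors(model, query), atol=1e-8,
        )

    def test_match_sklearn_lda(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(4)
        form, y = gaussian_clusters(rng, [(0, 0, 0), (2, 1, 0), (-1, 2, 1)], 40)
        model = fit_lda(form, y)
        sk = sklearn.LinearDiscriminantAnalysis(solver="svd").fit(form, y)
        np.testing.assert_allclose(
            posterior_probs(model, form).to_numpy(),
            sk.predict_proba(form), atol=1e-8,
        )

    def test_predictions_invariant_under_affine_maps(self):
        rng = np.random.default_rng(5)
        form, y = gaussian_clusters(rng, [(0, 0, 0), (2, 0, 1), (0, 3, -1)], 30)
        model = fit_lda(form, y)
        for _ in range(5):
            A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
            b = rng.normal(size=3)
            mapped = pd.DataFrame(form.to_numpy() @ A.T + b, columns=form.columns)
            m2 = fit_lda(mapped, y)
            np.testing.assert_allclose(
                posterior_probs(model, form).to_numpy(),
                posterior_probs(m2, mapped).to_numpy(), atol=1e-8,
            )


class TestCrossValidation:
    def test_loocv_equals_manual_refits(self):
        rng = np.random.default_rng(6)
        form, y = gaussian_clusters(rng, [(0, 0), (2.5, 1.0)], 18)  # n = 36
        report = cross_validate(form, y, scheme="loocv")
        correct = 0
        for i in range(len(y)):
            keep = [j for j in range(len(y)) if j != i]
            m = fit_lda(form.iloc[keep], y[keep])
            correct += int(predict(m, form.iloc[[i]]).iloc[0] == y[i])
        assert report.hit_ratio == pytest.approx(correct / len(y))
        assert report.confusion.to_numpy().sum() == len(y)
        assert np.trace(report.confusion.to_numpy()[:, :2]) == correct

    def test_widely_separated_genera_perfectly_reclassified(self):
        rng = np.random.default_rng(7)
        form, y = gaussian_clusters(rng, [(0, 0, 0), (10, 0, 0), (0, 10, 0)], 25)
        report = cross_validate(form, y)
        assert report.hit_ratio == 1.0
        assert report.overall_pass

    def test_monte_carlo_scheme_recorded_and_accurate(self):
        rng = np.random.default_rng(8)
        form, y = gaussian_clusters(rng, [(0, 0), (8, 0)], 25)
        report = cross_validate(form, y, scheme="monte_carlo", repetitions=50, seed=3)
        assert report.scheme == "monte_carlo"
        assert report.seed == 3 and report.repetitions == 50
        assert report.hit_ratio > 0.95

    def test_single_genus_rejected(self):
        form = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                            columns=["a", "b"])
        with pytest.raises(ValidationError):
            cross_validate(form, ["only"] * 10)

    def test_confusion_row_sums_are_group_sizes(self, training_table, measurements):
        small = training_table[training_table["genus"].isin(["Bettongia", "Lagostrophus"])]
        form = build_form(small, measurements)
        report = cross_validate(form, small["genus"])
        counts = small["genus"].value_counts()
        for genus in report.confusion.index:
            assert report.confusion.loc[genus].sum() == counts[genus]


class TestChanceCriteria:
    def test_known_compositions(self):
        c = chance_criteria([50, 50])
        assert (c.cmax, c.cpro) == (0.5, 0.5)
        assert (c.cmax_threshold, c.cpro_threshold) == (0.625, 0.625)
        c = chance_criteria([50, 30, 20])
        assert c.cmax == pytest.approx(0.5)
        assert c.cpro == pytest.approx(0.38)
        c = chance_criteria([77])
        assert c.cmax == c.cpro == 1.0

    def test_rejects_empty_or_nonpositive(self):
        with pytest.raises(ValidationError):
            chance_criteria([])
        with pytest.raises(ValidationError):
            chance_criteria([10, 0])


class TestPressQ:
    def test_closed_form_example(self):
        q, sig = press_q(90, 100, 2)
        assert q == pytest.approx(64.0)
        assert sig

    def test_chance_level_gives_zero(self):
        q, sig = press_q(50, 100, 2)
        assert q == 0.0 and not sig

    def test_cutoff_is_chi2_upper_point_one_quantile(self):
        # independent oracle: invert the chi2(1) CDF, F(x) = erf(sqrt(x/2))
        from math import erf, sqrt
        from scipy.optimize import brentq
        cutoff = brentq(lambda x: erf(sqrt(x / 2)) - 0.9, 1e-9, 10)
        assert cutoff == pytest.approx(2.70554, abs=1e-4)
        assert press_q(cutoff_correct(cutoff, 100, 2) + 1, 100, 2)[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            press_q(10, 100, 1)
        with pytest.raises(ValidationError):
            press_q(200, 100, 2)


def cutoff_correct(cutoff, n, k):
    """Smallest integer correct count whose Q exceeds the cutoff."""
    for c in range(n // k, n + 1):
        if (n - c * k) ** 2 / (n * (k - 1)) > cutoff:
            return c
    return n


class TestVerdicts:
    def _report(self, hit, cmax_thr, cpro_thr, q_sig):
        from pesmorph.discriminant import CrossValidationReport
        return CrossValidationReport(
            scheme="loocv", hit_ratio=hit, n_correct=hit * 100,
            confusion=pd.DataFrame(), n=100, k=3, cmax=cmax_thr / 1.25,
            cpro=cpro_thr / 1.25, cmax_threshold=cmax_thr, cpro_threshold=cpro_thr,
            press_q=100.0 if q_sig else 1.0, press_q_significant=q_sig,
        )

    def test_passing_row(self):
        # mirrors a clearly-passing composition: hit 0.90 vs thresholds 0.73/0.50
        v = evaluate_hit_ratio(self._report(0.90, 0.73, 0.50, True))
        assert v["overall_pass"]

    def test_equality_with_threshold_fails(self):
        v = evaluate_hit_ratio(self._report(0.73, 0.73, 0.50, True))
        assert not v["beats_cmax"] and not v["overall_pass"]

    def test_insignificant_q_fails_regardless_of_hit(self):
        v = evaluate_hit_ratio(self._report(0.99, 0.5, 0.4, False))
        assert not v["overall_pass"]


class TestClassifyUnknowns:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(9)
        form, y = gaussian_clusters(rng, [(0, 0, 0), (12, 0, 0), (0, 12, 0)], 40)
        return fit_lda(form, y, priors="equal")

    def test_unknown_at_group_mean_has_posterior_one(self, model):
        row = model.means.loc[["g1"]].reset_index(drop=True)
        result = classify_unknowns(model, row)
        assert result.table.loc[0, "g1"] == pytest.approx(1.0, abs=1e-9)
        assert result.table.loc[0, "predicted_genus"] == "g1"
        assert not result.table.loc[0, "atypical"]

    def test_equidistant_unknown_splits_posterior(self, model):
        mid = pd.DataFrame([(model.means.loc["g0"] + model.means.loc["g1"]) / 2])
        post = posterior_probs(model, mid)
        assert post.loc[0, "g0"] == pytest.approx(post.loc[0, "g1"], abs=1e-9)

    def test_far_unknown_flagged_atypical_but_classified(self, model):
        far = pd.DataFrame([[60.0, 60.0, 60.0]], columns=model.means.columns)
        result = classify_unknowns(model, far, typicality_alpha=0.01)
        assert bool(result.table.loc[0, "atypical"])
        assert result.posteriors.iloc[0].sum() == pytest.approx(1.0, abs=1e-9)
        assert result.table.loc[0, "predicted_genus"] in model.classes
        # chi-square tail oracle: the distance is enormous, typicality ~ 0
        assert typicality_probs(model, far).to_numpy().max() < 1e-10

    def test_incomplete_unknown_skipped_with_warning(self, model):
        rows = pd.DataFrame([[0.0, 0.0, np.nan], [12.0, 0.0, 0.0]],
                            columns=model.means.columns, index=["bad", "good"])
        with pytest.warns(UserWarning, match="bad"):
            result = classify_unknowns(model, rows)
        assert result.skipped == ["bad"]
        assert list(result.table.index) == ["good"]

    def test_posterior_rows_sum_to_one(self, model):
        rng = np.random.default_rng(10)
        rows = pd.DataFrame(rng.normal(0, 5, size=(20, 3)), columns=model.means.columns)
        post = posterior_probs(model, rows)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
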