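"""Mixture-model densities, nesting identities, likelihood and sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from crowdmix.circular import vm_pdf_180, wrap180
from crowdmix.models import (Condition, Model, ModelParams, TrialRecord,
                             log_likelihood, pdf_global_local,
                             pdf_global_perpendicular, pdf_local,
                             pdf_standard, sample_response)

from conftest import random_crowded_trial, random_valid_params


class TestTrialRecord:
    def test_pairing_enforced(self):
        with pytest.raises(ValueError, match="pairs"):
            TrialRecord("o", Condition.FA, 10, flankers=(20, 30, 40, 30),
                        global_ori=5, response=11)

    def test_uncrowded_excludes_flankers(self):
        with pytest.raises(ValueError):
            TrialRecord("o", Condition.U, 10, flankers=(20, 30, 20, 30),
                        global_ori=5, response=11)

    def test_crowded_requires_global(self):
        with pytest.raises(ValueError):
            TrialRecord("o", Condition.FM, 10, flankers=(20, 30, 20, 30),
                        response=11)

    def test_orientations_canonicalized(self):
        t = TrialRecord("o", Condition.FA, 180, flankers=(180, 30, 180, 30),
                        global_ori=180, response=180)
        assert t.target == 0 and t.global_ori == 0 and t.response == 0


class TestModelParams:
    def test_weight_simplex_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(gamma=0.6, sigma=8, beta_loc=0.3, beta_glo=0.2)
        with pytest.raises(ValueError):
            ModelParams(gamma=-0.1, sigma=8)
        with pytest.raises(ValueError):
            ModelParams(gamma=0.1, sigma=0.0)

    def test_p_target(self):
        p = ModelParams(gamma=0.1, sigma=8, beta_loc=0.15, beta_glo=0.05)
        assert p.p_target == pytest.approx(0.7)
        assert ModelParams(gamma=1.0, sigma=8).p_target == 0


class TestStandardPdf:
    def test_pure_guessing_is_uniform(self):
        p = ModelParams(gamma=1.0, sigma=10)
        x = np.linspace(0, 179, 60)
        np.testing.assert_allclose(pdf_standard(x, 90.0, p), 1 / 180)

    def test_no_guessing_at_target(self):
        p = ModelParams(gamma=0.0, sigma=10)
        assert pdf_standard(33.0, 33.0, p) == pytest.approx(vm_pdf_180(0, 10))

    def test_mixture_arithmetic(self):
        p = ModelParams(gamma=0.3, sigma=10)
        expected = 0.7 * vm_pdf_180(15, 10) + 0.3 / 180
        assert pdf_standard(45.0, 30.0, p) == pytest.approx(expected, rel=1e-12)


class TestNesting:
    def test_local_reduces_to_standard(self, crowded_trial):
        p_loc = ModelParams(gamma=0.2, sigma=9, beta_loc=0.0)
        p_std = ModelParams(gamma=0.2, sigma=9)
        x = np.linspace(0, 179, 180)
        np.testing.assert_allclose(pdf_local(x, crowded_trial, p_loc),
                                   pdf_standard(x, crowded_trial.target, p_std),
                                   atol=1e-12)

    def test_global_local_reduces_to_local(self, crowded_trial):
        p_gl = ModelParams(gamma=0.15, sigma=7, beta_loc=0.2, beta_glo=0.0)
        p_loc = ModelParams(gamma=0.15, sigma=7, beta_loc=0.2)
        x = np.linspace(0, 179, 180)
        np.testing.assert_allclose(pdf_global_local(x, crowded_trial, p_gl),
                                   pdf_local(x, crowded_trial, p_loc), atol=1e-12)

    def test_perpendicular_reduces_to_local_without_global(self, crowded_trial):
        p = ModelParams(gamma=0.15, sigma=7, beta_loc=0.2, beta_glo=0.0)
        p_loc = ModelParams(gamma=0.15, sigma=7, beta_loc=0.2)
        x = np.linspace(0, 179, 180)
        np.testing.assert_allclose(pdf_global_perpendicular(x, crowded_trial, p),
                                   pdf_local(x, crowded_trial, p_loc), atol=1e-12)

    def test_flankers_equal_target_collapse_to_standard_shape(self):
        t = TrialRecord("o", Condition.FA, 50, flankers=(50, 50, 50, 50),
                        global_ori=120, response=55)
        p = ModelParams(gamma=0.1, sigma=8, beta_loc=0.3)
        # flanker component sits exactly on the target: weight (1-gamma) total
        p_std = ModelParams(gamma=0.1, sigma=8)
        x = np.linspace(0, 179, 90)
        np.testing.assert_allclose(pdf_local(x, t, p),
                                   pdf_standard(x, 50.0, p_std), atol=1e-12)


class TestFlankerPairing:
    def test_four_item_sum_equals_two_unique_halves(self, rng):
        # m=4 with weight 1/4 over paired flankers == the two unique
        # orientations weighted 1/2 each
        for _ in range(20):
            t = random_crowded_trial(rng)
            p = random_valid_params(rng, Model.LOCAL)
            x = rng.uniform(0, 180, size=16)
            a, b = t.flankers[0], t.flankers[1]
            manual = ((1 - p.gamma - p.beta_loc) * vm_pdf_180(wrap180(x - t.target), p.sigma)
                      + p.gamma / 180
                      + p.beta_loc * (vm_pdf_180(wrap180(x - a), p.sigma)
                                      + vm_pdf_180(wrap180(x - b), p.sigma)) / 2)
            np.testing.assert_allclose(pdf_local(x, t, p), manual, rtol=1e-12)


class TestNormalization:
    def test_all_pdfs_integrate_to_one(self, rng):
        for _ in range(8):
            t = random_crowded_trial(rng)
            for model, pdf in [(Model.STANDARD, None), (Model.LOCAL, pdf_local),
                               (Model.GLOBAL_LOCAL, pdf_global_local),
                               (Model.GLOBAL_PERP, pdf_global_perpendicular)]:
                p = random_valid_params(rng, model)
                if model is Model.STANDARD:
                    f = lambda x: pdf_standard(x, t.target, p)
                else:
                    f = lambda x: pdf(x, t, p)
                total, _ = quad(f, 0, 180, limit=400)
                assert total == pytest.approx(1.0, abs=1e-6)

    def test_saturated_weights_density_independent_of_target(self, crowded_trial):
        p = ModelParams(gamma=0.5, sigma=8, beta_loc=0.3, beta_glo=0.2)
        t2 = TrialRecord("o", Condition.FA, 173.0, flankers=crowded_trial.flankers,
                         global_ori=crowded_trial.global_ori, response=42)
        x = np.linspace(0, 179, 45)
        np.testing.assert_allclose(pdf_global_local(x, crowded_trial, p),
                                   pdf_global_local(x, t2, p), atol=1e-12)


class TestPerpendicular:
    def test_global_component_peaks_at_perpendicular(self, crowded_trial):
        p = ModelParams(gamma=0.0, sigma=5, beta_loc=0.0, beta_glo=1.0)
        perp = (crowded_trial.global_ori + 90) % 180
        x = np.linspace(0, 179.5, 360)
        dens = pdf_global_perpendicular(x, crowded_trial, p)
        assert abs(wrap180(x[np.argmax(dens)] - perp)) < 1.0


class TestLogLikelihood:
    def test_pure_guess_single_trial(self, crowded_trial, rng):
        p = ModelParams(gamma=1.0, sigma=8)
        ll = log_likelihood(Model.STANDARD, p, [crowded_trial])
        assert ll == pytest.approx(math.log(1 / 180))

    def test_additivity_under_duplication(self, rng, gl_params):
        trials = [random_crowded_trial(rng) for _ in range(30)]
        ll1 = log_likelihood(Model.GLOBAL_LOCAL, gl_params, trials)
        ll2 = log_likelihood(Model.GLOBAL_LOCAL, gl_params, trials + trials)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_matches_per_trial_summation_oracle(self, rng, gl_params):
        trials = [random_crowded_trial(rng) for _ in range(100)]
        expected = sum(math.log(pdf_global_local(t.response, t, gl_params))
                       for t in trials)
        assert log_likelihood(Model.GLOBAL_LOCAL, gl_params, trials) == \
            pytest.approx(expected, rel=1e-10)

    def test_crowded_model_rejected_on_uncrowded_trials(self):
        t = TrialRecord("o", Condition.U, 10, response=12)
        with pytest.raises(ValueError):
            log_likelihood(Model.LOCAL, ModelParams(gamma=0.1, sigma=8, beta_loc=0.1), [t])


class TestSampling:
    def test_pure_guessing_uniform_chi2(self, crowded_trial):
        rng = np.random.default_rng(42)
        p = ModelParams(gamma=1.0, sigma=8)
        draws = np.array([sample_response(crowded_trial, Model.STANDARD, p, rng)[0]
                          for _ in range(20_000)])
        counts = np.bincount(draws.astype(int) % 180, minlength=180)
        assert chisquare(counts).pvalue > 0.01

    def test_pure_target_concentrates(self, crowded_trial):
        rng = np.random.default_rng(1)
        p = ModelParams(gamma=0.0, sigma=2.0)
        draws = np.array([sample_response(crowded_trial, Model.STANDARD, p, rng)[0]
                          for _ in range(2000)])
        errs = wrap180(draws - crowded_trial.target)
        assert np.mean(np.abs(errs) < 8) >= 0.99

    def test_histogram_matches_density(self, crowded_trial, gl_params):
        # empirical density of simulated responses vs pdf_global_local,
        # within 3 Monte-Carlo SEs per bin
        rng = np.random.default_rng(9)
        n = 100_000
        draws = np.array([sample_response(crowded_trial, Model.GLOBAL_LOCAL,
                                          gl_params, rng)[0] for _ in range(n)])
        bins = np.arange(0, 181, 4)
        counts, _ = np.histogram(draws, bins=bins)
        centers = (bins[:-1] + bins[1:]) / 2
        # bin probability by fine quadrature of the pdf
        probs = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            xs = np.linspace(lo, hi, 41)
            probs.append(np.trapezoid(pdf_global_local(xs, crowded_trial, gl_params), xs))
        probs = np.array(probs)
        se = np.sqrt(n * probs * (1 - probs))
        assert np.all(np.abs(counts - n * probs) < 3.5 * se + 3)

    def test_component_labels_returned(self, crowded_trial, gl_params):
        rng = np.random.default_rng(5)
        labels = {sample_response(crowded_trial, Model.GLOBAL_LOCAL, gl_params, rng)[1]
                  for _ in range(500)}
        assert labels <= {"target", "guess", "local", "global"}
        assert "target" in labels

    def test_crowded_model_cannot_generate_uncrowded(self):
        t = TrialRecord("o", Condition.U, 10)
        with pytest.raises(ValueError):
            sample_response(t, Model.GLOBAL_LOCAL,
                            ModelParams(gamma=0.1, sigma=8, beta_glo=0.1),
                            np.random.default_rng(0))
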