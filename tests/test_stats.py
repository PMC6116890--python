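"""Contrast codings, mixed-model contract, permutation test, mixture recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from facereloc.stats import (DegenerateDataError, UnidentifiableError,
                             capture_probability, code_contrasts,
                             estimate_sigma, fit_mixed_model,
                             permutation_inference, recover_mixture)


class TestCodeContrasts:
    def test_three_level_sliding_matrix(self):
        m = code_contrasts([2, 3, 4], "sliding").matrix
        expect = np.array([[-2 / 3, -1 / 3],
                           [1 / 3, -1 / 3],
                           [1 / 3, 2 / 3]])
        assert np.allclose(m, expect)

    def test_two_level_codings_coincide(self):
        for kind in ("sliding", "simple"):
            m = code_contrasts(["angry", "happy"], kind).matrix
            assert np.allclose(m.ravel(), [-0.5, 0.5])

    def test_columns_sum_to_zero_and_full_rank(self):
        for k in (2, 3, 4, 6):
            for kind in ("sliding", "simple"):
                scheme = code_contrasts(list(range(k)), kind)
                assert np.allclose(scheme.matrix.sum(axis=0), 0.0)
                assert np.linalg.matrix_rank(scheme.matrix) == k - 1

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError):
            code_contrasts(["a", "a", "b"])

    def test_sliding_coefficients_equal_adjacent_mean_differences(self):
        """Saturated noiseless one-factor model: exact adjacent differences."""
        means = {1: 2.0, 3: 3.5, 6: 3.1}
        scheme = code_contrasts([1, 3, 6], "sliding")
        rows = [(lvl, means[lvl]) for lvl in means for _ in range(5)]
        y = np.array([r[1] for r in rows])
        X = np.column_stack([np.ones(len(rows)),
                             scheme.expand([r[0] for r in rows]).to_numpy()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[1] == pytest.approx(means[3] - means[1])
        assert beta[2] == pytest.approx(means[6] - means[3])

    def test_simple_coefficients_compare_to_reference(self):
        means = {"first": 1.0, "second": 1.8, "third": 0.4}
        scheme = code_contrasts(["first", "second", "third"], "simple")
        rows = [(lvl, means[lvl]) for lvl in means for _ in range(4)]
        y = np.array([r[1] for r in rows])
        X = np.column_stack([np.ones(len(rows)),
                             scheme.expand([r[0] for r in rows]).to_numpy()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[1] == pytest.approx(means["second"] - means["first"])
        assert beta[2] == pytest.approx(means["third"] - means["first"])


def _gaussian_data(n_part, n_trial, effect, seed, sd_participant=0.2,
                   sd_noise=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_part):
        u = rng.normal(0, sd_participant)
        for t in range(n_trial):
            em = "happy" if t % 2 else "angry"
            y = (1.0 + u + effect * (0.5 if em == "happy" else -0.5)
                 + rng.normal(0, sd_noise))
            rows.append({"participant_id": f"p{p}", "trial_id": f"t{t}",
                         "emotion": em, "y": y})
    return pd.DataFrame(rows)


def _binomial_data(n_part, n_trial, beta0, beta_em, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_part):
        for t in range(n_trial):
            em = "happy" if t % 2 else "angry"
            logit = beta0 + beta_em * (0.5 if em == "happy" else -0.5)
            rows.append({"participant_id": f"p{p}", "trial_id": f"t{t}",
                         "emotion": em,
                         "acc": int(rng.random() < 1 / (1 + math.exp(-logit)))})
    return pd.DataFrame(rows)


class TestFitMixedModel:
    def test_gaussian_recovers_known_effect(self):
        df = _gaussian_data(24, 40, effect=0.3, seed=0)
        fit = fit_mixed_model(df, "y", ["emotion"],
                              random={"participant_id": ["1"],
                                      "trial_id": ["1"]})
        b = fit.beta["emotion[happy-angry]"]
        se = fit.se["emotion[happy-angry]"]
        assert abs(b - 0.3) < 3 * se
        assert fit.stat["emotion[happy-angry]"] == pytest.approx(b / se)
        assert fit.converged and fit.family == "gaussian"

    def test_binomial_family_inferred_and_effect_recovered(self):
        df = _binomial_data(24, 64, beta0=1.0, beta_em=0.6, seed=1)
        fit = fit_mixed_model(df, "acc", ["emotion"],
                              random={"participant_id": ["1"]})
        assert fit.family == "binomial"
        b = fit.beta["emotion[happy-angry]"]
        assert abs(b - 0.6) < 3 * fit.se["emotion[happy-angry]"]

    def test_ladder_simplifies_unidentifiable_structure(self):
        """Tiny data with a zero-variance slope cannot support the maximal
        model; the ladder must log steps yet still converge."""
        df = _gaussian_data(3, 4, effect=0.2, seed=5, sd_participant=0.0)
        fit = fit_mixed_model(df, "y", ["emotion"],
                              random={"participant_id": ["1", "emotion"],
                                      "trial_id": ["1"]})
        assert fit.converged
        assert len(fit.simplification_steps) >= 1

    def test_constant_outcome_rejected(self):
        df = _gaussian_data(4, 6, effect=0.0, seed=6)
        df["y"] = 1.0
        with pytest.raises(DegenerateDataError):
            fit_mixed_model(df, "y", ["emotion"])

    def test_standard_errors_shrink_with_sample_size(self):
        """Consistency mechanism: SE of the emotion effect scales ~1/sqrt(n)."""
        ses = []
        for n_part in (12, 48, 192):
            df = _binomial_data(n_part, 32, beta0=1.0, beta_em=0.25, seed=7)
            fit = fit_mixed_model(df, "acc", ["emotion"],
                                  random={"participant_id": ["1"]})
            ses.append(fit.se["emotion[happy-angry]"])
        assert 0.3 < ses[1] / ses[0] < 0.8  # expected 0.5
        assert 0.3 < ses[2] / ses[1] < 0.8

    def test_interaction_term_expansion(self):
        df = _gaussian_data(12, 24, effect=0.3, seed=8)
        df["exited_last"] = (np.arange(len(df)) % 3 == 0).astype(float)
        fit = fit_mixed_model(df, "y", ["emotion", "exited_last",
                                        "emotion:exited_last"],
                              random={"participant_id": ["1"]})
        assert "emotion[happy-angry]:exited_last" in fit.terms


class TestPermutationInference:
    def test_no_effect_gives_p_one(self):
        rows = [{"participant_id": f"p{p}", "emotion": em, "y": 1.0}
                for p in range(8) for em in ("angry", "happy")]
        res = permutation_inference(pd.DataFrame(rows), "y", "emotion",
                                    n_perm=200, rng=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_uniform_shift_attains_minimum_p(self):
        rows = []
        for p in range(48):
            rows.append({"participant_id": f"p{p}", "emotion": "angry",
                         "y": 0.5})
            rows.append({"participant_id": f"p{p}", "emotion": "happy",
                         "y": 0.7})
        res = permutation_inference(pd.DataFrame(rows), "y", "emotion",
                                    n_perm=1000, rng=1)
        assert res.observed == pytest.approx(0.2)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_too_few_participants_rejected(self):
        rows = [{"participant_id": "p0", "emotion": em, "y": 0.1}
                for em in ("angry", "happy")]
        with pytest.raises(DegenerateDataError):
            permutation_inference(pd.DataFrame(rows), "y", "emotion")

    def test_null_p_values_uniform(self):
        """KS check on 500 permutation p-values under the null."""
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(500):
            rows = []
            for p in range(12):
                for t in range(20):
                    rows.append({"participant_id": f"p{p}",
                                 "emotion": "happy" if t % 2 else "angry",
                                 "y": rng.normal()})
            pvals.append(permutation_inference(
                pd.DataFrame(rows), "y", "emotion", n_perm=999,
                rng=rng).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_agreement_with_mixed_model_decisions(self):
        """On balanced data the permutation and model tests should agree on
        reject/retain at alpha = .05 for clear effects and clear nulls."""
        agree = 0
        reps = 0
        for seed in range(8):
            for effect in (0.0, 0.4):
                df = _gaussian_data(16, 40, effect=effect, seed=100 + seed)
                perm = permutation_inference(df, "y", "emotion", n_perm=999,
                                             rng=seed)
                fit = fit_mixed_model(df, "y", ["emotion"],
                                      random={"participant_id": ["1"]})
                p_model = fit.p_value["emotion[happy-angry]"]
                agree += (perm.p_value < 0.05) == (p_model < 0.05)
                reps += 1
        assert agree / reps >= 0.9


class TestRecoverMixture:
    def test_half_capture_sigma(self):
        sigma = 7.0 / math.sqrt(2.0 * math.log(2.0))
        assert capture_probability(sigma) == pytest.approx(0.5)
        assert capture_probability(0.0) == 1.0

    def test_analytic_counts_invert_exactly(self):
        """Forward-map known weights, then recover them."""
        w = np.array([0.7, 0.2, 0.1])
        c = capture_probability(2.0)
        a = math.pi * 49.0 / (42.53 * 26.81)
        q = np.array([
            c * w[0] + a * w[2],
            c * w[1] + 3 * a * w[2],
            (1 - c) * (w[0] + w[1]) + (1 - 4 * a) * w[2],
        ])
        n = 1_000_000
        est = recover_mixture({"correct": int(q[0] * n), "swap": int(q[1] * n),
                               "random": int(q[2] * n)}, sigma_hat=2.0)
        assert est.p_target == pytest.approx(0.7, abs=1e-4)
        assert est.p_swap == pytest.approx(0.2, abs=1e-4)
        assert est.p_uniform == pytest.approx(0.1, abs=1e-4)

    def test_single_face_display_has_no_swap_component(self):
        est = recover_mixture({"correct": 900, "swap": 0, "random": 100},
                              sigma_hat=1.0, n_faces=1)
        assert est.p_swap == 0.0
        assert est.p_target + est.p_uniform == pytest.approx(1.0)

    def test_infinite_noise_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            recover_mixture({"correct": 10, "swap": 5, "random": 5},
                            sigma_hat=1e9)

    def test_estimates_sum_to_one(self):
        est = recover_mixture({"correct": 500, "swap": 300, "random": 200},
                              sigma_hat=3.0)
        assert est.p_target + est.p_swap + est.p_uniform == pytest.approx(1.0)


class TestEstimateSigma:
    def test_recovers_rayleigh_scale(self):
        rng = np.random.default_rng(3)
        d = rng.rayleigh(2.0, 8000)
        d = d[d <= 7.0]
        assert estimate_sigma(d) == pytest.approx(2.0, abs=0.1)

    def test_robust_to_uniform_contamination(self):
        rng = np.random.default_rng(4)
        target = rng.rayleigh(2.0, 7600)
        target = target[target <= 7.0]
        contaminant = 7.0 * np.sqrt(rng.random(400))  # uniform over the disc
        d = np.concatenate([target, contaminant])
        assert estimate_sigma(d) == pytest.approx(2.0, abs=0.1)

    def test_too_few_distances_rejected(self):
        with pytest.raises(DegenerateDataError):
            estimate_sigma([1.0, 2.0])
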