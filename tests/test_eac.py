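"""Segmented field-energy fits, EAC models, correction, and agreement scoring."""

import json

import numpy as np
import pytest

from costark import (
    EACModel,
    K_COUL,
    SegmentedStarkModel,
    agreement_stats,
    correct_energies,
    eac_energy,
    eac_from_fit,
    eac_from_slope,
    segmented_fit,
    slope_ratio,
)
from costark.synthetic import REFERENCE_EAC_CHARGES, reference_eac_models


def _hand_ols(x, y):
    """Closed-form normal equations, independent of the fit path."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def symmetric_fields(n_side=200, fmax=0.03):
    half = np.linspace(fmax / n_side, fmax, n_side)
    return np.concatenate([-half[::-1], half])


class TestSegmentedFit:
    def test_noiseless_two_slope_line(self):
        f = symmetric_fields()
        e = np.where(f > 0, -3.0 * f, 1.0 * f)
        fit = segmented_fit(f, e)
        assert fit.slope_pos == pytest.approx(-3.0, rel=1e-12)
        assert fit.slope_neg == pytest.approx(1.0, rel=1e-12)
        assert fit.r2_pos == pytest.approx(1.0, abs=1e-12)
        assert fit.r2_neg == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_pos == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_ols_oracle_per_side(self):
        f = np.array([-0.5, -0.3, -0.2, -0.15, -0.04, 0.03, 0.1, 0.22, 0.31, 0.45])
        e = np.array([1.2, 0.9, 0.1, 0.6, -0.2, -0.1, -0.9, -0.4, -1.5, -1.1])
        fit = segmented_fit(f, e)
        sp, ip = _hand_ols(list(f[f > 0]), list(e[f > 0]))
        sn, in_ = _hand_ols(list(f[f < 0]), list(e[f < 0]))
        assert fit.slope_pos == pytest.approx(sp, rel=1e-10)
        assert fit.intercept_pos == pytest.approx(ip, rel=1e-10)
        assert fit.slope_neg == pytest.approx(sn, rel=1e-10)
        assert fit.intercept_neg == pytest.approx(in_, rel=1e-10)

    def test_zero_field_samples_excluded_and_counted(self):
        f = np.array([-0.2, -0.1, 0.0, 0.0, 0.1, 0.2])
        e = np.where(f > 0, -f, f)
        fit = segmented_fit(f, e)
        assert fit.n_zero == 2
        assert fit.n_pos == 2 and fit.n_neg == 2

    def test_insufficient_side_names_the_side(self):
        with pytest.raises(ValueError, match="<"):
            segmented_fit([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])

    def test_parameter_recovery_with_noise(self, rng):
        model = EACModel(0.2541, -0.0843)
        n = 10_000
        f = np.abs(rng.normal(0, 0.01, n)) * rng.choice([1.0, -1.0], n)
        e = eac_energy(model, f) + 0.1 * rng.standard_normal(n)
        fit = segmented_fit(f, e)
        for slope, q_true, mask in ((fit.slope_pos, model.q_pos, f > 0),
                                    (fit.slope_neg, model.q_neg, f < 0)):
            x = f[mask]
            se = 0.1 / np.sqrt(np.sum((x - x.mean()) ** 2))
            true_slope = -K_COUL * q_true * model.bond_length
            assert slope == pytest.approx(true_slope, abs=3 * se)


class TestSlopeRatio:
    def test_symmetric_model_ratio_one(self):
        f = symmetric_fields()
        e = eac_energy(EACModel(0.15, -0.15), f)
        assert slope_ratio(segmented_fit(f, e)) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("label,expected", [
        ("HF", 0.83), ("B3LYP", 1.80), ("MP2", 3.02)])
    def test_reference_charge_sets_reproduce_printed_ratios(self, label, expected):
        model = reference_eac_models()[label]
        f = symmetric_fields()
        fit = segmented_fit(f, eac_energy(model, f))
        assert slope_ratio(fit) == pytest.approx(expected, abs=0.01)

    def test_scale_invariance(self):
        f = symmetric_fields()
        e = eac_energy(EACModel(0.2, -0.1), f)
        r1 = slope_ratio(segmented_fit(f, e))
        r2 = slope_ratio(segmented_fit(f, 2.0 * e))
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_consistency_identity(self):
        # for any EAC model, the fitted unsigned slope ratio equals |q_pos|/|q_neg|
        for q_pos, q_neg in [(0.1638, -0.1979), (0.3, -0.05), (0.08, -0.08)]:
            model = EACModel(q_pos, q_neg)
            f = symmetric_fields()
            ratio = slope_ratio(segmented_fit(f, eac_energy(model, f)))
            assert ratio == pytest.approx(abs(q_pos) / abs(q_neg), abs=1e-10)


class TestEACDerivation:
    def test_zero_slope_zero_charge(self):
        assert eac_from_slope(0.0) == 0.0

    def test_roundtrip_slope_to_charge(self):
        for q in (0.2541, -0.0843, 0.5):
            slope = -K_COUL * q * 1.14
            assert eac_from_slope(slope, 1.14) == pytest.approx(q, abs=1e-12)

    def test_sign_pattern_o_positive_under_positive_field(self):
        # stabilizing (negative) positive-branch slope → q_pos > 0 (C⁻O⁺)
        f = symmetric_fields()
        model_true = reference_eac_models()["HF"]
        fit = segmented_fit(f, eac_energy(model_true, f))
        derived = eac_from_fit(fit)
        assert derived.q_pos == pytest.approx(0.1638, abs=1e-10)
        assert derived.q_neg == pytest.approx(-0.1979, abs=1e-10)
        assert derived.q_pos > 0 > derived.q_neg

    def test_eac_energy_closed_form_and_signs(self):
        model = EACModel(0.2541, -0.0843)
        assert eac_energy(model, 0.0) == 0.0
        assert eac_energy(model, 0.01) == pytest.approx(
            -332.0636 * 0.2541 * 0.01 * 1.14, rel=1e-12)
        f = symmetric_fields()
        assert np.all(eac_energy(model, f) <= 0)  # both branches stabilizing


class TestCorrection:
    def test_identity_when_models_equal(self, rng):
        f = rng.normal(0, 0.01, 100)
        e = rng.standard_normal(100)
        model = EACModel(0.2, -0.1)
        np.testing.assert_array_equal(correct_energies(e, f, model, model), e)

    def test_noiseless_cancellation(self):
        f = symmetric_fields()
        low = reference_eac_models()["HF"]
        high = reference_eac_models()["MP2"]
        corrected = correct_energies(eac_energy(low, f), f, low, high)
        np.testing.assert_allclose(corrected, eac_energy(high, f),
                                   rtol=0, atol=1e-12)

    def test_mue_approaches_gaussian_closed_form(self, rng):
        # MUE of corrected-vs-truth → σ·√(2/π) for Gaussian noise
        n, sigma = 10_000, 0.1
        f = rng.normal(0, 0.01, n)
        low, high = reference_eac_models()["HF"], reference_eac_models()["MP2"]
        e_low = eac_energy(low, f) + sigma * rng.standard_normal(n)
        corrected = correct_energies(e_low, f, low, high)
        mue = np.mean(np.abs(corrected - eac_energy(high, f)))
        expected = sigma * np.sqrt(2 / np.pi)
        assert mue == pytest.approx(expected, rel=0.05)

    def test_length_mismatch(self):
        model = EACModel(0.2, -0.1)
        with pytest.raises(ValueError):
            correct_energies([1.0, 2.0], [0.1], model, model)


class TestAgreementStats:
    def test_identical_series(self):
        s = agreement_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r_squared == 1.0 and s.mue == 0.0

    def test_hand_computed_offset_series(self):
        s = agreement_stats([0, 1, 2, 3], [0.5, 1.5, 2.5, 3.5])
        assert s.r_squared == pytest.approx(1.0)
        assert s.mue == pytest.approx(0.5)

    def test_sign_flip_perfect_r2_nonzero_mue(self):
        a = np.array([1.0, 2.0, 3.0])
        s = agreement_stats(a, -a)
        assert s.r_squared == pytest.approx(1.0)
        assert s.mue == pytest.approx(np.mean(2 * a))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestModelResultsWorkflow:
    def test_fit_results_summary_and_json(self, tmp_path, rng):
        model_true = reference_eac_models()["B3LYP"]
        f = np.abs(rng.normal(0, 0.01, 2000)) * rng.choice([1.0, -1.0], 2000)
        e = eac_energy(model_true, f) + 0.1 * rng.standard_normal(2000)
        res = SegmentedStarkModel(f, e, "B3LYP").fit(n_boot=200, seed=7)
        text = res.summary()
        assert "B3LYP" in text and "|k1|/|k2|" in text
        assert res.ratio_ci[0] < res.ratio < res.ratio_ci[1]
        path = tmp_path / "fit.json"
        res.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["slope_ratio"] == pytest.approx(res.ratio)
        assert loaded["n_pos"] + loaded["n_neg"] == 2000

    def test_bootstrap_ci_covers_truth_and_is_seeded(self, rng):
        model_true = EACModel(0.2, -0.1)
        f = np.abs(rng.normal(0, 0.01, 3000)) * rng.choice([1.0, -1.0], 3000)
        e = eac_energy(model_true, f) + 0.05 * rng.standard_normal(3000)
        m = SegmentedStarkModel(f, e)
        r1 = m.fit(n_boot=300, seed=11)
        r2 = m.fit(n_boot=300, seed=11)
        np.testing.assert_array_equal(r1.bootstrap_ratios, r2.bootstrap_ratios)
        assert r1.ratio_ci[0] <= 2.0 <= r1.ratio_ci[1]

    def test_from_dataframe(self):
        import pandas as pd

        f = symmetric_fields(50)
        df = pd.DataFrame({"field": f, "E_EI": eac_energy(EACModel(0.2, -0.1), f)})
        res = SegmentedStarkModel.from_dataframe(df).fit(n_boot=0)
        assert res.ratio == pytest.approx(2.0, abs=1e-10)

    def test_monotone_degradation_in_noise(self):
        low, high = reference_eac_models()["HF"], reference_eac_models()["MP2"]
        r2s = []
        for sigma in (0.0, 0.05, 0.1, 0.2):
            rng = np.random.default_rng(99)  # matched seeds across noise levels
            f = rng.normal(0, 0.01, 4000)
            e_low = eac_energy(low, f) + sigma * rng.standard_normal(4000)
            corrected = correct_energies(e_low, f, low, high)
            r2s.append(agreement_stats(corrected, eac_energy(high, f)).r_squared)
        assert all(a >= b for a, b in zip(r2s, r2s[1:]))
        assert r2s[0] == pytest.approx(1.0, abs=1e-12)
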