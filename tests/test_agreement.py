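"""Bland-Altman limits, evidence scale, Jeffreys correlation, correction."""

import numpy as np
import pingouin as pg
import pytest

from stridepower.bayes_compare import (
    bayesian_correlation,
    bland_altman,
    classify_bf,
    correction_function,
)
from stridepower.grf_pipeline import ValidationError


class TestBlandAltman:
    def test_identity_gives_zero_bias_zero_width(self):
        x = np.linspace(300, 700, 20)
        res = bland_altman(x, x)
        assert res.bias == 0.0 and res.sd == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_constant_offset(self):
        x = np.linspace(300, 700, 20)
        res = bland_altman(x, x - 300.0)
        assert res.bias == pytest.approx(-300.0)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_normal_differences(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(400, 800, 1000)
        dev = ref + rng.normal(-300.0, 50.0, 1000)
        res = bland_altman(ref, dev)
        assert res.bias == pytest.approx(-300.0, abs=5.0)
        assert res.loa_lower == pytest.approx(-398.0, abs=8.0)
        assert res.loa_upper == pytest.approx(-202.0, abs=8.0)
        assert res.loa_lower < res.bias < res.loa_upper

    def test_antisymmetry_under_input_swap(self):
        rng = np.random.default_rng(8)
        a = rng.normal(500, 50, 40)
        b = a + rng.normal(-20, 10, 40)
        fwd, rev = bland_altman(a, b), bland_altman(b, a)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_lower == pytest.approx(-fwd.loa_upper)
        assert rev.loa_upper == pytest.approx(-fwd.loa_lower)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman(np.arange(5.0), np.arange(4.0))


class TestEvidenceScale:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (150.0, "extreme evidence for H1"),
            (100.0, "extreme evidence for H1"),
            (45.0, "very strong evidence for H1"),
            (15.0, "strong evidence for H1"),
            (5.0, "moderate evidence for H1"),
            (2.0, "anecdotal evidence for H1"),
            (1.0, "no evidence"),
            (0.5, "anecdotal evidence for H0"),
            (0.05, "strong evidence for H0"),
            (0.008, "extreme evidence for H0"),
        ],
    )
    def test_jeffreys_scale_boundaries(self, bf, label):
        assert classify_bf(bf) == label

    def test_inverse_symmetry(self):
        for bf in (2.0, 7.0, 20.0, 60.0, 300.0):
            assert classify_bf(bf).replace("H1", "H0") == classify_bf(1.0 / bf)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            classify_bf(0.0)


class TestBayesianCorrelation:
    def test_perfect_correlation_extreme_evidence(self):
        x = np.linspace(0, 1, 50)
        res = bayesian_correlation(x, x)
        assert res.rho_median > 0.9
        assert res.bf10 > 100.0

    def test_independent_normals_favour_null(self):
        rng = np.random.default_rng(9)
        res = bayesian_correlation(rng.normal(size=200), rng.normal(size=200))
        assert res.ci[0] < 0 < res.ci[1]
        assert res.bf10 < 1.0

    def test_strong_correlation_recovered(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=100)
        res = bayesian_correlation(x, y)
        assert res.rho_median == pytest.approx(0.9, abs=0.07)

    @pytest.mark.parametrize("seed,n", [(1, 40), (2, 80), (3, 150)])
    def test_bf_matches_independent_exact_implementation(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        ours = bayesian_correlation(x, y).bf10
        reference = float(pg.corr(x, y)["BF10"].iloc[0])
        assert ours == pytest.approx(reference, rel=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            bayesian_correlation(np.ones(10), np.arange(10.0))


class TestCorrectionFunction:
    def test_identity_devices(self):
        ref = np.linspace(300, 700, 8)
        res = correction_function(ref, ref)
        assert res.a == pytest.approx(1.0) and res.b == pytest.approx(0.0, abs=1e-9)

    def test_exact_inverse_of_affine_bias(self):
        ref = np.linspace(300, 700, 8)
        dev = 0.5 * ref - 10.0
        res = correction_function(ref, dev)
        assert res.a == pytest.approx(2.0)
        assert res.b == pytest.approx(20.0, abs=1e-9)
        assert np.allclose(res.apply(dev), ref)

    def test_constant_device_rejected(self):
        with pytest.raises(ValidationError):
            correction_function(np.linspace(300, 700, 5), np.full(5, 400.0))
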