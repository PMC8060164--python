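"""Gaussian entropies, information decomposition and the flow matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndteflow import (
    EmbeddingSpec,
    TimeSeriesPanel,
    gaussian_entropy,
    info_decomposition,
    ndte_matrix,
    ndte_pair,
)
from ndteflow.ndte import SingularCovarianceError, UndefinedFlowError

LN_2PI_E = np.log(2 * np.pi * np.e)


def linear_channel(rng, n, coef=0.8, noise_var=0.36):
    """y_{t+1} = coef * x_t + eps; x white noise; returns standardized (x, y)."""
    x = rng.standard_normal(n)
    y = np.empty(n)
    y[0] = rng.standard_normal()
    y[1:] = coef * x[:-1] + rng.standard_normal(n - 1) * np.sqrt(noise_var)
    return (x - x.mean()) / x.std(), (y - y.mean()) / y.std()


class TestGaussianEntropy:
    @pytest.mark.parametrize(
        "cov,expected",
        [
            (np.array([[1.0]]), 0.5 * LN_2PI_E),
            (np.eye(2), LN_2PI_E),
            (np.diag([2.0, 3.0]), LN_2PI_E + 0.5 * np.log(6.0)),
        ],
    )
    def test_closed_forms(self, cov, expected):
        assert gaussian_entropy(cov) == pytest.approx(expected, abs=1e-12)

    def test_correlation_reduces_joint_entropy(self):
        cov = np.array([[1.0, 0.99], [0.99, 1.0]])
        assert gaussian_entropy(cov) == pytest.approx(
            LN_2PI_E + 0.5 * np.log(1 - 0.99**2), abs=1e-12
        )
        assert gaussian_entropy(cov) < gaussian_entropy(np.eye(2))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gaussian_entropy(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_singular_covariance_error(self):
        ones = np.ones((3, 3))
        with pytest.raises(SingularCovarianceError):
            with pytest.warns(UserWarning):
                gaussian_entropy(ones - 1.0)  # zero matrix


class TestInfoDecomposition:
    def test_independent_white_noise_near_zero(self, rng):
        x = rng.standard_normal(100_000)
        y = rng.standard_normal(100_000)
        dec = info_decomposition(x, y, EmbeddingSpec(T=10))
        assert abs(dec.i_cond) < 0.01

    def test_linear_channel_analytic_value(self, rng):
        x, y = linear_channel(rng, 100_000)
        dec = info_decomposition(x, y, EmbeddingSpec(T=1))
        assert dec.i_cond == pytest.approx(-0.5 * np.log(0.36), abs=0.01)
        assert abs(dec.i_self) < 0.01
        assert ndte_pair(x, y, EmbeddingSpec(T=1)) > 0.95

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), T=st.integers(1, 6))
    def test_chain_rule_identity(self, seed, T):
        """I(Y+;X,Y) = I(Y+;Y) + I(Y+;X|Y) on arbitrary correlated inputs."""
        rng = np.random.default_rng(seed)
        n = 300
        mix = rng.standard_normal((2, 2))
        z = mix @ rng.standard_normal((2, n))
        dec = info_decomposition(z[0], z[1], EmbeddingSpec(T=T))
        assert abs(dec.i_joint - dec.i_self - dec.i_cond) < 1e-10
        assert dec.i_cond >= -1e-12
        assert dec.i_self >= -1e-12

    def test_affine_invariance_of_mi_terms(self, rng):
        x = rng.standard_normal(2000)
        y = 0.5 * np.roll(x, 1) + rng.standard_normal(2000)
        spec = EmbeddingSpec(T=2)
        d1 = info_decomposition(x, y, spec)
        d2 = info_decomposition(3.0 * x - 1.0, -2.0 * y + 5.0, spec)
        assert d1.i_cond == pytest.approx(d2.i_cond, abs=1e-9)
        assert d1.i_joint == pytest.approx(d2.i_joint, abs=1e-9)

    def test_constant_series_raises(self):
        with pytest.raises((SingularCovarianceError, ValueError)):
            with pytest.warns(UserWarning):
                info_decomposition(np.ones(100), np.ones(100), EmbeddingSpec(T=2))


class TestNdtePair:
    def test_flow_asymmetry_on_directed_coupling(self, rng):
        # the source needs its own memory, otherwise the reverse direction's
        # normalizer I(X+; X, Y) vanishes and the reverse ratio is undefined noise
        n = 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.7 * x[t - 1] + eps[t]
        y = np.empty(n)
        y[0] = 0.0
        y[1:] = 0.8 * x[:-1] + rng.standard_normal(n - 1) * 0.6
        spec = EmbeddingSpec(T=2)
        assert ndte_pair(x, y, spec) > 10 * ndte_pair(y, x, spec)

    def test_independent_of_autocorrelated_target(self, rng):
        y = np.empty(20_000)
        y[0] = rng.standard_normal()
        eps = rng.standard_normal(20_000)
        for t in range(1, 20_000):
            y[t] = 0.7 * y[t - 1] + eps[t]
        x = rng.standard_normal(20_000)
        assert ndte_pair(x, y, EmbeddingSpec(T=5)) < 0.02

    def test_flow_in_unit_interval(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            y = rng.standard_normal(500)
            f = ndte_pair(x, y, EmbeddingSpec(T=3))
            assert 0.0 <= f <= 1.0


class TestNdteMatrix:
    def test_null_panel_small_flows(self):
        # AR(1) regions: each target is self-predictable, so the normalized
        # flow between independent regions is a well-defined near-zero ratio
        from ndteflow.synthfix import make_null_panels

        panel = make_null_panels(1, 3, 10_000, model="ar1", ar_coef=0.5, rng_seed=3)[0]
        flow = ndte_matrix(panel, EmbeddingSpec(T=5))
        off = ~np.eye(3, dtype=bool)
        assert flow.values[off].max() < 0.05
        assert np.all(np.diag(flow.values) == 0)

    def test_directed_pair_dominates(self, rng):
        n = 5000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.7 * x[t - 1] + eps[t]
        y = np.empty(n)
        y[0] = 0.0
        y[1:] = 0.8 * x[:-1] + rng.standard_normal(n - 1) * 0.6
        panel = TimeSeriesPanel(data=np.vstack([x, y]), tr=0.72)
        flow = ndte_matrix(panel, EmbeddingSpec(T=2))
        assert flow.values[1, 0] > 10 * flow.values[0, 1]

    def test_region_permutation_equivariance(self, rng):
        data = rng.standard_normal((4, 1500))
        panel = TimeSeriesPanel(data=data, tr=0.72, region_labels=list("ABCD"))
        perm = [2, 0, 3, 1]
        panel_p = TimeSeriesPanel(
            data=data[perm], tr=0.72, region_labels=[panel.region_labels[i] for i in perm]
        )
        spec = EmbeddingSpec(T=3)
        f = ndte_matrix(panel, spec).values
        fp = ndte_matrix(panel_p, spec).values
        np.testing.assert_allclose(fp, f[np.ix_(perm, perm)], atol=1e-12)

    def test_error_names_offending_pair(self):
        data = np.vstack([np.ones(100) + np.arange(100) * 0, np.random.default_rng(0).standard_normal(100)])
        panel = TimeSeriesPanel(data=data, tr=0.72, region_labels=["const", "noise"])
        with pytest.raises(ValueError):
            ndte_matrix(panel, EmbeddingSpec(T=2))
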