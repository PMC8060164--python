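"""Surrogate testing, Stouffer pooling, FDR correction and group inference."""

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from ndteflow import (
    EmbeddingSpec,
    GroupNDTE,
    SurrogateSpec,
    bh_fdr,
    circular_shift,
    pair_pvalue,
    stouffer_combine,
)
from ndteflow.synthfix import make_null_panels
from tests.conftest import ar1_series


class TestCircularShift:
    def test_forced_example(self):
        out = circular_shift(np.arange(1, 11), 3)
        np.testing.assert_array_equal(out, [4, 5, 6, 7, 8, 9, 10, 1, 2, 3])

    def test_zero_shift_identity(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(circular_shift(x, 0), x)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(n=st.integers(5, 200), frac=st.floats(0, 0.999))
    def test_multiset_preserved(self, n, frac):
        x = np.random.default_rng(n).standard_normal(n)
        shifted = circular_shift(x, int(frac * n))
        np.testing.assert_array_equal(np.sort(shifted), np.sort(x))

    def test_acf_preserved_up_to_boundary(self, rng):
        x = ar1_series(rng, 5000, 0.6)
        shifted = circular_shift(x, 1234)
        for lag in (1, 2, 5):
            r0 = np.corrcoef(x[:-lag], x[lag:])[0, 1]
            r1 = np.corrcoef(shifted[:-lag], shifted[lag:])[0, 1]
            assert abs(r0 - r1) < 0.05

    def test_out_of_range_shift(self):
        with pytest.raises(IndexError):
            circular_shift(np.arange(5), 5)


class TestPairPvalue:
    def test_strong_coupling_hits_floor(self, rng):
        n = 2000
        x = ar1_series(rng, n, 0.5)
        y = np.empty(n)
        y[0] = 0.0
        y[1:] = 0.9 * x[:-1] + rng.standard_normal(n - 1) * 0.3
        y = (y - y.mean()) / y.std()
        p = pair_pvalue(x, y, EmbeddingSpec(T=3), SurrogateSpec(rng_seed=1))
        assert p < 1e-4

    def test_seeded_determinism(self, rng):
        x = ar1_series(rng, 800, 0.5)
        y = ar1_series(rng, 800, 0.5)
        spec, surr = EmbeddingSpec(T=3), SurrogateSpec(n_surrogates=30, rng_seed=9)
        assert pair_pvalue(x, y, spec, surr) == pair_pvalue(x, y, spec, surr)

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the surrogate test on independent AR(1) pairs."""
        streams = np.random.SeedSequence(77).spawn(200)
        rejected = 0
        for ss in streams:
            r = np.random.default_rng(ss)
            x = ar1_series(r, 600, 0.5)
            y = ar1_series(r, 600, 0.5)
            p = pair_pvalue(
                x, y, EmbeddingSpec(T=5), SurrogateSpec(n_surrogates=60, rng_seed=int(ss.generate_state(1)[0] % 2**31))
            )
            rejected += p < 0.05
        # binomial 99% interval around 0.05 for 200 trials
        assert 0.01 <= rejected / 200 <= 0.10


class TestStouffer:
    def test_all_half_gives_half(self):
        s, p = stouffer_combine(np.full(4, 0.5))
        assert s == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_worked_example_against_normal_oracle(self):
        pvals = np.array([0.02, 0.03, 0.04, 0.05])
        s, p = stouffer_combine(pvals)
        expected_s = sum(stats.norm.ppf(v) for v in pvals)
        assert s == pytest.approx(expected_s, abs=1e-10)
        assert p == pytest.approx(stats.norm.cdf(expected_s / 2.0), abs=1e-12)
        assert p < 1e-3

    def test_monotone_in_extreme_p(self):
        base = [0.5] * 5
        group_ps = [stouffer_combine(np.array(base + [tail]))[1] for tail in (1e-2, 1e-4, 1e-6)]
        assert group_ps[0] > group_ps[1] > group_ps[2]

    def test_null_calibration_normal(self):
        """S/sqrt(m) over simulated null subject p-values is standard normal."""
        rng = np.random.default_rng(5)
        m = 8
        z = np.array([stouffer_combine(rng.uniform(size=m))[0] / np.sqrt(m) for _ in range(5000)])
        _, p = stats.kstest(z, "norm")
        assert p > 0.01


class TestBhFdr:
    def test_step_up_worked_example(self):
        # 6 off-diagonal tests; step-up thresholds i*q/6 reject exactly the
        # first three sorted p-values (0.04 > 4*0.05/6 breaks the chain)
        p = np.ones((3, 3))
        vals = [0.001, 0.012, 0.02, 0.04, 0.2, 1.0]
        off = np.argwhere(~np.eye(3, dtype=bool))
        for (i, j), v in zip(off, vals):
            p[i, j] = v
        mask = bh_fdr(p, q=0.05)
        rejected = {tuple(ij) for ij in off[:3]}
        for i, j in off:
            assert mask[i, j] == (1 if (i, j) in rejected else 0)

    def test_all_ones_empty_mask(self):
        p = np.ones((4, 4))
        assert bh_fdr(p, 0.05).sum() == 0

    def test_monotone_in_q(self, rng):
        p = np.ones((6, 6))
        off = ~np.eye(6, dtype=bool)
        p[off] = rng.uniform(size=30)
        m1 = bh_fdr(p, 0.01)
        m5 = bh_fdr(p, 0.05)
        assert np.all(m5 >= m1)


class TestGroupNDTE:
    def test_null_group_mask_mostly_empty(self):
        panels = make_null_panels(6, 3, 400, model="ar1", ar_coef=0.5, rng_seed=11)
        est = GroupNDTE(T=3, n_surrogates=40, q=0.05, seed=4).fit(panels)
        off = ~np.eye(3, dtype=bool)
        assert est.significance_.mask[off].mean() <= 0.05 + 1e-9
        # masked mean is zero wherever the mask is zero
        assert np.all(est.flow_matrix_.values[est.significance_.mask == 0] == 0)

    def test_directed_system_recovered(self, rng):
        panels = []
        for s in range(8):
            n = 1200
            x = ar1_series(rng, n, 0.6)
            y = np.empty(n)
            y[0] = 0.0
            y[1:] = 0.7 * x[:-1] + rng.standard_normal(n - 1) * 0.5
            panels.append(
                __import__("ndteflow").TimeSeriesPanel(
                    data=np.vstack([x, y]), tr=0.72, subject_id=f"s{s}"
                )
            )
        est = GroupNDTE(T=3, n_surrogates=50, q=0.05, seed=1).fit(panels)
        mask = est.significance_.mask
        assert mask[1, 0] == 1  # true direction x -> y
        assert mask[0, 1] == 0  # reverse not significant

    def test_subject_order_invariance_of_mean(self):
        panels = make_null_panels(4, 3, 300, model="ar1", rng_seed=2)
        a = GroupNDTE(T=2, n_surrogates=10, seed=0, mask_mean=False).fit(panels)
        b = GroupNDTE(T=2, n_surrogates=10, seed=0, mask_mean=False).fit(panels[::-1])
        np.testing.assert_allclose(a.raw_mean_, b.raw_mean_, atol=1e-12)

    def test_mismatched_regions_rejected(self):
        panels = make_null_panels(2, 3, 300, rng_seed=0, model="ar1")
        panels[1].region_labels = ["X", "Y", "Z"]
        with pytest.raises(ValueError, match="regions"):
            GroupNDTE(T=2, n_surrogates=5).fit(panels)

    def test_master_seed_determinism(self):
        panels = make_null_panels(3, 3, 300, model="ar1", rng_seed=8)
        a = GroupNDTE(T=2, n_surrogates=15, seed=3).fit(panels)
        b = GroupNDTE(T=2, n_surrogates=15, seed=3).fit(panels)
        np.testing.assert_array_equal(
            a.significance_.subject_pvalues, b.significance_.subject_pvalues
        )
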