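"""Curve-comparison statistics: cosSim, NDI, band tests, band partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dogcsf import (
    CSFCurve,
    DEFAULT_BANDS,
    band_significance,
    band_slice,
    compare_curves,
    cosine_similarity,
    ndi,
)
from dogcsf.stats import UndefinedStatisticError


def curve(freqs, s):
    return CSFCurve(frequencies_cpd=np.asarray(freqs, float),
                    sensitivities=np.asarray(s, float))


class TestCosineSimilarity:
    def test_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        c, th = cosine_similarity(v, v)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert th == pytest.approx(0.0, abs=1e-5)

    def test_scale_invariance(self):
        v = np.array([0.3, 0.7, 0.1])
        c, th = cosine_similarity(2.0 * v, v)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert th == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_vectors(self):
        c, th = cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert c == 0.0
        assert th == pytest.approx(90.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cosine_similarity(np.zeros(3), np.ones(3))

    @settings(derandomize=True, max_examples=40)
    @given(
        v=hnp.arrays(float, 6, elements=st.floats(0.01, 10)),
        a=st.floats(0.01, 100),
    )
    def test_positive_scaling_invariance_property(self, v, a):
        c1, _ = cosine_similarity(v, np.ones(6))
        c2, _ = cosine_similarity(a * v, np.ones(6))
        assert c2 == pytest.approx(c1, abs=1e-12)


class TestNdi:
    def test_equal_norms_zero(self):
        assert ndi([3.0, 4.0], [4.0, 3.0]) == pytest.approx(0.0, abs=1e-15)

    def test_three_to_one(self):
        assert ndi([3.0, 0.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_zero_vs_nonzero_lower_extreme(self):
        assert ndi([0.0, 0.0], [1.0, 1.0]) == -1.0

    def test_both_zero_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ndi([0.0], [0.0])

    @settings(derandomize=True, max_examples=40)
    @given(
        u=hnp.arrays(float, 5, elements=st.floats(0, 5)),
        v=hnp.arrays(float, 5, elements=st.floats(0.1, 5)),
    )
    def test_antisymmetry_and_range(self, u, v):
        x = ndi(u, v)
        assert x == pytest.approx(-ndi(v, u), abs=1e-12)
        assert -1.0 <= x <= 1.0


class TestBandSignificance:
    def test_identical_curves(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = band_significance(v, v)
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_zero_variance(self):
        v = np.zeros(5)
        t, p = band_significance(v + 0.3, v)
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_shift_with_jitter_significant(self):
        """Clear positive shift with small jitter: matches the textbook
        paired-t computed directly from the differences."""
        rng = np.random.default_rng(3)
        base = np.linspace(1, 2, 30)
        d = 0.5 + rng.normal(0, 0.01, 30)
        t, p = band_significance(base + d, base)
        n = d.size
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert t == pytest.approx(t_direct, rel=1e-10)
        assert p < 0.05

    def test_sign_flip_negates_t(self):
        rng = np.random.default_rng(4)
        base = np.ones(20)
        d = rng.normal(0.2, 0.05, 20)
        t1, p1 = band_significance(base + d, base)
        t2, p2 = band_significance(base - d, base)
        assert t2 == pytest.approx(-t1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_too_short_band(self):
        with pytest.raises(UndefinedStatisticError):
            band_significance([1.0, 2.0], [1.0, 2.0])


class TestBands:
    def test_partition_covers_analysis_range(self, base_curve):
        freqs = base_curve.frequencies_cpd
        in_range = (freqs >= 0.1) & (freqs <= 25.0)
        counts = sum(b.mask(freqs).sum() for b in DEFAULT_BANDS)
        assert counts == in_range.sum()
        # disjoint
        m = np.zeros_like(freqs, dtype=int)
        for b in DEFAULT_BANDS:
            m += b.mask(freqs)
        assert m.max() <= 1

    def test_band_slice_membership(self, base_curve):
        low = band_slice(base_curve, DEFAULT_BANDS.low)
        freqs = base_curve.frequencies_cpd
        assert low.size == ((freqs >= 0.1) & (freqs < 4.0)).sum()

    def test_high_band_closed_at_25(self):
        freqs = np.array([9.0, 10.0, 24.0, 25.0, 26.0, 30.0])
        m = DEFAULT_BANDS.high.mask(freqs)
        np.testing.assert_array_equal(m, [False, True, True, True, False, False])

    def test_empty_band_rejected(self):
        c = curve([50.0, 60.0, 70.0], [1.0, 1.0, 1.0])
        with pytest.raises(UndefinedStatisticError):
            band_slice(c, DEFAULT_BANDS.low)


class TestCompareCurves:
    def test_self_comparison_identity(self, base_curve):
        r = compare_curves(base_curve, base_curve)
        for bc in list(r.bands.values()) + [r.overall]:
            assert bc.ndi == 0.0
            assert bc.theta_deg == pytest.approx(0.0, abs=1e-5)
            assert bc.outcome == "unchanged"
        assert r.peak_shift_steps == 0
        assert r.peak_shift_relative == 0.0

    def test_uniform_scaling_increases_all_bands(self, base_curve):
        scaled = CSFCurve(
            frequencies_cpd=base_curve.frequencies_cpd,
            sensitivities=1.5 * base_curve.sensitivities,
        )
        r = compare_curves(scaled, base_curve)
        for bc in r.bands.values():
            assert bc.outcome == "increased"
            assert bc.cos_sim == pytest.approx(1.0, abs=1e-12)
            assert bc.ndi == pytest.approx(0.2)  # (1.5-1)/(1.5+1)

    def test_grid_mismatch_names_first_difference(self, base_curve):
        other = CSFCurve(
            frequencies_cpd=base_curve.frequencies_cpd * 1.001,
            sensitivities=base_curve.sensitivities,
        )
        with pytest.raises(UndefinedStatisticError, match="index 0"):
            compare_curves(other, base_curve)

    def test_length_mismatch(self, base_curve):
        short = CSFCurve(
            frequencies_cpd=base_curve.frequencies_cpd[:-1],
            sensitivities=base_curve.sensitivities[:-1],
        )
        with pytest.raises(UndefinedStatisticError, match="lengths"):
            compare_curves(short, base_curve)
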