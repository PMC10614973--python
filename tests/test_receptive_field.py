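"""Gaussian subfield kernels and stimulus convolution."""

import numpy as np
import pytest

from dogcsf import (
    RFParams,
    Stimulus,
    UnderResolutionError,
    convolve_input,
    dog_profile,
    generate_grating,
    make_grid,
    make_kernel,
)
from dogcsf.receptive_field import PAIR_GAIN


class TestMakeKernel:
    def test_center_weight_is_amplitude(self):
        k = make_kernel(amplitude=0.7, sigma_units=1.0)
        center = k.n_taps // 2
        assert k.weights[center] == 0.7
        assert k.offsets_deg[center] == 0.0
        assert k.weights.max() == 0.7

    def test_weight_at_one_sigma(self):
        # sigma = 0.05 deg is an exact lattice multiple of the 0.0025 spacing
        k = make_kernel(amplitude=1.0, sigma_units=1.0)
        center = k.n_taps // 2
        i = center + round(0.05 / k.spacing_deg)
        assert k.weights[i] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_tap_count_five_sigma_support(self):
        # lattice points in [-0.25, 0.25] at 0.0025 deg spacing: 2*100 + 1
        k = make_kernel(1.0, 1.0, deg_per_unit=0.05, spacing_deg=0.0025)
        assert k.n_taps == 201
        assert np.abs(k.offsets_deg).max() <= 5 * 0.05 + 1e-12

    def test_symmetry(self):
        k = make_kernel(1.3, 1.6)
        np.testing.assert_allclose(k.weights, k.weights[::-1], rtol=1e-12)

    def test_under_resolution_error(self):
        with pytest.raises(UnderResolutionError):
            make_kernel(1.0, 1.0, deg_per_unit=0.001, spacing_deg=0.0025)

    @pytest.mark.parametrize("kw", [dict(amplitude=0), dict(sigma_units=-1),
                                    dict(deg_per_unit=np.nan)])
    def test_invalid_arguments(self, kw):
        args = dict(amplitude=1.0, sigma_units=1.0)
        args.update(kw)
        with pytest.raises(ValueError):
            make_kernel(**args)


class TestDogProfile:
    def test_base_center_difference_is_zero(self):
        prof = dog_profile(RFParams())
        assert prof.weights[prof.n_taps // 2] == 0.0

    def test_center_equals_amplitude_difference(self):
        prof = dog_profile(RFParams(amp_ex=2.0, amp_inh=1.0))
        assert prof.weights[prof.n_taps // 2] == pytest.approx(1.0)

    def test_base_profile_integral_negative(self):
        # Riemann sum against the closed-form area sqrt(2*pi)*(Ae*se - Ai*si)
        rf = RFParams()
        prof = dog_profile(rf)
        riemann = prof.weights.sum() * prof.spacing_deg
        closed = np.sqrt(2 * np.pi) * 0.05 * (
            rf.amp_ex * rf.sigma_ex - rf.amp_inh * rf.sigma_inh
        )
        assert riemann < 0
        assert riemann == pytest.approx(closed, rel=1e-4)

    def test_on_center_off_surround_shape(self):
        # stronger center: positive middle, negative flanks
        prof = dog_profile(RFParams(amp_ex=2.0))
        c = prof.n_taps // 2
        assert prof.weights[c] > 0
        flank = np.abs(prof.offsets_deg - 0.1).argmin()
        assert prof.weights[flank] < 0


class TestConvolveInput:
    def test_zero_stimulus_gives_zero_drives(self, grid):
        stim = generate_grating(grid, 1.0, amplitude=0.0)
        conv = convolve_input(stim, RFParams())
        assert np.all(conv.i_ex == 0.0)
        assert np.all(conv.i_inh == 0.0)

    def test_uniform_stimulus_gives_exact_dc_gain(self, grid):
        # unit-sum kernels: interior drive = pair_gain * Amp * luminance
        c = 0.37
        stim = generate_grating(grid, 1e-12, amplitude=0.0, dc_offset=c)
        rf = RFParams(amp_ex=1.2, amp_inh=0.8)
        conv = convolve_input(stim, rf)
        np.testing.assert_allclose(
            conv.i_ex[conv.valid_mask], PAIR_GAIN * 1.2 * c, rtol=1e-12
        )
        np.testing.assert_allclose(
            conv.i_inh[conv.valid_mask], PAIR_GAIN * 0.8 * c, rtol=1e-12
        )

    @pytest.mark.parametrize("f", [0.5, 2.0, 5.0, 8.0, 12.0])
    def test_fourier_transfer_oracle(self, grid, f):
        """Interior sinusoid amplitude matches the Gaussian transform.

        Within the resolvable band the drive amplitude is
        a * pair_gain * Amp * exp(-2 pi^2 sigma_deg^2 f^2) to < 1%
        (above ~10-15 cpd the 5-sigma truncation sidelobes dominate the
        inhibitory transfer and the comparison loses meaning).
        """
        a = 0.1
        stim = generate_grating(grid, f, amplitude=a)
        rf = RFParams()
        conv = convolve_input(stim, rf)
        for drive, amp, sigma in ((conv.i_ex, rf.amp_ex, rf.sigma_ex * 0.05),
                                  (conv.i_inh, rf.amp_inh, rf.sigma_inh * 0.05)):
            if np.exp(-2 * np.pi**2 * sigma**2 * f**2) < 1e-4:
                continue  # below the truncation floor for this subfield
            v = drive[conv.valid_mask]
            measured = (v.max() - v.min()) / 2
            analytic = a * PAIR_GAIN * amp * np.exp(-2 * np.pi**2 * sigma**2 * f**2)
            assert measured == pytest.approx(analytic, rel=0.01)

    def test_linearity(self, grid):
        s1 = generate_grating(grid, 1.3, amplitude=0.1)
        s2 = generate_grating(grid, 4.7, amplitude=0.1)
        alpha, beta = 0.6, -1.7
        combo = Stimulus(grid=grid, amplitude=np.nan, frequency_cpd=np.nan,
                         dc_offset=0.0, values=alpha * s1.values + beta * s2.values)
        rf = RFParams()
        c1, c2 = convolve_input(s1, rf), convolve_input(s2, rf)
        cc = convolve_input(combo, rf)
        m = cc.valid_mask
        np.testing.assert_allclose(
            cc.i_ex[m], alpha * c1.i_ex[m] + beta * c2.i_ex[m],
            rtol=1e-10, atol=1e-14,
        )

    def test_shift_equivariance(self, grid):
        m_shift = 37
        s = generate_grating(grid, 2.9, amplitude=0.1)
        shifted = Stimulus(grid=grid, amplitude=0.1, frequency_cpd=2.9,
                           dc_offset=0.0, values=np.roll(s.values, m_shift))
        rf = RFParams()
        c0, c1 = convolve_input(s, rf), convolve_input(shifted, rf)
        # compare on an interior region untouched by either field edge
        lo = np.argmax(c0.valid_mask) + m_shift
        hi = grid.n_samples - np.argmax(c0.valid_mask[::-1]) - m_shift
        np.testing.assert_allclose(
            c1.i_ex[lo:hi], np.roll(c0.i_ex, m_shift)[lo:hi], rtol=1e-10,
            atol=1e-15,
        )

    def test_valid_mask_margin(self, grid):
        from dogcsf.receptive_field import edge_margin_samples

        rf = RFParams()
        conv = convolve_input(generate_grating(grid, 1.0), rf)
        margin = edge_margin_samples(rf, 0.05, grid.spacing_deg)
        # at least 5 sigma_inh excluded on each side, first interior sample valid
        assert margin >= 5 * rf.sigma_inh * 0.05 / grid.spacing_deg - 1
        assert not conv.valid_mask[:margin].any()
        assert not conv.valid_mask[-margin:].any()
        assert conv.valid_mask[margin]

    def test_grid_mismatch_error(self, grid):
        other = make_grid(2000, 10.0)
        stim = generate_grating(other, 1.0)
        with pytest.raises(ValueError, match="different grid"):
            convolve_input(stim, RFParams(), grid)
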