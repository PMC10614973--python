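"""Center-surround receptive fields: Gaussian subfields and their convolutions.

The receptive field of each model neuron is a difference of two concentric
Gaussians: a narrow excitatory center ``G_ex`` and a broader inhibitory
surround ``G_inh``, each parameterized by an amplitude (strength) and a
width sigma (spread) in model units.  Kernels are truncated at +/-5 sigma.

Two kernel conventions coexist here:

* the *profile* convention (``make_kernel``, ``dog_profile``): raw Gaussian
  taps with the peak equal to the amplitude — used for inspecting and
  exporting receptive-field shapes;
* the *drive* convention (``convolve_input``): each subfield's taps are
  normalized to unit sum, scaled by its amplitude and by a fixed pair gain
  of 0.5, so the base center + surround together deliver unit DC gain.
  Under this convention the amplitude sets a subfield's integrated synaptic
  strength and sigma sets only its spread, which keeps the two parameters
  independent; the effective transfer of a subfield for a grating of
  frequency f is ``0.5 * Amp * exp(-2*pi^2*sigma_deg^2*f^2)``.

Model units are converted to degrees through ``deg_per_unit`` (default
0.05 deg/unit), which places the base curve's sensitivity peak in the low
spatial-frequency range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_stimulus import SamplingGrid, Stimulus

__all__ = [
    "RFParams",
    "Kernel",
    "ConvolvedField",
    "make_kernel",
    "dog_profile",
    "convolve_input",
    "UnderResolutionError",
    "DEG_PER_UNIT",
    "PAIR_GAIN",
]

#: Degrees of visual angle per model unit of sigma.
DEG_PER_UNIT = 0.05
#: Shared DC gain factor of the normalized subfield kernels.  With base
#: amplitudes Amp_ex = Amp_inh = 1 the center and surround then sum to unit
#: total feedforward gain.
PAIR_GAIN = 0.5
#: Kernel support half-width in sigmas.
KERNEL_HALF_WIDTH_SIGMAS = 5.0


class UnderResolutionError(ValueError):
    """A Gaussian subfield is narrower than the grid spacing."""


@dataclass(frozen=True)
class RFParams:
    """Receptive-field subfield parameters (amplitudes and widths).

    The base (control) configuration uses unit amplitudes and the classical
    1:1.6 center-to-surround width ratio for optimal contrast registration.
    """

    amp_ex: float = 1.0
    sigma_ex: float = 1.0
    amp_inh: float = 1.0
    sigma_inh: float = 1.6

    def __post_init__(self):
        for name in ("amp_ex", "sigma_ex", "amp_inh", "sigma_inh"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class Kernel:
    """A symmetric kernel sampled on the grid lattice over [-5s, +5s]."""

    offsets_deg: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    spacing_deg: float = 0.0

    @property
    def n_taps(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ConvolvedField:
    """Excitatory and inhibitory drives after convolution with the input.

    ``valid_mask`` marks interior samples whose drives are unaffected by the
    zero-padded field edges (a 5*sigma_inh margin is excluded on each side).
    """

    i_ex: np.ndarray = field(repr=False)
    i_inh: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)


def _gaussian_taps(sigma_deg: float, spacing_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets and unnormalized Gaussian values over [-5s, +5s]."""
    m = int(np.floor(KERNEL_HALF_WIDTH_SIGMAS * sigma_deg / spacing_deg))
    offsets = np.arange(-m, m + 1) * spacing_deg
    return offsets, np.exp(-(offsets**2) / (2.0 * sigma_deg**2))


def make_kernel(
    amplitude: float,
    sigma_units: float,
    deg_per_unit: float = DEG_PER_UNIT,
    spacing_deg: float = 0.0025,
) -> Kernel:
    """Raw Gaussian kernel ``Amp * exp(-x^2 / 2 sigma^2)`` on the lattice.

    The center tap equals ``amplitude`` exactly; support is truncated at the
    largest lattice multiple <= 5 sigma.
    """
    for name, v in (("amplitude", amplitude), ("sigma_units", sigma_units),
                    ("deg_per_unit", deg_per_unit), ("spacing_deg", spacing_deg)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v}")
    sigma_deg = sigma_units * deg_per_unit
    if sigma_deg < spacing_deg:
        raise UnderResolutionError(
            f"sigma = {sigma_deg:g} deg is below the grid spacing "
            f"{spacing_deg:g} deg; increase grid density"
        )
    offsets, g = _gaussian_taps(sigma_deg, spacing_deg)
    weights = amplitude * g
    offsets.setflags(write=False)
    weights.setflags(write=False)
    return Kernel(offsets_deg=offsets, weights=weights, spacing_deg=spacing_deg)


def dog_profile(
    rf: RFParams,
    deg_per_unit: float = DEG_PER_UNIT,
    spacing_deg: float = 0.0025,
) -> Kernel:
    """Pointwise difference G_ex - G_inh on the surround's (wider) lattice."""
    k_ex = make_kernel(rf.amp_ex, rf.sigma_ex, deg_per_unit, spacing_deg)
    k_inh = make_kernel(rf.amp_inh, rf.sigma_inh, deg_per_unit, spacing_deg)
    if k_inh.n_taps < k_ex.n_taps:  # unusual sigma_inh < sigma_ex case
        k_ex, k_inh = k_inh, k_ex
        sign = -1.0
    else:
        sign = 1.0
    pad = (k_inh.n_taps - k_ex.n_taps) // 2
    wide = np.zeros_like(k_inh.weights)
    wide[pad : pad + k_ex.n_taps] = k_ex.weights
    weights = sign * (wide - k_inh.weights)
    weights.setflags(write=False)
    return Kernel(
        offsets_deg=k_inh.offsets_deg, weights=weights, spacing_deg=spacing_deg
    )


def _drive_kernel(amplitude: float, sigma_deg: float, spacing_deg: float) -> np.ndarray:
    """Unit-sum Gaussian taps scaled by amplitude and the pair gain."""
    _, g = _gaussian_taps(sigma_deg, spacing_deg)
    return PAIR_GAIN * amplitude * g / g.sum()


def edge_margin_samples(rf: RFParams, deg_per_unit: float, spacing_deg: float) -> int:
    """Samples at each field edge reached by the (wider) surround kernel."""
    sigma_wide = max(rf.sigma_ex, rf.sigma_inh) * deg_per_unit
    return int(np.ceil(KERNEL_HALF_WIDTH_SIGMAS * sigma_wide / spacing_deg))


def convolve_input(
    stimulus: Stimulus,
    rf: RFParams,
    grid: SamplingGrid | None = None,
    deg_per_unit: float = DEG_PER_UNIT,
) -> ConvolvedField:
    """Convolve a stimulus with the excitatory and inhibitory drive kernels.

    Same-length, zero-padded convolution; samples within 5 sigma of either
    edge are flagged invalid.  A uniform stimulus of luminance c yields
    interior drives ``i_ex = 0.5*Amp_ex*c`` and ``i_inh = 0.5*Amp_inh*c``
    exactly (unit-sum normalization).
    """
    if grid is None:
        grid = stimulus.grid
    if grid.n_samples != stimulus.values.size or grid is not stimulus.grid and (
        grid.n_samples != stimulus.grid.n_samples
        or grid.spacing_deg != stimulus.grid.spacing_deg
    ):
        raise ValueError(
            "stimulus was generated on a different grid "
            f"(n={stimulus.grid.n_samples}, spacing={stimulus.grid.spacing_deg:g}) "
            f"than requested (n={grid.n_samples}, spacing={grid.spacing_deg:g})"
        )
    dx = grid.spacing_deg
    for name, sig in (("sigma_ex", rf.sigma_ex), ("sigma_inh", rf.sigma_inh)):
        if sig * deg_per_unit < dx:
            raise UnderResolutionError(
                f"{name} = {sig * deg_per_unit:g} deg is below the grid spacing {dx:g} deg"
            )
    w_ex = _drive_kernel(rf.amp_ex, rf.sigma_ex * deg_per_unit, dx)
    w_inh = _drive_kernel(rf.amp_inh, rf.sigma_inh * deg_per_unit, dx)
    i_ex = np.convolve(stimulus.values, w_ex, mode="same")
    i_inh = np.convolve(stimulus.values, w_inh, mode="same")
    margin = edge_margin_samples(rf, deg_per_unit, dx)
    valid = np.zeros(grid.n_samples, dtype=bool)
    if margin < grid.n_samples - margin:
        valid[margin : grid.n_samples - margin] = True
    for arr in (i_ex, i_inh, valid):
        arr.setflags(write=False)
    return ConvolvedField(i_ex=i_ex, i_inh=i_inh, valid_mask=valid)
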