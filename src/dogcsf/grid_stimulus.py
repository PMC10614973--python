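"""Spatial sampling of 1-D visual space and sinusoidal grating stimuli.

The simulated field is a line of sample points (one per model neuron)
spanning a fixed extent of visual angle.  Stimuli are luminance gratings

    y(i) = dc + a * sin(2*pi*f*i)

with ``a`` the modulation amplitude, ``f`` the spatial frequency in cycles
per degree (cpd) and ``i`` the position in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingGrid",
    "Stimulus",
    "FrequencySweep",
    "make_grid",
    "generate_grating",
    "make_sweep",
    "AliasingError",
]

#: Default number of model neurons / sample points.
DEFAULT_N_SAMPLES = 4000
#: Default field width in degrees of visual angle.
DEFAULT_EXTENT_DEG = 10.0
#: Default grating modulation amplitude (dimensionless luminance units).
DEFAULT_AMPLITUDE = 0.1
#: Default sweep: 200 frequencies covering 0.1-100 cpd.
DEFAULT_F_MIN = 0.1
DEFAULT_F_MAX = 100.0
DEFAULT_N_FREQ = 200


class AliasingError(ValueError):
    """Requested spatial frequency exceeds the grid's Nyquist limit."""


@dataclass(frozen=True)
class SamplingGrid:
    """Uniform discretization of the 1-D visual field.

    Sample centers sit at ``(k + 0.5) * spacing_deg`` for ``k = 0..n-1`` so
    the field is covered symmetrically with no sample on either edge.
    """

    n_samples: int
    extent_deg: float
    spacing_deg: float
    positions_deg: np.ndarray = field(repr=False)

    @property
    def samples_per_degree(self) -> float:
        return 1.0 / self.spacing_deg

    @property
    def nyquist_cpd(self) -> float:
        """Highest representable spatial frequency, half the sampling rate."""
        return 0.5 * self.samples_per_degree


@dataclass(frozen=True)
class Stimulus:
    """A sampled sinusoidal luminance grating on a :class:`SamplingGrid`."""

    grid: SamplingGrid
    amplitude: float
    frequency_cpd: float
    dc_offset: float
    values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class FrequencySweep:
    """Ordered set of spatial frequencies probed by a sensitivity sweep."""

    frequencies_cpd: np.ndarray
    spacing_mode: str  # "logarithmic" | "linear"

    @property
    def n_freq(self) -> int:
        return self.frequencies_cpd.size

    @property
    def f_min(self) -> float:
        return float(self.frequencies_cpd[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies_cpd[-1])


def make_grid(
    n_samples: int = DEFAULT_N_SAMPLES,
    extent_deg: float = DEFAULT_EXTENT_DEG,
) -> SamplingGrid:
    """Build a uniform sampling grid of ``n_samples`` cell centers.

    Parameters
    ----------
    n_samples:
        Number of sample points (model neurons); must be >= 2.
    extent_deg:
        Width of the simulated visual field in degrees; must be > 0.
    """
    if not isinstance(n_samples, (int, np.integer)) or isinstance(n_samples, bool):
        raise ValueError(f"n_samples must be an integer, got {n_samples!r}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    extent_deg = float(extent_deg)
    if not np.isfinite(extent_deg) or extent_deg <= 0:
        raise ValueError(f"extent_deg must be positive and finite, got {extent_deg}")
    spacing = extent_deg / n_samples
    positions = (np.arange(n_samples) + 0.5) * spacing
    positions.setflags(write=False)
    return SamplingGrid(
        n_samples=int(n_samples),
        extent_deg=extent_deg,
        spacing_deg=spacing,
        positions_deg=positions,
    )


def generate_grating(
    grid: SamplingGrid,
    frequency_cpd: float,
    amplitude: float = DEFAULT_AMPLITUDE,
    dc_offset: float = 0.0,
) -> Stimulus:
    """Sample ``dc + a*sin(2*pi*f*x)`` at the grid positions.

    Raises
    ------
    AliasingError
        If ``frequency_cpd`` exceeds the grid's Nyquist frequency.
    """
    frequency_cpd = float(frequency_cpd)
    amplitude = float(amplitude)
    dc_offset = float(dc_offset)
    if not np.isfinite(frequency_cpd) or frequency_cpd <= 0:
        raise ValueError(f"frequency_cpd must be positive, got {frequency_cpd}")
    if not np.isfinite(amplitude):
        raise ValueError(f"amplitude must be finite, got {amplitude}")
    if frequency_cpd > grid.nyquist_cpd:
        raise AliasingError(
            f"grating frequency {frequency_cpd:g} cpd exceeds the grid Nyquist "
            f"limit {grid.nyquist_cpd:g} cpd"
        )
    values = dc_offset + amplitude * np.sin(
        2.0 * np.pi * frequency_cpd * grid.positions_deg
    )
    values.setflags(write=False)
    return Stimulus(
        grid=grid,
        amplitude=amplitude,
        frequency_cpd=frequency_cpd,
        dc_offset=dc_offset,
        values=values,
    )


def make_sweep(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    n_freq: int = DEFAULT_N_FREQ,
    spacing_mode: str = "logarithmic",
) -> FrequencySweep:
    """Build the frequency sweep probed by a contrast-sensitivity run.

    ``logarithmic`` spacing (the default, standard for contrast-sensitivity
    work) places frequencies geometrically between ``f_min`` and ``f_max``;
    ``linear`` places them arithmetically.  Endpoints are included exactly.
    """
    f_min, f_max = float(f_min), float(f_max)
    if not (0 < f_min < f_max) or not np.isfinite(f_max):
        raise ValueError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if not isinstance(n_freq, (int, np.integer)) or n_freq < 2:
        raise ValueError(f"n_freq must be an integer >= 2, got {n_freq!r}")
    if spacing_mode == "logarithmic":
        freqs = np.geomspace(f_min, f_max, int(n_freq))
    elif spacing_mode == "linear":
        freqs = np.linspace(f_min, f_max, int(n_freq))
    else:
        raise ValueError(
            f"spacing_mode must be 'logarithmic' or 'linear', got {spacing_mode!r}"
        )
    # pin endpoints against round-off
    freqs[0], freqs[-1] = f_min, f_max
    freqs.setflags(write=False)
    return FrequencySweep(frequencies_cpd=freqs, spacing_mode=spacing_mode)
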