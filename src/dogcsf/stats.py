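"""Curve-comparison statistics: cosine similarity, NDI, band tests.

Curves are compared band-wise over the low (0.1-4 cpd), medium (4-10 cpd)
and high (10-25 cpd) spatial-frequency ranges and overall.  For a condition
curve MSV and the base curve MBCSV:

* cosine similarity  cosSim = MSV . MBCSV / (|MSV| |MBCSV|) and its angle
  theta = arccos(cosSim) measure shape agreement (scale-invariant);
* the normalized difference index  NDI = (|MSV| - |MBCSV|) /
  (|MSV| + |MBCSV|), with |.| the Euclidean norm, gives a signed magnitude
  change in [-1, 1];
* a two-sided paired t-test on the per-frequency sensitivity differences
  within a band accompanies the band NDI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import stats as sps

from .csf import CSFCurve, describe_curve

__all__ = [
    "Band",
    "BandRanges",
    "ComparisonResult",
    "BandComparison",
    "band_slice",
    "cosine_similarity",
    "ndi",
    "band_significance",
    "compare_curves",
    "UndefinedStatisticError",
    "DEFAULT_BANDS",
]

#: Default label threshold on |NDI| separating increased/decreased from
#: unchanged.
NDI_THRESHOLD = 0.01


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given vectors (e.g. zero norms)."""


@dataclass(frozen=True)
class Band:
    """Half-open frequency interval [lo, hi), optionally closed at hi."""

    name: str
    lo: float
    hi: float
    closed_hi: bool = False

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        upper = freqs <= self.hi if self.closed_hi else freqs < self.hi
        return (freqs >= self.lo) & upper


@dataclass(frozen=True)
class BandRanges:
    """The three analysis bands; together they cover [0.1, 25] cpd."""

    low: Band = field(default_factory=lambda: Band("low", 0.1, 4.0))
    medium: Band = field(default_factory=lambda: Band("medium", 4.0, 10.0))
    high: Band = field(default_factory=lambda: Band("high", 10.0, 25.0, closed_hi=True))

    def __iter__(self):
        return iter((self.low, self.medium, self.high))

    @property
    def f_max(self) -> float:
        return self.high.hi


DEFAULT_BANDS = BandRanges()


@dataclass(frozen=True)
class BandComparison:
    """Comparison statistics for one band (or the overall range)."""

    band: str
    n_freq: int
    cos_sim: float
    theta_deg: float
    ndi: float
    t_statistic: float
    p_value: float
    outcome: str  # increased | decreased | unchanged


@dataclass(frozen=True)
class ComparisonResult:
    """Band-wise and overall comparison of a condition curve to the base."""

    overall: BandComparison
    bands: Dict[str, BandComparison]
    peak_shift_steps: int
    peak_shift_relative: float  # refined-peak ratio minus 1


def band_slice(curve: CSFCurve, band: Band) -> np.ndarray:
    """Sensitivity sub-vector whose frequencies fall inside the band."""
    m = band.mask(curve.frequencies_cpd)
    if m.sum() < 2:
        raise UndefinedStatisticError(
            f"band {band.name} [{band.lo}, {band.hi}) contains "
            f"{int(m.sum())} sweep frequencies; need >= 2"
        )
    return curve.sensitivities[m]


def cosine_similarity(msv: np.ndarray, mbcsv: np.ndarray) -> tuple[float, float]:
    """Cosine similarity and its angle in degrees between two curves."""
    msv = np.asarray(msv, dtype=float)
    mbcsv = np.asarray(mbcsv, dtype=float)
    if msv.shape != mbcsv.shape or msv.size < 2:
        raise UndefinedStatisticError(
            f"vectors must have equal length >= 2, got {msv.size} and {mbcsv.size}"
        )
    na, nb = np.linalg.norm(msv), np.linalg.norm(mbcsv)
    if na == 0.0 or nb == 0.0:
        raise UndefinedStatisticError("cosine similarity undefined for a zero vector")
    c = float(np.clip(msv @ mbcsv / (na * nb), -1.0, 1.0))
    return c, float(np.degrees(np.arccos(c)))


def ndi(msv: np.ndarray, mbcsv: np.ndarray) -> float:
    """Normalized difference index of Euclidean norms, in [-1, 1]."""
    na = float(np.linalg.norm(np.asarray(msv, dtype=float)))
    nb = float(np.linalg.norm(np.asarray(mbcsv, dtype=float)))
    if na + nb == 0.0:
        raise UndefinedStatisticError("NDI undefined when both vectors are zero")
    return (na - nb) / (na + nb)


def band_significance(msv_band: np.ndarray, mbcsv_band: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-frequency differences within a band.

    Degenerate conventions: all-zero differences give (0, 1); zero variance
    with a nonzero mean gives (+/-inf, 0).
    """
    d = np.asarray(msv_band, dtype=float) - np.asarray(mbcsv_band, dtype=float)
    if d.size < 3:
        raise UndefinedStatisticError(
            f"paired test needs >= 3 frequencies in the band, got {d.size}"
        )
    if np.all(d == 0.0):
        return 0.0, 1.0
    if np.ptp(d) == 0.0:  # constant nonzero shift, zero variance
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = sps.ttest_rel(msv_band, mbcsv_band)
    return float(t), float(p)


def _label(ndi_value: float, threshold: float) -> str:
    if ndi_value > threshold:
        return "increased"
    if ndi_value < -threshold:
        return "decreased"
    return "unchanged"


def compare_curves(
    curve: CSFCurve,
    base: CSFCurve,
    bands: BandRanges = DEFAULT_BANDS,
    ndi_threshold: float = NDI_THRESHOLD,
) -> ComparisonResult:
    """Full band-wise comparison of a condition curve against the base.

    Both curves must share the frequency grid.  The overall statistics are
    computed over the union of the analysis bands ([0.1, 25] cpd); the peak
    shift is reported both in sweep steps (sampled argmax) and as the
    relative change of the log-parabolically refined peak frequency.
    """
    if curve.n_freq != base.n_freq or not np.array_equal(
        curve.frequencies_cpd, base.frequencies_cpd
    ):
        if curve.n_freq == base.n_freq:
            k = int(np.argmax(curve.frequencies_cpd != base.frequencies_cpd))
            detail = (
                f"first differing frequency at index {k}: "
                f"{curve.frequencies_cpd[k]:g} vs {base.frequencies_cpd[k]:g} cpd"
            )
        else:
            detail = f"lengths {curve.n_freq} vs {base.n_freq}"
        raise UndefinedStatisticError(f"curves are on different frequency grids: {detail}")

    freqs = curve.frequencies_cpd
    results: Dict[str, BandComparison] = {}
    for band in bands:
        m = band.mask(freqs)
        u, v = curve.sensitivities[m], base.sensitivities[m]
        c, th = cosine_similarity(u, v)
        nd = ndi(u, v)
        t, p = band_significance(u, v)
        results[band.name] = BandComparison(
            band=band.name, n_freq=int(m.sum()), cos_sim=c, theta_deg=th,
            ndi=nd, t_statistic=t, p_value=p, outcome=_label(nd, ndi_threshold),
        )

    m_all = np.zeros_like(freqs, dtype=bool)
    for band in bands:
        m_all |= band.mask(freqs)
    u, v = curve.sensitivities[m_all], base.sensitivities[m_all]
    c, th = cosine_similarity(u, v)
    nd = ndi(u, v)
    t, p = band_significance(u, v)
    overall = BandComparison(
        band="overall", n_freq=int(m_all.sum()), cos_sim=c, theta_deg=th,
        ndi=nd, t_statistic=t, p_value=p, outcome=_label(nd, ndi_threshold),
    )

    from .csf import slice_curve

    dc = describe_curve(slice_curve(curve, bands.low.lo, bands.f_max))
    db = describe_curve(slice_curve(base, bands.low.lo, bands.f_max))
    shift_steps = dc.peak_index - db.peak_index
    shift_rel = dc.peak_frequency_refined_cpd / db.peak_frequency_refined_cpd - 1.0
    return ComparisonResult(
        overall=overall,
        bands=results,
        peak_shift_steps=int(shift_steps),
        peak_shift_relative=float(shift_rel),
    )
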