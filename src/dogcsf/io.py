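"""Configuration handling and CSV/JSON import-export.

CSV dialect: comma-separated, dot decimal, single header row, UTF-8,
newline-terminated.  Curve files print floats with ``repr`` (shortest
round-trip form), so a written curve re-reads bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .catalog import ReplicationReport
from .csf import CSFCurve, ModelParams
from .receptive_field import Kernel, RFParams
from .shunting import ShuntingParams
from .stats import ComparisonResult

__all__ = [
    "RunConfig",
    "ConfigError",
    "CurveFormatError",
    "load_config",
    "write_curve_csv",
    "read_curve_csv",
    "write_kernel_csv",
    "comparison_to_dict",
    "comparison_to_frame",
    "report_to_frame",
    "report_to_dict",
]

CURVE_HEADER = "frequency_cpd,sensitivity"


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


class CurveFormatError(ValueError):
    """A curve CSV file does not match the expected format."""


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one simulation run."""

    n_samples: int = 4000
    extent_deg: float = 10.0
    deg_per_unit: float = 0.05
    f_min: float = 0.1
    f_max: float = 100.0
    n_freq: int = 200
    spacing_mode: str = "logarithmic"
    amplitude: float = 0.1
    dc_offset: float = 0.0
    condition: str = "base"
    prominence_threshold: float = 0.05
    ndi_threshold: float = 0.01

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file; unknown keys are rejected by name."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown configuration key: {key!r}")
    try:
        return RunConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


# --------------------------------------------------------------------------
# curves

def write_curve_csv(curve: CSFCurve, path: str | Path) -> None:
    lines = [CURVE_HEADER]
    for f, s in zip(curve.frequencies_cpd, curve.sensitivities):
        lines.append(f"{float(f)!r},{float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_curve_csv(path: str | Path) -> CSFCurve:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].replace(" ", "") != CURVE_HEADER:
        raise CurveFormatError(
            f"{path}: line 1 must be the header '{CURVE_HEADER}', "
            f"got {lines[0] if lines else '<empty file>'!r}"
        )
    freqs: List[float] = []
    sens: List[float] = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise CurveFormatError(f"{path}: line {i}: expected 2 columns, got {len(parts)}")
        try:
            freqs.append(float(parts[0]))
            sens.append(float(parts[1]))
        except ValueError as exc:
            raise CurveFormatError(f"{path}: line {i}: {exc}") from exc
    return CSFCurve(
        frequencies_cpd=np.asarray(freqs), sensitivities=np.asarray(sens), params=None
    )


def write_kernel_csv(kernel: Kernel, path: str | Path) -> None:
    lines = ["offset_deg,weight"]
    for x, w in zip(kernel.offsets_deg, kernel.weights):
        lines.append(f"{float(x)!r},{float(w)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# comparisons and replication reports

def _band_row(bc) -> Dict:
    return {
        "band": bc.band, "n": bc.n_freq, "cos_sim": bc.cos_sim,
        "theta_deg": bc.theta_deg, "ndi": bc.ndi, "t": bc.t_statistic,
        "p": bc.p_value, "outcome": bc.outcome,
    }


def comparison_to_frame(cmp: ComparisonResult) -> pd.DataFrame:
    rows = [_band_row(bc) for bc in cmp.bands.values()] + [_band_row(cmp.overall)]
    return pd.DataFrame(rows)


def comparison_to_dict(cmp: ComparisonResult) -> Dict:
    return {
        "bands": {name: _band_row(bc) for name, bc in cmp.bands.items()},
        "overall": _band_row(cmp.overall),
        "peak_shift_steps": cmp.peak_shift_steps,
        "peak_shift_relative": cmp.peak_shift_relative,
    }


def report_to_frame(report: ReplicationReport) -> pd.DataFrame:
    rows = []
    for o in report.outcomes:
        row = {
            "condition": o.condition.name,
            "patient_group": o.condition.patient_group,
            "is_best_fit": o.condition.is_best_fit,
            "asserted": o.condition.asserted,
            "passed": o.passed,
            "n_checks": len(o.checks),
            "failed_checks": ";".join(k for k, v in o.checks.items() if not v),
            "peak_shift_relative": o.comparison.peak_shift_relative,
            "peak_prominence": o.descriptors.peak_prominence,
        }
        for name, bc in o.comparison.bands.items():
            row[f"ndi_{name}"] = bc.ndi
            row[f"cos_sim_{name}"] = bc.cos_sim
            row[f"p_{name}"] = bc.p_value
        row["ndi_overall"] = o.comparison.overall.ndi
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_dict(report: ReplicationReport) -> Dict:
    return {
        "pass_fraction": report.pass_fraction,
        "base": {
            "peak_frequency_cpd": report.base_descriptors.peak_frequency_cpd,
            "peak_prominence": report.base_descriptors.peak_prominence,
        },
        "conditions": {
            o.condition.name: {
                "source": o.condition.source,
                "patient_group": o.condition.patient_group,
                "is_best_fit": o.condition.is_best_fit,
                "asserted": o.condition.asserted,
                "passed": o.passed,
                "checks": o.checks,
                "comparison": comparison_to_dict(o.comparison),
            }
            for o in report.outcomes
        },
    }


# --------------------------------------------------------------------------
# parameter assembly

def params_from_config(cfg: RunConfig, overrides: Optional[Dict[str, float]] = None) -> ModelParams:
    """Resolve a ModelParams from a config plus explicit rf/shunting overrides.

    Override keys: sigma_ex, amp_ex, sigma_inh, amp_inh, decay_a, upper_b,
    lower_c.  The named condition (if not "base") is applied first.
    """
    from .catalog import builtin_catalog

    if cfg.condition == "base":
        params = ModelParams(
            stimulus_amplitude=cfg.amplitude, dc_offset=cfg.dc_offset
        )
    else:
        match = [c for c in builtin_catalog() if c.name == cfg.condition]
        if not match:
            raise ConfigError(f"unknown condition name: {cfg.condition!r}")
        params = dataclasses.replace(
            match[0].params,
            stimulus_amplitude=cfg.amplitude,
            dc_offset=cfg.dc_offset,
        )
    if overrides:
        rf_keys = {"sigma_ex", "amp_ex", "sigma_inh", "amp_inh"}
        sp_keys = {"decay_a", "upper_b", "lower_c"}
        rf_kw = {k: v for k, v in overrides.items() if k in rf_keys}
        sp_kw = {k: v for k, v in overrides.items() if k in sp_keys}
        unknown = set(overrides) - rf_keys - sp_keys
        if unknown:
            raise ConfigError(f"unknown parameter name(s): {sorted(unknown)}")
        rf = dataclasses.replace(params.rf, **rf_kw) if rf_kw else params.rf
        sp = dataclasses.replace(params.shunting, **sp_kw) if sp_kw else params.shunting
        params = dataclasses.replace(params, rf=rf, shunting=sp)
    return params
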