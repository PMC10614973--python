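"""Shunting (membrane) dynamics of the model neuron array.

Each neuron's rate x obeys the shunting equation

    dx/dt = -A*x + (B - x)*I_ex - (C + x)*I_inh

with passive decay A, upper bound B and lower-bound magnitude C.  The
multiplicative gating keeps x inside (-C, B) whenever the drives are
nonnegative.  All sensitivity results use the closed-form equilibrium

    x_eq = (B*I_ex - C*I_inh) / (A + I_ex + I_inh);

the time-domain integrator here exists purely as an independent validation
oracle (per neuron the equation is linear with rate A + I_ex + I_inh, so the
integrated state must relax to x_eq).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .receptive_field import ConvolvedField

__all__ = [
    "ShuntingParams",
    "ActivityField",
    "equilibrium_response",
    "integrate_dynamics",
    "DegenerateDynamicsError",
]

#: Minimum admissible equilibrium denominator A + I_ex + I_inh.
DENOMINATOR_EPS = 1e-9


class DegenerateDynamicsError(ValueError):
    """Equilibrium denominator A + I_ex + I_inh is not safely positive."""


@dataclass(frozen=True)
class ShuntingParams:
    """Shunting constants; defaults are the model's standard values."""

    decay_a: float = 1.0
    upper_b: float = 10.1
    lower_c: float = 5.0

    def __post_init__(self):
        if not np.isfinite(self.decay_a) or self.decay_a <= 0:
            raise ValueError(f"decay_a must be positive, got {self.decay_a}")
        if not np.isfinite(self.upper_b) or self.upper_b <= 0:
            raise ValueError(f"upper_b must be positive, got {self.upper_b}")
        if not np.isfinite(self.lower_c) or self.lower_c < 0:
            raise ValueError(f"lower_c must be nonnegative, got {self.lower_c}")


@dataclass(frozen=True)
class ActivityField:
    """Per-neuron activities with the validity mask of their drives."""

    values: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)


def equilibrium_response(conv: ConvolvedField, sp: ShuntingParams) -> ActivityField:
    """Closed-form equilibrium of the shunting equation, pointwise.

    Raises
    ------
    DegenerateDynamicsError
        If the denominator falls to ``DENOMINATOR_EPS`` or below at any
        valid sample (the fixed point is then ill-conditioned or unstable).
    """
    denom = sp.decay_a + conv.i_ex + conv.i_inh
    bad = conv.valid_mask & (denom <= DENOMINATOR_EPS)
    if bad.any():
        k = int(np.argmax(bad))
        raise DegenerateDynamicsError(
            f"equilibrium denominator {denom[k]:.3e} <= {DENOMINATOR_EPS:g} "
            f"at sample {k}"
        )
    values = (sp.upper_b * conv.i_ex - sp.lower_c * conv.i_inh) / denom
    values.setflags(write=False)
    return ActivityField(values=values, valid_mask=conv.valid_mask)


def integrate_dynamics(
    conv: ConvolvedField,
    sp: ShuntingParams,
    x0: ActivityField | np.ndarray | None = None,
    t_end: float = 20.0,
    rtol: float = 1e-8,
) -> ActivityField:
    """Integrate the shunting ODE from ``x0`` (default zero state) to t_end.

    Validation oracle only: for ``t_end >= 20/A`` the result agrees with
    :func:`equilibrium_response` to well below 1e-6 because each neuron
    relaxes exponentially at rate ``A + I_ex + I_inh``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if x0 is None:
        y0 = np.zeros_like(conv.i_ex)
    elif isinstance(x0, ActivityField):
        y0 = np.asarray(x0.values, dtype=float)
    else:
        y0 = np.asarray(x0, dtype=float)

    a, b, c = sp.decay_a, sp.upper_b, sp.lower_c
    i_ex, i_inh = conv.i_ex, conv.i_inh

    def rhs(_t, x):
        return -a * x + (b - x) * i_ex - (c + x) * i_inh

    sol = solve_ivp(
        rhs, (0.0, float(t_end)), y0, method="RK45", rtol=rtol, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"shunting integration failed: {sol.message}")
    values = sol.y[:, -1]
    values.setflags(write=False)
    return ActivityField(values=values, valid_mask=conv.valid_mask)
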