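"""Cubic switching function used for smooth coordination numbers.

The weight is 1 for d <= D0, 0 for d >= Dmax, and in between

    w(y) = (y - 1)^2 (1 + 2 y),   y = (d - D0) / (Dmax - D0),

which is the cubic (RATIONAL-free) switching convention of the PLUMED manual:
continuously differentiable at both ends (w'(0) = w'(1) = 0) and monotone
nonincreasing on [D0, Dmax].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SwitchSpec:
    """Cutoffs of the cubic switch: full weight below ``d0``, zero above ``dmax``."""

    d0: float
    dmax: float

    def __post_init__(self) -> None:
        if not 0 <= self.d0 < self.dmax:
            raise ValueError(f"need 0 <= D0 < Dmax, got D0={self.d0}, Dmax={self.dmax}")


def switch_cubic(d: np.ndarray | float, spec: SwitchSpec) -> np.ndarray | float:
    """Cubic switching weight in [0, 1]; vectorised over ``d``."""
    d_arr = np.asarray(d, dtype=float)
    y = np.clip((d_arr - spec.d0) / (spec.dmax - spec.d0), 0.0, 1.0)
    w = (y - 1.0) ** 2 * (1.0 + 2.0 * y)
    return w if d_arr.ndim else float(w)


def switch_cubic_derivative(d: np.ndarray | float, spec: SwitchSpec) -> np.ndarray | float:
    """dw/dd of the cubic switch (zero outside [D0, Dmax])."""
    d_arr = np.asarray(d, dtype=float)
    width = spec.dmax - spec.d0
    y = (d_arr - spec.d0) / width
    inside = (y > 0) & (y < 1)
    dw = np.where(inside, 6.0 * y * (y - 1.0) / width, 0.0)
    return dw if d_arr.ndim else float(dw)
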