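"""Insulin-action state profiles on a dense time grid.

The latent action state x obeys x' = -p2 x + gain * (I(t) - Ib)+ with x(0)=0.
For the glucose model the gain is p3 (so x = XG has units 1/min); for the
glycerol model the gain equals the time constant p2g itself (so x = Xg carries
insulin concentration units and its step-response plateau is the insulin
excess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._integrate import pl_lowpass
from .forcing import InsulinForcing

#: dense-profile resolution, minutes
DEFAULT_GRID_STEP = 1.0
_SUBSTEPS = 4  # internal refinement under the reported grid


@dataclass(frozen=True)
class ActionProfile:
    """Dense-grid trajectory of an insulin-action state (XG or Xg)."""

    grid: np.ndarray
    values: np.ndarray
    label: str  # "glucose" or "glycerol"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.shape != v.shape or g.ndim != 1:
            raise ValueError("grid/values must be aligned 1-d arrays")
        if v.size and abs(v[0]) > 1e-12:
            raise ValueError("action profiles start at zero")
        if np.any(v < -1e-12):
            raise ValueError("action values must be nonnegative")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))


def action_profile(
    p2: float,
    gain: float,
    forcing: InsulinForcing,
    t_end: float,
    *,
    step: float = DEFAULT_GRID_STEP,
    label: str = "glucose",
) -> ActionProfile:
    """Exact action trajectory on a uniform grid [0, t_end].

    The drive gain*(I - Ib)+ is piecewise linear between insulin samples, so
    the integrating-factor recurrence in :func:`pl_lowpass` is exact up to the
    sub-grid location of basal-crossing kinks (refined 4x under ``step``).
    """
    h = step / _SUBSTEPS
    n_fine = int(round(t_end / h))
    fine = np.arange(n_fine + 1) * h
    drive = gain * forcing.excess(fine)
    x = pl_lowpass(p2, drive, h)
    return ActionProfile(grid=fine[::_SUBSTEPS], values=x[::_SUBSTEPS], label=label)
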