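"""Continuous insulin input I(t) used as the forcing function of both ODE models.

Insulin is never modelled mechanistically here: measured serum insulin samples
are interpolated to give a continuous forcing, and the basal level ``Ib`` is the
mean of the three pre-drink samples (-20, -10, 0 min).  Both insulin-action
states are driven by the *excess* insulin ``(I(t) - Ib)+``, which implements the
piecewise action equations as a single clipped form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

PRE_DRINK_TIMES = (-20.0, -10.0, 0.0)


def compute_basal(
    times: np.ndarray,
    values: np.ndarray,
    *,
    pre_times: tuple[float, ...] = PRE_DRINK_TIMES,
    tol: float = 0.0,
) -> float:
    """Basal concentration: mean of the samples at -20, -10 and 0 min.

    If any of the three pre-drink timepoints is missing (within ``tol`` minutes
    of the protocol time), falls back to the mean of all samples at t <= 0 with
    a warning.  Raises ``ValueError`` if there are no pre-drink samples at all.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must be aligned")
    picked = []
    for tp in pre_times:
        hit = np.flatnonzero(np.abs(times - tp) <= tol)
        if hit.size:
            picked.append(values[hit[0]])
    if len(picked) == len(pre_times):
        return float(np.mean(picked))
    pre = values[times <= 0]
    if pre.size == 0:
        raise ValueError("no pre-drink (t <= 0) samples to compute a basal value")
    warnings.warn(
        "missing one of the -20/-10/0 min samples; basal taken as mean of all t <= 0 samples",
        stacklevel=2,
    )
    return float(np.mean(pre))


@dataclass(frozen=True)
class InsulinForcing:
    """Piecewise interpolant of insulin samples with constant boundary extrapolation.

    Evaluation at any sample time returns that sample exactly; outside the
    sampling window the nearest boundary sample is held constant.  With the
    default linear interpolation the forcing is nonnegative wherever the
    samples are, and monotone between adjacent samples.
    """

    times: np.ndarray
    values: np.ndarray
    Ib: float
    kind: str = "linear"  # "linear" or "pchip" (monotone cubic)
    _interp: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 1:
            raise ValueError("times/values must be aligned 1-d arrays")
        if t.size > 1 and np.any(np.diff(t) == 0):
            raise ValueError("duplicate sample times in insulin forcing")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("negative insulin values")
        if not self.Ib > 0:
            raise ValueError("basal insulin Ib must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.kind == "pchip" and t.size > 1:
            object.__setattr__(self, "_interp", PchipInterpolator(t, v))
        elif self.kind not in ("linear", "pchip"):
            raise ValueError(f"unknown interpolation kind {self.kind!r}")

    def __call__(self, t):
        t = np.clip(t, self.times[0], self.times[-1])
        if self._interp is not None:
            return self._interp(t)
        return np.interp(t, self.times, self.values)

    def excess(self, t):
        """Drive term (I(t) - Ib)+ of both insulin-action ODEs."""
        return np.maximum(self(t) - self.Ib, 0.0)


def make_forcing(times, values, Ib: float, kind: str = "linear") -> InsulinForcing:
    """Build the insulin forcing; see :class:`InsulinForcing` for the contract."""
    return InsulinForcing(np.asarray(times, float), np.asarray(values, float), float(Ib), kind)


def excess_insulin(forcing: InsulinForcing, t):
    """max(I(t) - Ib, 0): zero at or below basal, the excursion height above it."""
    return forcing.excess(t)
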