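"""Singular-spectrum-analysis smoothing and the weighted least-squares objective.

Every fit in this package minimises the sum of squared residuals between data
and model, divided by a participant-specific variance.  The variance comes
from a rank-1 singular spectrum analysis (SSA) reconstruction of the data: the
series is embedded in its Hankel trajectory matrix, the leading singular
component is kept, and the smooth series is recovered by anti-diagonal
averaging.  The variance is then the squared (population) standard deviation
of the *squared* residuals between data and smooth curve — implemented
literally; ``mode="residual"`` offers the conventional std(residual)^2
alternative.  The variance is computed once per participant from the data, not
per optimiser iteration, since both inputs are model-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel, svd

DEFAULT_VARIANCE_FLOOR = 1e-8


def default_window_length(n: int) -> int:
    """floor(n/2), the common SSA choice maximising trajectory-matrix rank."""
    return max(2, n // 2)


def ssa_smooth(series, window_length: int | None = None, rank: int = 1) -> np.ndarray:
    """Rank-truncated SSA reconstruction of a 1-d series.

    Embeds into the L x (n-L+1) Hankel matrix, keeps the leading ``rank``
    singular triplets, and averages anti-diagonals back to a series of the
    original length.  Constants and noiseless exponentials are exactly rank-1;
    full rank reproduces the input.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("series too short for SSA (need at least 3 points)")
    L = default_window_length(n) if window_length is None else int(window_length)
    if not 2 <= L <= n - 1:
        raise ValueError(f"window_length must lie in [2, {n - 1}]")
    if not 1 <= rank <= L:
        raise ValueError("rank must lie in [1, window_length]")
    X = hankel(x[:L], x[L - 1:])
    U, s, Vt = svd(X, full_matrices=False)
    Xr = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    idx = np.add.outer(np.arange(L), np.arange(n - L + 1)).ravel()
    sums = np.bincount(idx, weights=Xr.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return sums / counts


def estimate_variance(
    data,
    smooth,
    floor: float = DEFAULT_VARIANCE_FLOOR,
    mode: str = "literal",
) -> float:
    """Variance of the data about its SSA smooth, floored away from zero.

    ``literal`` (default): std over the squared residuals, squared —
    var = std((data - smooth)^2)^2 with the population (divisor n) convention.
    ``residual``: ordinary residual variance std(data - smooth)^2.
    """
    d = np.asarray(data, dtype=float) - np.asarray(smooth, dtype=float)
    if mode == "literal":
        v = float(np.std(d ** 2) ** 2)
    elif mode == "residual":
        v = float(np.std(d) ** 2)
    else:
        raise ValueError(f"unknown variance mode {mode!r}")
    return max(v, floor)


def objective_value(data, model_prediction, variance: float) -> float:
    """Weighted sum of squares: sum((data - model)^2) / variance."""
    if not variance > 0:
        raise ValueError("variance must be positive")
    r = np.asarray(data, dtype=float) - np.asarray(model_prediction, dtype=float)
    return float(np.sum(r * r) / variance)


@dataclass(frozen=True)
class ObjectiveContext:
    """Per-participant objective ingredients: data, its SSA smooth, and variance."""

    data: np.ndarray
    smooth: np.ndarray
    variance: float
    window_length: int

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        s = np.asarray(self.smooth, dtype=float)
        if d.shape != s.shape:
            raise ValueError("smooth must have the same length as data")
        if not self.variance > 0:
            raise ValueError("variance must be positive")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "smooth", s)

    @classmethod
    def from_data(
        cls,
        data,
        window_length: int | None = None,
        floor: float = DEFAULT_VARIANCE_FLOOR,
        mode: str = "literal",
    ) -> "ObjectiveContext":
        data = np.asarray(data, dtype=float)
        L = default_window_length(data.size) if window_length is None else window_length
        smooth = ssa_smooth(data, L, rank=1)
        var = estimate_variance(data, smooth, floor=floor, mode=mode)
        return cls(data=data, smooth=smooth, variance=var, window_length=L)

    def __call__(self, model_prediction) -> float:
        return objective_value(self.data, model_prediction, self.variance)
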