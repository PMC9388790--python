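"""Coupled glycerol-insulin dynamics model of lipolysis suppression.

State equations, with measured insulin I(t) as a known forcing:

    dg/dt  = -Sg g + l0 + l2 / (1 + (Xg / X2)^A)
    dXg/dt = -p2g Xg + p2g (I(t) - Ib)+          Xg(0) = 0

g is plasma glycerol (umol/L); Xg is insulin action on glycerol, which by the
algebra of its own equation carries insulin units (uU/mL) — a step of excess
insulin c drives Xg to the plateau c itself, since p2g multiplies both decay
and drive.  Lipolysis is the sum of an insulin-independent rate l0 and a
falling Hill function of the action: from the fasted maximum l0 + l2 at
Xg = 0, through half-suppression l0 + l2/2 at Xg = X2, to the floor l0 at
full suppression.  The exponent A is fixed at 2 (the model is insensitive to
it, and fixing improves identifiability).  Because the maximum lipolysis rate
is the fasted one, the model cannot raise glycerol above basal; records are
truncated at the glucose nadir before fitting for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from ._integrate import pl_lowpass, solve_piecewise
from .actions import ActionProfile
from .fitting import FitProblem, FitResult, multistart_fit
from .forcing import InsulinForcing, make_forcing
from .preprocess import OGTTRecord
from .ssa import ObjectiveContext

DEFAULT_HILL_EXPONENT = 2.0
SOLVER_ABS_TOL = 1e-10
SOLVER_REL_TOL = 1e-9

PARAM_NAMES = ("Sg", "l0", "l2", "X2", "p2g")


@dataclass(frozen=True)
class GlycerolParams:
    Sg: float                        # glycerol uptake effectiveness, 1/min
    l0: float                        # insulin-independent lipolysis, umol/L/min
    l2: float                        # suppressible lipolysis, umol/L/min
    X2: float                        # action half-suppression scale, uU/mL
    p2g: float                       # insulin-action time constant, 1/min
    A: float = DEFAULT_HILL_EXPONENT  # Hill exponent, fixed (never fitted)

    def __post_init__(self) -> None:
        for name in ("Sg", "l0", "l2", "X2", "p2g", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.Sg <= 1:
            raise ValueError("Sg is a proportion: must lie in [0, 1]")
        if not 0 <= self.p2g <= 1:
            raise ValueError("p2g is a proportion: must lie in [0, 1]")
        if not self.X2 > 0:
            raise ValueError("X2 must be positive")

    @property
    def basal_steady_state(self) -> float:
        """Fasted fixed point (l0 + l2) / Sg at Xg = 0."""
        return (self.l0 + self.l2) / self.Sg


def lipolysis_rate(Xg, params: GlycerolParams):
    """l0 + l2 / (1 + (Xg/X2)^A): decreasing in Xg, range (l0, l0 + l2]."""
    if params.X2 <= 0:
        raise ValueError("X2 must be positive")
    Xg = np.asarray(Xg, dtype=float)
    if np.any(Xg < 0):
        raise ValueError("Xg must be nonnegative")
    return params.l0 + params.l2 / (1.0 + (Xg / params.X2) ** params.A)


def simulate_glycerol(
    params: GlycerolParams,
    forcing: InsulinForcing,
    g0: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, ActionProfile]:
    """Integrate the two-state glycerol model (stiff-capable solver, atol 1e-10)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0:
        raise ValueError("grid must start at 0 (drink ingestion)")
    if not g0 > 0:
        raise ValueError("initial glycerol must be positive")

    def rhs(t, y):
        g, Xg = y
        return (
            -params.Sg * g + params.l0 + params.l2 / (1.0 + (max(Xg, 0.0) / params.X2) ** params.A),
            -params.p2g * Xg + params.p2g * forcing.excess(t),
        )

    try:
        y = solve_piecewise(rhs, grid, [g0, 0.0], forcing.times,
                            atol=SOLVER_ABS_TOL, rtol=SOLVER_REL_TOL)
    except RuntimeError as exc:
        raise RuntimeError(f"glycerol solver failed with params {params}: {exc}") from exc
    Xg = np.maximum(y[1], 0.0)
    Xg[0] = 0.0
    return y[0], ActionProfile(grid=grid, values=Xg, label="glycerol")


@dataclass(frozen=True)
class GlycerolFitConfig:
    n_restarts: int = 75
    A: float = DEFAULT_HILL_EXPONENT
    # parameter order (Sg, l0, l2, X2, p2g)
    bounds: tuple = ((0.0, 1.0), (0.0, np.inf), (0.0, np.inf), (0.0, np.inf), (0.0, 1.0))
    # Sg, p2g seeded in [0, 1]; lipolysis seed ranges bracket 0-200% of
    # plausible cohort values (implementer defaults, configurable)
    seed_ranges: tuple = ((0.0, 1.0), (0.0, 20.0), (0.0, 40.0), (0.0, 400.0), (0.0, 1.0))
    grid_step: float = 0.25
    g0_mode: str = "basal"          # "basal" (-20/-10/0 average) or "sample0"
    window_length: int | None = None
    variance_floor: float = 1e-8
    variance_mode: str = "literal"
    constrain_basal_balance: bool = False   # l0 + l2 = Sg * gb identifiability experiment
    basal_penalty: float = 1e4


class _GlycerolSimulator:
    """Fast prediction of glycerol at the truncated sample times."""

    def __init__(self, record: OGTTRecord, config: GlycerolFitConfig, forcing: InsulinForcing):
        post = record.times >= 0
        t = record.times[post]
        y = record.glycerol[post]
        keep = np.isfinite(y)
        self.t_data, self.y_data = t[keep], y[keep]
        self.config = config
        self.g0 = record.gb if config.g0_mode == "basal" else float(self.y_data[0])
        self.gb = record.gb
        self.h = config.grid_step
        n = int(round(self.t_data[-1] / self.h))
        self.fine = np.arange(n + 1) * self.h
        self.excess_fine = forcing.excess(self.fine)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        Sg, l0, l2, X2, p2g = x
        if X2 <= 0:
            return np.full(self.t_data.size, np.nan)
        Xg = pl_lowpass(p2g, p2g * self.excess_fine, self.h)
        u = l0 + l2 / (1.0 + (Xg / X2) ** self.config.A)
        g = pl_lowpass(Sg, u, self.h, x0=self.g0)
        return np.interp(self.t_data, self.fine, g)

    def validate(self, x: np.ndarray) -> bool:
        Sg, l0, l2, X2, p2g = x
        if not np.all(np.isfinite(x)) or X2 <= 0:
            return False
        return np.isfinite(l0 + l2 / (1.0 + (0.0 / X2) ** self.config.A))


def fit_glycerol(
    record: OGTTRecord,
    config: GlycerolFitConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> FitResult:
    """Best-of-75 multistart estimate of {Sg, l0, l2, X2, p2g} with A fixed.

    ``record`` must already be truncated at the glucose nadir.  The objective
    is the SSA-weighted sum of squares at the glycerol samples; Sg and p2g are
    bounded in [0, 1] and everything is nonnegative.
    """
    config = config or GlycerolFitConfig()
    post = record.times >= 0
    if int(np.sum(np.isfinite(record.glycerol[post]))) < 4:
        raise ValueError("fewer than 4 glycerol samples in the fitting window")
    forcing = make_forcing(
        record.times[np.isfinite(record.insulin)],
        record.insulin[np.isfinite(record.insulin)],
        record.Ib,
    )
    sim = _GlycerolSimulator(record, config, forcing)
    ctx = ObjectiveContext.from_data(
        sim.y_data, window_length=config.window_length,
        floor=config.variance_floor, mode=config.variance_mode,
    )
    problem = FitProblem(
        simulate=sim,
        bounds=config.bounds,
        seed_ranges=config.seed_ranges,
        objective=ctx,
        names=PARAM_NAMES,
        validate=sim.validate,
    )
    if config.constrain_basal_balance:
        base_obj = problem.objective_of
        gb, pen = sim.gb, config.basal_penalty

        def penalised(x):
            Sg, l0, l2 = x[0], x[1], x[2]
            return base_obj(x) + pen * (l0 + l2 - Sg * gb) ** 2

        problem.objective_of = penalised  # type: ignore[method-assign]
    result = multistart_fit(
        problem, n_restarts=config.n_restarts, rng=rng,
        window=(float(sim.t_data[0]), float(sim.t_data[-1])),
    )
    result.extra["params"] = GlycerolParams(*result.best_params, A=config.A)
    result.extra["g0"] = sim.g0
    return result
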