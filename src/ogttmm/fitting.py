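"""Multistart bound-constrained fitting engine shared by both models.

Each model fit draws parameter seeds uniformly from physiological seed ranges,
re-drawing whole vectors until the initial model state is valid, runs a
bound-respecting local minimiser from every seed (default 75 restarts), and
keeps the solution with the lowest objective.  All randomness flows from one
master seed so the whole restart ensemble is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .ssa import ObjectiveContext

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 75
_PENALTY = 1e30  # objective value returned for non-finite model output


@dataclass
class FitProblem:
    """A parametric model prediction paired with bounds, seeds and an objective.

    ``simulate`` maps a parameter vector to the model prediction at the data's
    sample times.  ``validate`` (optional) mirrors the seeding rule that the
    initial model state must be real and positive: seeds failing it are
    redrawn wholesale.
    """

    simulate: Callable[[np.ndarray], np.ndarray]
    bounds: Sequence[tuple[float, float]]
    seed_ranges: Sequence[tuple[float, float]]
    objective: ObjectiveContext
    names: Sequence[str]
    validate: Callable[[np.ndarray], bool] | None = None

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.seed_ranges) or len(self.bounds) != len(self.names):
            raise ValueError("bounds, seed_ranges and names must align")
        for (lo, hi), (slo, shi) in zip(self.bounds, self.seed_ranges):
            if slo < lo or shi > hi:
                raise ValueError("seed_ranges must lie inside bounds")

    def objective_of(self, x: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            pred = self.simulate(np.asarray(x, dtype=float))
            if pred is None or not np.all(np.isfinite(pred)):
                return _PENALTY
            val = self.objective(pred)
        if not np.isfinite(val):
            return _PENALTY
        return min(float(val), _PENALTY)


@dataclass(frozen=True)
class RestartRecord:
    seed_params: np.ndarray
    params: np.ndarray
    objective: float
    status: str
    success: bool


@dataclass(frozen=True)
class FitResult:
    """Best-of-N multistart solution with the full per-restart log."""

    best_params: np.ndarray
    best_objective: float
    restarts: list[RestartRecord]
    rng_seed: int | None
    names: tuple[str, ...]
    window: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    def params_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.best_params)}


def seed_parameters(rng: np.random.Generator, problem: FitProblem, max_retries: int = 1000) -> np.ndarray:
    """Uniform draw from the seed ranges, re-drawn until the model state is valid."""
    lo = np.array([r[0] for r in problem.seed_ranges], dtype=float)
    hi = np.array([r[1] for r in problem.seed_ranges], dtype=float)
    for _ in range(max_retries):
        x = rng.uniform(lo, hi)
        if problem.validate is None or problem.validate(x):
            return x
    raise RuntimeError("cannot seed valid state: rejection-sampling retry cap exceeded")


def multistart_fit(
    problem: FitProblem,
    n_restarts: int = DEFAULT_N_RESTARTS,
    rng: np.random.Generator | int | None = None,
    window: tuple[float, float] | None = None,
    optimizer_options: dict | None = None,
) -> FitResult:
    """Run the local optimiser from ``n_restarts`` random seeds; keep the best.

    Failed restarts are logged, not fatal; the fit errors out only when every
    restart fails.  ``best_objective`` is non-increasing in ``n_restarts`` for
    a fixed random stream prefix.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seed_val = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    options = {"maxiter": 400, "ftol": 1e-12, "gtol": 1e-9}
    if optimizer_options:
        options.update(optimizer_options)
    bounds = [(lo, None if np.isinf(hi) else hi) for lo, hi in problem.bounds]
    restarts: list[RestartRecord] = []
    for _ in range(n_restarts):
        x0 = seed_parameters(gen, problem)
        try:
            res = minimize(
                problem.objective_of, x0, method="L-BFGS-B", bounds=bounds, options=options
            )
            x = np.clip(res.x, [b[0] for b in problem.bounds], [b[1] for b in problem.bounds])
            fun = problem.objective_of(x)
            ok = np.isfinite(fun) and fun < _PENALTY
            restarts.append(RestartRecord(x0, x, float(fun), str(res.message), ok))
        except Exception as exc:  # noqa: BLE001 - a failed restart is logged, not fatal
            logger.warning("restart failed: %s", exc)
            restarts.append(RestartRecord(x0, x0, np.inf, f"error: {exc}", False))
    good = [r for r in restarts if r.success]
    if not good:
        raise RuntimeError(f"all {n_restarts} restarts failed: {[r.status for r in restarts]}")
    best = min(good, key=lambda r: r.objective)
    return FitResult(
        best_params=best.params,
        best_objective=best.objective,
        restarts=restarts,
        rng_seed=int(seed_val) if seed_val is not None else None,
        names=tuple(problem.names),
        window=window,
    )
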