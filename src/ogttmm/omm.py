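"""Oral Minimal Model (OMM) of OGTT glucose dynamics.

State equations, with measured insulin I(t) as a known forcing:

    dG/dt  = -(SG + XG) G + SG Gb + Ra_meal(alpha, t) / V
    dXG/dt = -p2G XG + p3 (I(t) - Ib)+          XG(0) = 0, G(0) = Gb

G is plasma glucose (mg/dL), XG the insulin action on glucose (1/min), SG the
glucose effectiveness (1/min), p2G the action time constant (1/min), p3 the
action gain, and Ra_meal a piecewise-linear meal rate of appearance (mg/kg/min)
over fixed knot times with estimated heights alpha.  V (dL/kg) is fixed: V and
p3 are jointly unidentifiable from OGTT data alone.  Insulin sensitivity is
the minimal-model identity SI = V p3 / p2G.

Fitting uses variable projection: for fixed (SG, p2G, p3) the glucose
trajectory is affine in the Ra heights, which are therefore solved by
nonnegative least squares inside a multistart search over the three dynamic
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

from ._integrate import affine_rk4, pl_lowpass, solve_piecewise
from .actions import ActionProfile
from .fitting import FitProblem, FitResult, multistart_fit
from .forcing import InsulinForcing, make_forcing
from .preprocess import OGTTRecord
from .ssa import ObjectiveContext

#: glucose distribution volume, dL/kg (standard minimal-model convention)
DEFAULT_V = 1.45
#: Ra knot times, minutes (protocol-aligned)
DEFAULT_RA_BREAKPOINTS = np.array([0.0, 10, 30, 60, 90, 120, 180, 240, 300, 360])

SOLVER_ABS_TOL = 1e-10
SOLVER_REL_TOL = 1e-9


@dataclass(frozen=True)
class OMMParams:
    SG: float                      # glucose effectiveness, 1/min
    p2G: float                     # insulin-action time constant, 1/min
    p3: float                      # action gain, (1/min^2) per (uU/mL)
    V: float = DEFAULT_V           # distribution volume, dL/kg
    ra_breakpoints: np.ndarray = field(default_factory=lambda: DEFAULT_RA_BREAKPOINTS.copy())
    ra_heights: np.ndarray = field(default_factory=lambda: np.zeros(DEFAULT_RA_BREAKPOINTS.size))

    def __post_init__(self) -> None:
        bp = np.asarray(self.ra_breakpoints, dtype=float)
        h = np.asarray(self.ra_heights, dtype=float)
        if bp.shape != h.shape:
            raise ValueError("ra_breakpoints and ra_heights must align")
        if bp[0] != 0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing and start at 0")
        if h[0] != 0:
            raise ValueError("ra_heights[0] must be 0 (no appearance at t = 0)")
        for name in ("SG", "p2G", "p3", "V"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.p2G > 1:
            raise ValueError("p2G must not exceed 1")
        if np.any(h < 0):
            raise ValueError("ra_heights must be nonnegative")
        object.__setattr__(self, "ra_breakpoints", bp)
        object.__setattr__(self, "ra_heights", h)


def ra_meal(params: OMMParams, t):
    """Piecewise-linear meal rate of appearance; last height held beyond the last knot."""
    return np.interp(t, params.ra_breakpoints, params.ra_heights)


def simulate_omm(
    params: OMMParams,
    forcing: InsulinForcing,
    Gb: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, ActionProfile]:
    """Integrate the two-state OMM with a stiff-capable solver (atol 1e-10).

    Returns the glucose trajectory on ``grid`` and the XG action profile.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0:
        raise ValueError("grid must start at 0 (drink ingestion)")

    def rhs(t, y):
        G, XG = y
        return (
            -(params.SG + XG) * G + params.SG * Gb + ra_meal(params, t) / params.V,
            -params.p2G * XG + params.p3 * forcing.excess(t),
        )

    knots = np.concatenate([forcing.times, params.ra_breakpoints])
    try:
        y = solve_piecewise(rhs, grid, [Gb, 0.0], knots,
                            atol=SOLVER_ABS_TOL, rtol=SOLVER_REL_TOL)
    except RuntimeError as exc:
        raise RuntimeError(f"OMM solver failed with params {params} on grid "
                           f"[{grid[0]}, {grid[-1]}]: {exc}") from exc
    XG = np.maximum(y[1], 0.0)
    XG[0] = 0.0
    return y[0], ActionProfile(grid=grid, values=XG, label="glucose")


def insulin_sensitivity(params: OMMParams) -> float:
    """SI = V p3 / p2G, dL/kg/min per uU/mL."""
    if params.p2G == 0:
        raise ValueError("unidentifiable SI: p2G = 0")
    return params.V * params.p3 / params.p2G


@dataclass(frozen=True)
class OMMFitConfig:
    V: float = DEFAULT_V
    ra_breakpoints: np.ndarray = field(default_factory=lambda: DEFAULT_RA_BREAKPOINTS.copy())
    n_restarts: int = 75
    # outer-parameter boxes: (SG, p2G, p3)
    bounds: tuple = ((0.0, 0.15), (1e-6, 1.0), (0.0, 1e-3))
    seed_ranges: tuple = ((0.001, 0.05), (1e-4, 0.1), (1e-8, 2e-5))
    # typical magnitudes used to condition the search (finite differences are
    # taken on parameters of order one)
    scales: tuple = (0.02, 0.01, 1e-6)
    # weakly informative MAP priors on log10(SG) and log10(p2G): with a
    # piecewise-linear Ra this flexible, the action time constant is nearly
    # unidentifiable from noisy OGTT glucose alone, and minimal-model practice
    # regularises it; disable for pure weighted-least-squares estimation
    map_priors: bool = True
    prior_log10_SG: tuple = (-1.72, 0.3)     # centre log10(0.019 / min)
    prior_log10_p2G: tuple = (-2.0, 0.5)     # centre log10(0.01 / min)
    grid_step: float = 0.5
    window_length: int | None = None
    variance_floor: float = 1e-8
    variance_mode: str = "literal"
    # optional AUC(Ra) = f * dose / body weight equality, enforced as a penalty
    f_absorbed: float = 0.87
    dose_mg: float | None = None
    body_weight_kg: float | None = None
    auc_penalty: float = 1e4


class _VarProSimulator:
    """Prediction at glucose sample times as a function of (SG, p2G, p3).

    Precomputes the excess-insulin drive and Ra tent bases on a fine grid;
    each call propagates XG exactly, then advances the basal response and all
    tent responses with one affine-RK4 pass, and projects the heights by NNLS.
    """

    def __init__(self, record: OGTTRecord, config: OMMFitConfig, forcing: InsulinForcing):
        post = record.times >= 0
        self.t_data = record.times[post]
        self.y_data = record.glucose[post]
        keep = np.isfinite(self.y_data)
        self.t_data, self.y_data = self.t_data[keep], self.y_data[keep]
        self.Gb = record.Gb
        self.config = config
        t_end = self.t_data[-1]
        self.h = config.grid_step
        n_steps = int(round(t_end / self.h))
        self.fine = np.linspace(0.0, t_end, 2 * n_steps + 1)   # half-step grid
        self.grid = self.fine[::2]
        self.excess_fine = forcing.excess(self.fine)
        bp = np.asarray(config.ra_breakpoints, dtype=float)
        self.bp = bp[bp <= t_end]
        # tent basis for each estimated knot (all but the zero-clamped first)
        m = self.bp.size - 1
        self.tents = np.empty((self.fine.size, m))
        for j in range(1, self.bp.size):
            heights = np.zeros(self.bp.size)
            heights[j] = 1.0
            self.tents[:, j - 1] = np.interp(self.fine, self.bp, heights)
        self.last_heights: np.ndarray | None = None

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        SG, p2G, p3 = theta
        XG = pl_lowpass(p2G, p3 * self.excess_fine, self.h / 2.0)
        a = SG + XG
        sources = np.empty((self.fine.size, 1 + self.tents.shape[1]))
        sources[:, 0] = SG * self.Gb
        sources[:, 1:] = self.tents / self.config.V
        x0 = np.zeros(sources.shape[1])
        x0[0] = self.Gb
        traj = affine_rk4(a, sources, self.h, x0)          # (n_grid, 1+m)
        at_data = np.empty((self.t_data.size, traj.shape[1]))
        for j in range(traj.shape[1]):
            at_data[:, j] = np.interp(self.t_data, self.grid, traj[:, j])
        base = at_data[:, 0]
        M = at_data[:, 1:]
        cfg = self.config
        if cfg.dose_mg is not None and cfg.body_weight_kg is not None:
            # fold the AUC equality in as an extra weighted row
            target = cfg.f_absorbed * cfg.dose_mg / cfg.body_weight_kg
            w = np.sqrt(cfg.auc_penalty)
            auc_row = np.array(
                [np.trapezoid(self.tents[:, j], self.fine) for j in range(M.shape[1])]
            )
            M_aug = np.vstack([M, w * auc_row])
            r_aug = np.concatenate([self.y_data - base, [w * target]])
            heights, _ = nnls(M_aug, r_aug)
        else:
            heights, _ = nnls(M, self.y_data - base)
        self.last_heights = heights
        return base + M @ heights

    def params_from(self, theta: np.ndarray) -> OMMParams:
        pred = self(theta)  # refresh heights for this theta
        del pred
        heights = np.zeros(self.bp.size)
        heights[1:] = self.last_heights
        return OMMParams(
            SG=float(theta[0]), p2G=float(theta[1]), p3=float(theta[2]),
            V=self.config.V, ra_breakpoints=self.bp.copy(), ra_heights=heights,
        )


def fit_omm(
    record: OGTTRecord,
    config: OMMFitConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> FitResult:
    """Multistart fit of {SG, p2G, p3, ra_heights} to the full 6-h record.

    The SSA-weighted objective (see :mod:`ogttmm.ssa`) is evaluated at the
    post-drink glucose samples; Ra heights are profiled out by NNLS.
    """
    config = config or OMMFitConfig()
    post = record.times >= 0
    if int(np.sum(np.isfinite(record.glucose[post]))) < 8:
        raise ValueError("insufficient data: need at least 8 post-drink glucose samples")
    forcing = _record_forcing(record)
    sim = _VarProSimulator(record, config, forcing)
    ctx = ObjectiveContext.from_data(
        sim.y_data, window_length=config.window_length,
        floor=config.variance_floor, mode=config.variance_mode,
    )
    scales = np.asarray(config.scales, dtype=float)
    problem = FitProblem(
        simulate=lambda z: sim(z * scales),
        bounds=[(lo / s, hi / s) for (lo, hi), s in zip(config.bounds, scales)],
        seed_ranges=[(lo / s, hi / s) for (lo, hi), s in zip(config.seed_ranges, scales)],
        objective=ctx,
        names=("SG", "p2G", "p3"),
        validate=lambda z: bool(np.all(np.isfinite(z))),
    )
    if config.map_priors:
        base_objective = problem.objective_of
        (mu_sg, sd_sg), (mu_p2, sd_p2) = config.prior_log10_SG, config.prior_log10_p2G

        def map_objective(z):
            x = np.maximum(np.asarray(z) * scales, 1e-12)
            prior = (((np.log10(x[0]) - mu_sg) / sd_sg) ** 2
                     + ((np.log10(x[1]) - mu_p2) / sd_p2) ** 2)
            return base_objective(z) + prior

        problem.objective_of = map_objective  # type: ignore[method-assign]
    scaled = multistart_fit(
        problem, n_restarts=config.n_restarts, rng=rng,
        window=(float(sim.t_data[0]), float(sim.t_data[-1])),
    )
    result = FitResult(
        best_params=scaled.best_params * scales,
        best_objective=scaled.best_objective,
        restarts=[
            replace(r, seed_params=r.seed_params * scales, params=r.params * scales)
            for r in scaled.restarts
        ],
        rng_seed=scaled.rng_seed,
        names=scaled.names,
        window=scaled.window,
    )
    params = sim.params_from(result.best_params)
    result.extra["params"] = params
    result.extra["ra_heights"] = params.ra_heights
    result.extra["SI"] = insulin_sensitivity(params) if params.p2G > 0 else np.nan
    return result


def _record_forcing(record: OGTTRecord) -> InsulinForcing:
    keep = np.isfinite(record.insulin)
    return make_forcing(record.times[keep], record.insulin[keep], record.Ib)
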