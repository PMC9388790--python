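"""Shared fixtures: analytic oracles and (cached) synthetic cohorts with fits.

The closed-form solvers here are intentionally independent of the package's
integrators: they implement the integrating-factor solution of the linear
action ODE x' = -p2 x + d(t) segment by segment for piecewise-linear drives,
and serve as the oracle the simulation code is checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ogttmm import (  # noqa: E402
    GlycerolFitConfig,
    PopulationConfig,
    fit_glycerol,
    generate_cohort,
    make_forcing,
    truncate_record,
)
from ogttmm.preprocess import PROTOCOL_TIMES, find_glucose_nadir
from ogttmm.synthetic import noiseless


def exact_action_step(p2: float, drive: float, t: np.ndarray) -> np.ndarray:
    """Closed form for a constant drive: x(t) = (drive/p2)(1 - e^(-p2 t))."""
    return drive / p2 * (1.0 - np.exp(-p2 * t))


def exact_action_piecewise_linear(
    p2: float, knot_times: np.ndarray, knot_drive: np.ndarray, t_eval: np.ndarray
) -> np.ndarray:
    """Integrating-factor solution for a piecewise-linear drive.

    On each segment d(s) = a + b s the particular solution is
    (a + b s)/p2 - b/p2^2, and the homogeneous part decays as e^(-p2 s).
    Evaluation points must lie within the knot span.
    """
    out = np.empty(t_eval.size)
    order = np.argsort(t_eval)
    x = 0.0
    seg = 0
    for idx in order:
        t = t_eval[idx]
        while seg < knot_times.size - 1 and knot_times[seg + 1] <= t:
            x = _advance(p2, x, knot_times[seg], knot_times[seg + 1],
                         knot_drive[seg], knot_drive[seg + 1])
            seg += 1
        if t > knot_times[seg]:
            d1 = np.interp(t, knot_times, knot_drive)
            out[idx] = _advance(p2, x, knot_times[seg], t, knot_drive[seg], d1)
        else:
            out[idx] = x
    return out


def _advance(p2, x0, t0, t1, d0, d1):
    h = t1 - t0
    if h == 0:
        return x0
    b = (d1 - d0) / h
    a = d0
    xp0 = a / p2 - b / p2 ** 2
    xp1 = (a + b * h) / p2 - b / p2 ** 2
    return (x0 - xp0) * np.exp(-p2 * h) + xp1


def step_forcing(Ib: float = 26.0, c: float = 100.0, t_end: float = 360.0):
    """Constant forcing Ib + c: a step of excess insulin c for the whole run.

    Simulations start at t = 0 with zero action, so this realises the exact
    step-response experiment of the closed-form oracle.
    """
    return make_forcing(np.array([-20.0, t_end]), np.array([Ib + c, Ib + c]), Ib)


@pytest.fixture(scope="session")
def sip_forcing():
    """A realistic single-peak insulin forcing on the protocol grid."""
    t = PROTOCOL_TIMES
    Ib = 26.0
    pulse = 335.0 * np.where(t > 0, (t / 84.0) ** 3 * np.exp(3 * (1 - t / 84.0)), 0.0)
    return make_forcing(t, Ib + pulse, Ib)


@pytest.fixture(scope="session")
def cohort_noiseless():
    return generate_cohort(20, 101, noiseless())


@pytest.fixture(scope="session")
def cohort_noisy():
    return generate_cohort(20, 101, PopulationConfig())


def glycerol_fits_for(cohort, seed: int, n_restarts: int = 75):
    fits = []
    for i, (rec, truth) in enumerate(cohort):
        t_nadir = find_glucose_nadir(rec.times, rec.glucose)
        truncated = truncate_record(rec, t_nadir)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9, i)))
        fits.append((fit_glycerol(truncated, GlycerolFitConfig(n_restarts=n_restarts),
                                  rng=rng), truth))
    return fits


@pytest.fixture(scope="session")
def glycerol_recovery_noiseless(cohort_noiseless):
    return glycerol_fits_for(cohort_noiseless, seed=202)


@pytest.fixture(scope="session")
def glycerol_recovery_noisy(cohort_noisy):
    return glycerol_fits_for(cohort_noisy, seed=203)
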