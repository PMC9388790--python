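"""Synthetic OGTT cohort generator.

The study's clinical data sit behind a data-sharing agreement, so every
end-to-end exercise of the pipeline runs on synthetic participants whose
population statistics emulate the studied cohort of adolescent girls with
obesity and insulin resistance: fasting glucose ~90 mg/dL, fasting insulin
~26 uU/mL, fasting glycerol ~118 umol/L, insulin peaking near 361 uU/mL at
~84 min, and insulin-action time constants separated by about two orders of
magnitude between the glycerol and glucose systems.  Insulin excursions are
sums of gamma-density-shaped pulses — one for single-peak (SIP) phenotypes,
two (with the earlier pulse smaller) for double-peak (DIP) phenotypes.

Glucose is generated from the oral minimal model itself and glycerol from the
glycerol model, both driven by the piecewise-linear interpolation of the
noiseless protocol-grid insulin samples: the generating process lies inside
the fitted model family, so noiseless parameter recovery is well-posed.
Gaussian noise with per-analyte CV is added to all sampled analytes, clipped
at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .forcing import compute_basal, make_forcing
from .glycerol import GlycerolParams, simulate_glycerol
from .omm import DEFAULT_RA_BREAKPOINTS, DEFAULT_V, OMMParams, simulate_omm
from .preprocess import PROTOCOL_TIMES, OGTTRecord, find_glucose_nadir

logger = logging.getLogger(__name__)

#: reference Ra height profile (mg/kg/min) at the default knots; its area is
#: ~680 mg/kg, i.e. f*D/BW for a 75 g load, f = 0.87, at the cohort's weight
_RA_BASE_HEIGHTS = np.array([0.0, 2.1, 5.5, 4.6, 3.4, 2.5, 1.5, 0.85, 0.35, 0.0])


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level targets and dispersion for the generator (units in names)."""

    fasting_glucose_mean: float = 90.0       # mg/dL
    fasting_glucose_sd: float = 9.0
    fasting_insulin_mean: float = 26.0       # uU/mL
    fasting_insulin_sd: float = 15.0
    fasting_glycerol_mean: float = 118.0     # umol/L
    fasting_glycerol_sd: float = 26.0
    peak_insulin_mean: float = 361.0         # uU/mL
    peak_insulin_sd: float = 207.0
    peak_time_mean: float = 84.0             # min
    peak_time_sd: float = 47.0
    dip_fraction: float = 0.25               # share of double-insulin-peak phenotypes
    insulin_sensitivity_mean: float = 2.9e-4  # dL/kg/min per uU/mL
    insulin_sensitivity_sd: float = 2.4e-4
    SG_median: float = 0.019                 # 1/min
    SG_gsd: float = 1.25
    p2G_median: float = 0.006                # 1/min
    p2G_log10_sd: float = 0.12
    p2_ratio: float = 100.0                  # p2g / p2G separation
    Sg_median: float = 0.045                 # 1/min
    Sg_gsd: float = 1.3
    X2_median: float = 40.0                  # uU/mL
    X2_gsd: float = 1.5
    suppressible_fraction_range: tuple[float, float] = (0.5, 0.8)
    ra_scale_gsd: float = 1.2
    V: float = DEFAULT_V
    noise_cv: dict = field(
        default_factory=lambda: {"glucose": 0.02, "insulin": 0.07, "glycerol": 0.07}
    )
    hypoglycemia_fraction: float = 0.10      # deep-nadir participants (exercise truncation)
    hypoglycemia_si_boost: float = 2.5
    pulse_shape: float = 3.0                 # gamma-pulse sharpness
    redraw_cap: int = 25


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated participant."""

    omm_params: OMMParams
    glycerol_params: GlycerolParams
    insulin_shape: str                        # "SIP" or "DIP"
    pulse_amplitudes: tuple[float, ...]       # uU/mL above basal
    pulse_centers: tuple[float, ...]          # min
    pulse_shapes: tuple[float, ...]
    Ib: float
    Gb: float
    gb: float
    noise_cv: dict
    rng_seed: int
    hypoglycemia: bool = False


def _lognormal_from_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def _gamma_pulse(t, amp: float, center: float, shape: float):
    """Smooth nonnegative right-skewed pulse peaking at ``center`` with value ``amp``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    z = t[pos] / center
    out[pos] = amp * z ** shape * np.exp(shape * (1.0 - z))
    return out


def generate_insulin_curve(truth: SyntheticTruth, grid) -> np.ndarray:
    """Dense insulin series: Ib plus the participant's pulse sum (Ib before t=0)."""
    grid = np.asarray(grid, dtype=float)
    curve = np.full(grid.shape, truth.Ib, dtype=float)
    for amp, c, s in zip(truth.pulse_amplitudes, truth.pulse_centers, truth.pulse_shapes):
        if amp < 0:
            raise ValueError("pulse amplitudes must be nonnegative")
        curve += _gamma_pulse(grid, amp, c, s)
    if np.any(curve < 0):
        raise ValueError("insulin curve went negative")
    return curve


def _count_local_maxima(y: np.ndarray) -> int:
    d = np.diff(y)
    return int(np.sum((d[:-1] > 0) & (d[1:] < 0)))


def _draw_truth(rng: np.random.Generator, cfg: PopulationConfig, seed: int) -> SyntheticTruth:
    Gb = _lognormal_from_moments(rng, cfg.fasting_glucose_mean, cfg.fasting_glucose_sd)
    Ib = _lognormal_from_moments(rng, cfg.fasting_insulin_mean, cfg.fasting_insulin_sd)
    gb = _lognormal_from_moments(rng, cfg.fasting_glycerol_mean, cfg.fasting_glycerol_sd)
    Ib = max(Ib, 5.0)

    shape = "DIP" if rng.uniform() < cfg.dip_fraction else "SIP"
    peak = _lognormal_from_moments(rng, cfg.peak_insulin_mean, cfg.peak_insulin_sd)
    peak = max(peak, Ib + 60.0)
    t_peak = float(np.clip(
        _lognormal_from_moments(rng, cfg.peak_time_mean, cfg.peak_time_sd), 40.0, 200.0
    ))
    amp_main = peak - Ib
    if shape == "DIP":
        amp2 = amp_main * rng.uniform(0.25, 0.45)
        t2 = t_peak * rng.uniform(0.25, 0.4)
        amps = (amp2, amp_main)
        centers = (t2, t_peak)
        shapes = (8.0, cfg.pulse_shape + 2.0)
    else:
        amps = (amp_main,)
        centers = (t_peak,)
        shapes = (cfg.pulse_shape,)

    hypo = rng.uniform() < cfg.hypoglycemia_fraction
    SG = float(np.clip(_lognormal_from_moments(
        rng, cfg.SG_median, cfg.SG_median * (cfg.SG_gsd - 1.0)), 0.008, 0.05))
    p2G = float(10 ** rng.normal(np.log10(cfg.p2G_median), cfg.p2G_log10_sd))
    SI = _lognormal_from_moments(rng, cfg.insulin_sensitivity_mean, cfg.insulin_sensitivity_sd)
    if hypo:
        SI *= cfg.hypoglycemia_si_boost
    p3 = SI * p2G / cfg.V
    ra_scale = _lognormal_from_moments(rng, 1.0, cfg.ra_scale_gsd - 1.0)
    omm = OMMParams(
        SG=SG, p2G=p2G, p3=p3, V=cfg.V,
        ra_breakpoints=DEFAULT_RA_BREAKPOINTS.copy(),
        ra_heights=_RA_BASE_HEIGHTS * ra_scale,
    )

    p2g = float(min(cfg.p2_ratio * p2G, 0.98))
    Sg = float(np.clip(_lognormal_from_moments(
        rng, cfg.Sg_median, cfg.Sg_median * (cfg.Sg_gsd - 1.0)), 0.015, 0.2))
    frac = rng.uniform(*cfg.suppressible_fraction_range)
    production = Sg * gb                       # fasted steady state (l0 + l2)/Sg = gb
    gly = GlycerolParams(
        Sg=Sg, l0=(1.0 - frac) * production, l2=frac * production,
        X2=float(np.clip(_lognormal_from_moments(
            rng, cfg.X2_median, cfg.X2_median * (cfg.X2_gsd - 1.0)), 8.0, 300.0)),
        p2g=p2g,
    )
    return SyntheticTruth(
        omm_params=omm, glycerol_params=gly, insulin_shape=shape,
        pulse_amplitudes=amps, pulse_centers=centers, pulse_shapes=shapes,
        Ib=Ib, Gb=Gb, gb=gb, noise_cv=dict(cfg.noise_cv), rng_seed=seed,
        hypoglycemia=hypo,
    )


def generate_participant(
    rng: np.random.Generator,
    config: PopulationConfig | None = None,
    participant_id: str = "synthetic",
    seed: int = 0,
) -> tuple[OGTTRecord, SyntheticTruth]:
    """Draw one participant, forward-simulate both models, sample and add noise.

    Re-draws (capped) when the simulated glucose lacks a post-drink excursion
    with a usable nadir, or when a DIP draw fails to produce two local maxima.
    """
    cfg = config or PopulationConfig()
    times = PROTOCOL_TIMES.copy()
    dense = np.arange(0.0, times[-1] + 1.0)
    for attempt in range(cfg.redraw_cap):
        truth = _draw_truth(rng, cfg, seed)
        curve = generate_insulin_curve(truth, dense)
        if truth.insulin_shape == "DIP" and _count_local_maxima(curve) != 2:
            continue
        ins_samples = np.where(times < 0, truth.Ib, np.interp(times, dense, curve))
        forcing = make_forcing(times, ins_samples, truth.Ib)
        glucose, _ = simulate_omm(truth.omm_params, forcing, truth.Gb, dense)
        gly, _ = simulate_glycerol(truth.glycerol_params, forcing, truth.gb, dense)
        glu_samples = np.where(times < 0, truth.Gb, np.interp(times, dense, glucose))
        gly_samples = np.where(times < 0, truth.gb, np.interp(times, dense, gly))

        cv = truth.noise_cv
        noisy = {}
        for name, clean in (("glucose", glu_samples), ("insulin", ins_samples),
                            ("glycerol", gly_samples)):
            c = cv.get(name, 0.0)
            noisy[name] = np.maximum(clean * (1.0 + c * rng.standard_normal(clean.size)), 0.0)

        try:
            record = OGTTRecord(
                participant_id=participant_id,
                times=times,
                glucose=noisy["glucose"],
                insulin=noisy["insulin"],
                glycerol=noisy["glycerol"],
                Gb=compute_basal(times, noisy["glucose"]),
                Ib=compute_basal(times, noisy["insulin"]),
                gb=compute_basal(times, noisy["glycerol"]),
            )
            t_nadir = find_glucose_nadir(record.times, record.glucose)
        except ValueError:
            continue
        if t_nadir < 45.0:   # need >= 4 glycerol samples inside the fitting window
            continue
        return record, truth
    raise RuntimeError(f"no valid glucose excursion after {cfg.redraw_cap} redraws")


def generate_cohort(
    n: int,
    master_seed: int,
    config: PopulationConfig | None = None,
) -> list[tuple[OGTTRecord, SyntheticTruth]]:
    """n independent participants with deterministically derived sub-seeds.

    Participant i is a pure function of (master_seed, i): growing the cohort
    leaves earlier participants unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or PopulationConfig()
    children = np.random.SeedSequence(master_seed).spawn(n)
    cohort = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        rec, truth = generate_participant(
            rng, cfg, participant_id=f"S{i:03d}", seed=master_seed
        )
        cohort.append((rec, truth))
    return cohort


def noiseless(config: PopulationConfig | None = None) -> PopulationConfig:
    """Copy of ``config`` with all measurement noise switched off."""
    cfg = config or PopulationConfig()
    return replace(cfg, noise_cv={"glucose": 0.0, "insulin": 0.0, "glycerol": 0.0})
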