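# Methods

## Models and assumptions

Both models treat measured serum insulin as a known forcing function — there
is no insulin-secretion feedback.  Insulin samples are interpolated linearly
(the standard minimal-model choice; a monotone-cubic alternative is exposed
via `InsulinForcing(kind="pchip")`), held constant outside the sampling
window, and the basal level `Ib` is the mean of the −20, −10 and 0 min
samples.  The same pre-drink averaging is applied to glucose and glycerol
basals; only insulin's rule is dictated by the protocol description, so the
choice for the other two analytes is configurable.

The piecewise action equations (decay only below basal insulin, decay plus
drive above) are implemented as the single clipped form
`x' = -p2 x + gain (I - Ib)+`, which is identical trajectory-wise and keeps
the right-hand side event-free.  In the glucose model the gain is `p3`; in
the glycerol model the time constant `p2g` multiplies the drive as well, so
the action state carries insulin units and a sustained excess `c` drives it
to the plateau `c`.

The glycerol model assumes the fasted state realises the *maximum* lipolysis
rate `l0 + l2`: it cannot raise glycerol above basal, which is why each
record is truncated at the post-excursion glucose nadir (found on the
measured samples — the earliest minimum strictly after the post-drink
maximum) before fitting.  The glucose model is fit on the full 6-h window.
The initial glycerol value is the basal glycerol (configurable to the t = 0
sample); basal start is the only state consistent with `Xg(0) = 0`.

## Parameters

| parameter | units | role | default / bound |
|---|---|---|---|
| `SG` | 1/min | glucose effectiveness | fit, [0, 0.15] |
| `p2G` | 1/min | glucose action time constant | fit, [1e-6, 1] |
| `p3` | 1/min² per uU/mL | action gain | fit, [0, 1e-3] |
| `V` | dL/kg | glucose distribution volume | fixed 1.45 |
| `α` | mg/kg/min | Ra knot heights | fit, ≥ 0, knots {0,10,30,60,90,120,180,240,300,360} min |
| `Sg` | 1/min | glycerol uptake effectiveness | fit, [0, 1] |
| `l0`, `l2` | umol/L/min | insulin-independent / suppressible lipolysis | fit, ≥ 0 |
| `X2` | uU/mL | half-suppression action scale | fit, > 0 |
| `p2g` | 1/min | glycerol action time constant | fit, [0, 1] |
| `A` | — | Hill exponent | fixed 2 |

`V` is fixed because `V` and `p3` are jointly unidentifiable from OGTT data;
`A` is fixed because the fit is insensitive to it.  Seed ranges: `Sg`, `p2g`
uniform in [0, 1]; the lipolysis-side seeds (`l0` in [0, 20], `l2` in
[0, 40] umol/L/min, `X2` in [0, 400] uU/mL) bracket roughly 0–200% of
plausible cohort values and are implementer defaults exposed in config.  No
equality constraint `l0 + l2 = Sg·gb` is imposed by default (a config flag
enables it for identifiability experiments).

## Fitting

Each fit minimises `Σ(data_i − model_i)² / variance`.  The variance is
computed once per participant: the data are embedded in their Hankel
trajectory matrix (window `floor(n/2)`, the common SSA default that
maximises trajectory-matrix rank), the leading singular component is kept and
anti-diagonal-averaged back into a smooth series, and the variance is the
squared population standard deviation of the squared residuals about that
smooth curve.  That formula is implemented literally as stated; because it
may be a misstatement of the ordinary residual variance, a
`variance_mode="residual"` alternative (std(residual)²) is available.  A
floor (default 1e-8) keeps the objective defined for noiseless data.

The multistart engine draws 75 uniform seed vectors (re-drawing any seed
whose initial model state is invalid, capped at 1000 retries), runs L-BFGS-B
from each, logs every restart, and keeps the lowest-objective solution.  All
randomness flows from one master seed via `numpy` seed sequences, so the
whole ensemble is reproducible and per-participant streams are stable as the
cohort grows.

The OMM fit uses variable projection: for fixed `(SG, p2G, p3)` the glucose
trajectory is affine in the Ra heights, which are solved by nonnegative least
squares inside the outer search.  The outer parameters are optimised on
scaled axes (typical magnitudes 0.02, 0.01, 1e-6) so finite-difference
gradients are well conditioned.  By default the OMM objective adds weakly
informative MAP penalties on `log10 SG` (centre −1.72, sd 0.3) and
`log10 p2G` (centre −2, sd 0.5): with nine free Ra heights the action time
constant is nearly flat in the likelihood for noisy OGTT glucose, and
regularising it is standard minimal-model practice.  `map_priors=False`
gives the pure weighted-least-squares fit (used, e.g., for noiseless
parameter-recovery checks, which it passes to well under 1%).

An optional equality constraint `AUC(Ra) = f·D/BW` (f = 0.87) is folded into
the height projection as a weighted row when dose and body weight are
supplied; it is off by default because the synthetic cohort does not carry
body weights.

## Numerics

Public simulation (`simulate_omm`, `simulate_glycerol`) integrates with
LSODA at absolute tolerance 1e-10 (relative 1e-9), restarted at every
forcing/Ra knot so the piecewise-linear kinks never sit inside a solver step.
Inside the fitting objective, the action state is propagated with the exact
integrating-factor recurrence for piecewise-linear drive on a 0.25-min grid
(an IIR filter pass), and the metabolite with an exact-linear-source
recurrence (glycerol) or an affine RK4 sweep advancing all Ra basis responses
together (glucose, 0.5-min steps).  The two routes agree to ~1e-6 on the
data scale; tests cross-check them against closed-form solutions.  Dense
action profiles for the metrics are computed analytically on a 1-min grid
(4× internal refinement), well under the 10–15 min sampling interval, XG
over the full 6-h window and Xg over the truncated window, each normalised
by its own maximum.  Peak ties break to the earliest time; the insulin peak
is taken on measured samples, matching how a cohort peak-time descriptive is
tabulated.

Degenerate inputs are handled explicitly: a glucose peak on the final sample
raises "no nadir"; an all-zero action profile is an error (`peak_time`), and
the pipeline quarantines such participants with the reason rather than
aborting the cohort; Wilcoxon tests on all-zero paired differences report
p = 1 with a flag; zero-variance t-tests are flagged NaN.

## Synthetic cohort

The generator emulates the studied population (obese, insulin-resistant
adolescent girls): fasting glucose 90 ± 9 mg/dL, fasting insulin 26 ± 15
uU/mL, fasting glycerol 118 ± 26 umol/L, insulin peak 361 ± 207 uU/mL at
84 ± 47 min, insulin sensitivity 2.9e-4 dL/kg/min per uU/mL; per-participant
values are log-normal (moment-matched) for positivity and right skew.
Insulin excursions are gamma-density-shaped pulses — one for single-peak
(SIP) phenotypes, two with the earlier pulse smaller for double-peak (DIP,
25% of draws).  Glucose is generated from the OMM itself and glycerol from
the glycerol model (both driven by the interpolated noiseless protocol-grid
insulin samples), so noiseless refitting is a well-posed recovery problem;
the glycerol parameters satisfy `(l0 + l2)/Sg = gb` so records start at the
fasted steady state.  The glycerol time constant is `p2g = 100·p2G` (capped
at 0.98), encoding the two-order-of-magnitude separation under study.
Gaussian noise with CV 2% (glucose) / 7% (insulin) / 7% (glycerol) is added
and clipped at zero; real assay noise magnitudes are not published for this
protocol, so these are implementer choices exposed in config.  About 10% of
draws get a 2.5× insulin-sensitivity boost to produce deep sub-basal glucose
nadirs, exercising the truncation path.  Draws without a usable excursion
(no nadir, or nadir before 45 min) are rejected and redrawn, capped at 25.

What the generator does *not* emulate: the post-nadir glycerol rebound and
counterregulatory response (excluded by the model's own truncation), incretin
effects, the fructose component of the drink, assay-specific error
structure, and PCOS/medication subgroup structure.  Passing tests therefore
demonstrate internal consistency of the method and the direction of the
timing effect under the stated population — not clinical validity on real
records.

## Known limitations

- Under measurement noise the glycerol fit has a degenerate mode
  (`X2 → 0`, `p2g → 0`: suppression becomes an immediate step) that can
  genuinely attain a lower objective for some noise draws; affected
  participants show `log10 p2g` outliers or are quarantined when the fitted
  action is identically zero.  Cohort statistics are rank-based or
  median-based partly for this reason.
- `p2G` is not identifiable from noisy OGTT glucose with a fully flexible
  piecewise-linear Ra; the default MAP penalty concentrates its posterior
  near the prior centre, so cohort dispersion of `log10 p2G` under noise
  mostly reflects the prior, not the data.
- Analysis-scale runs use 20-participant cohorts and 75 restarts; the study
  sizes are stated in the analysis scripts and can be raised freely.
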