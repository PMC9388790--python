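# ogttmm — tissue-specific insulin action dynamics from OGTT time series

During an oral glucose tolerance test (OGTT), insulin acts on muscle and
liver (clearing glucose) and on adipose tissue (suppressing lipolysis, hence
plasma glycerol).  This package models both arms from the same frequently
sampled OGTT record and asks a timing question: does insulin action on
adipose tissue lead or lag insulin action on glucose?

It is written for metabolic-physiology modellers: the library under
`src/ogttmm/` implements the models, fitting machinery and metrics; the
numbered scripts under `analysis/` run the study end to end on a synthetic
cohort (the motivating clinical data sit behind a data-sharing agreement, so
a calibrated generator stands in for them).

## Models

**Oral minimal model (OMM)** for glucose `G` (mg/dL), driven by measured
insulin `I(t)` through a latent insulin-action state `X_G`:

    dG/dt   = -(S_G + X_G) G + S_G G_b + Ra_meal(α, t) / V
    dX_G/dt = -p_2G X_G + p_3 (I(t) - I_b)_+        G(0) = G_b, X_G(0) = 0

with glucose effectiveness `S_G` (1/min), action time constant `p_2G`
(1/min), gain `p_3`, fixed distribution volume `V` = 1.45 dL/kg, and a
piecewise-linear meal rate of appearance `Ra` with estimated knot heights.
Insulin sensitivity is the minimal-model identity `S_I = V p_3 / p_2G`.

**Glycerol–insulin model** for glycerol `g` (umol/L), in which insulin action
`X_g` *suppresses* lipolysis through a falling Hill function:

    dg/dt   = -S_g g + l_0 + l_2 / (1 + (X_g / X_2)^A)
    dX_g/dt = -p_2g X_g + p_2g (I(t) - I_b)_+       X_g(0) = 0

Lipolysis falls from its fasted maximum `l_0 + l_2` to the floor `l_0` as
action rises past the half-suppression scale `X_2`; the Hill exponent `A` is
fixed at 2.  Records are truncated at the post-excursion glucose nadir before
fitting, because the model cannot produce glycerol above basal (the
counterregulatory rebound is out of scope).

Both models are fit per participant by 75-restart multistart bound-constrained
optimisation of a weighted least-squares objective whose variance comes from a
rank-1 singular-spectrum-analysis smoothing of the data.  Three metrics then
compare the dense action profiles: peak delays behind the measured insulin
peak, the glucose-minus-glycerol action peak gap, and the difference of
peak-normalised actions at the glucose nadir; time constants are compared as
`log10 p_2G` vs `log10 p_2g` (Wilcoxon signed-rank), the gaps against zero
(one-sample t).

## Worked example

```
python analysis/01_simulate_cohort.py --n 20 --seed 11
python analysis/03_action_metrics.py --n 20 --seed 11
```

prints (abridged; the full run takes a few minutes):

```
cohort n = 18; quarantined: ['S007', 'S008']
peak gap (glucose - glycerol action peak): 38.44 +/- 17.16 min (95% CI), t-test p = 0.00019
nadir gap (normalised action difference):  0.2337 +/- 0.0999 (95% CI), t-test p = 0.00013
Wilcoxon |delay| glucose vs glycerol: p = 0.005
Wilcoxon log10(p2G) vs log10(p2g):    p = 0.014
```

Read: across the refitted cohort, insulin action on glucose peaks ~40 min
later than insulin action on glycerol, glucose action is still near its peak
at the glucose nadir while glycerol action has largely decayed, and the two
action time constants differ by orders of magnitude — adipose tissue responds
to insulin faster than the glucose-handling tissues.  Participants whose
noisy record drives the fit into a degenerate zero-action mode are
quarantined and reported, not silently dropped.

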