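"""Compute insulin-action dynamics metrics and cohort statistics.

Runs the full pipeline (fits + dense action profiles + the three metrics) on
the simulated cohort and writes results/metrics.csv and
results/cohort_stats.json.  The headline comparison: insulin action on
glycerol peaks earlier and tracks plasma insulin more closely than insulin
action on glucose, visible in the positive peak gap, the positive normalised
nadir gap, and the separation of log10 time constants.
"""

import argparse
from pathlib import Path

from ogttmm.io import RunConfig
from ogttmm.pipeline import run_pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--n", type=int, default=20)
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = RunConfig(n_synthetic=args.n, master_seed=args.seed, output_dir=str(args.out))
res = run_pipeline(cfg)
s = res.stats
print(f"cohort n = {s.n}; quarantined: {list(res.quarantined) or 'none'}")
print(f"peak gap (glucose - glycerol action peak): "
      f"{s.ttest_peak_gap[2]:.2f} +/- {s.ttest_peak_gap[3]:.2f} min (95% CI), "
      f"t-test p = {s.ttest_peak_gap[1]:.2g}")
print(f"nadir gap (normalised action difference):  "
      f"{s.ttest_nadir_gap[2]:.4f} +/- {s.ttest_nadir_gap[3]:.4f} (95% CI), "
      f"t-test p = {s.ttest_nadir_gap[1]:.2g}")
print(f"Wilcoxon |delay| glucose vs glycerol: p = {s.wilcoxon_delays[1]:.2g}")
print(f"Wilcoxon log10(p2G) vs log10(p2g):    p = {s.wilcoxon_log_p2[1]:.2g}")
print(f"wrote {args.out / 'metrics.csv'} and {args.out / 'cohort_stats.json'}")
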