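"""Score categorical phenotypes and compare groups statistically.

Simulates three batches of 20 larvae per condition scored for sideways
floating, runs the pooled chi-square comparing Mn-treated with
recovered larvae, then compares simulated LAM-duration samples with
the Wilcoxon rank-sum test (Bonferroni-corrected) and demonstrates the
Lilliefors-gated choice between repeated-measures ANOVA and the
Friedman test on paired intensity data.
"""

import numpy as np

from larvamotor.group_stats import (
    chi_square_counts,
    gated_paired_test,
    rank_sum_bonferroni,
)
from larvamotor.synthetic import BehaviorCountParams, simulate_behavior_counts

# -- phenotype counts: Mn-treated vs recovered sideways floating ---------
tables = simulate_behavior_counts(
    BehaviorCountParams(conditions=("mn", "recovered"), seed=6)
)
table = tables["sideways_floating"]
res = chi_square_counts(table)  # pooled 2x2, df = 1
pooled = table.pooled()
print(f"sideways floating: {pooled.affected[0]}/{pooled.totals[0]} Mn vs "
      f"{pooled.affected[1]}/{pooled.totals[1]} recovered")
print(f"  chi-square = {res.statistic:.1f}, df = {res.df}, p = {res.p:.3g}")

# -- LAM durations: control vs Mn-treated vs recovered -------------------
rng = np.random.default_rng(6)
durations = {
    "control": np.maximum(rng.normal(57.0, 15.0, 12), 5.0),
    "mn": np.maximum(rng.normal(163.4, 40.0, 12), 5.0),
    "recovered": np.maximum(rng.normal(54.7, 14.0, 12), 5.0),
}
pairs = [("control", "mn"), ("control", "recovered")]
for r in rank_sum_bonferroni(durations, pairs):
    print(f"  rank-sum {r.pair[0]} vs {r.pair[1]}: U = {r.statistic:.0f}, "
          f"adjusted p = {r.p_adjusted:.3g}")

# -- paired ROI intensities: normality-gated test -------------------------
intensities = {
    "control": rng.normal(100.0, 10.0, 16),
    "treated": rng.normal(80.0, 10.0, 16),
}
gated = gated_paired_test(intensities)
print(f"  paired intensities: normality gate selected {gated.test}, "
      f"statistic = {gated.statistic:.2f}, p = {gated.p:.3g}")
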