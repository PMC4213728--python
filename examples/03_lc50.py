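"""Estimate an LC50 from an endpoint dose-survival table.

Draws binomial survival counts (20 larvae per dose) from a
log-logistic dose-response with a true LC50 of 2 mM, then estimates
the LC50 by log-linear interpolation and by the two-parameter logistic
maximum-likelihood fit.  Both estimates should land near 2 mM; the
interpolation reads the curve off directly, the fit also reports a
Hill slope.
"""

from larvamotor.group_stats import lc50_estimate
from larvamotor.synthetic import SurvivalParams, simulate_survival

data = simulate_survival(SurvivalParams(lc50=2.0, hill_slope=2.0, seed=5))
for dose, frac in zip(data.dose, data.surviving_fraction):
    print(f"  {dose:5.1f} mM : {frac * 100:5.1f} % surviving")

interp = lc50_estimate(data, method="interpolation")
logistic = lc50_estimate(data, method="logistic")
print(f"LC50 (interpolation): {interp.lc50:.2f} mM ({interp.note})")
print(f"LC50 (logistic fit):  {logistic.lc50:.2f} mM, "
      f"Hill slope {logistic.hill_slope:.2f}")
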