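"""Validation statistics: power, exact test, confidence intervals,
subgroups, and minimization randomization.

Everything here operates on score/outcome columns, independent of where
the scores came from.
"""

import numpy as np

from scnp.cohort import AllocationState, minimization_assign, DEFAULT_FACTORS
from scnp.stats import (auroc_trapezoid, bca_ci, delong_ci, exact_mw_test,
                        median_split, power_simulation, subgroup_performance)

rng = np.random.default_rng(42)

# 1. design power: n=50 at the 72% training response rate, true AUROC 0.75
power = power_simulation(n_total=50, response_rate=0.72, true_auroc=0.75,
                         alpha=0.05, reps=2000, rng=rng)
print(f"power of the one-sided exact AUROC test at n=50: {100 * power:.1f}%")
# the validation design was sized so this exceeds 80%

# 2. one validation-sized cohort: AUROC, exact p, BCa and DeLong intervals
mu = np.sqrt(2) * 0.6745  # binormal separation for true AUROC 0.75
scores = np.r_[rng.normal(mu, 1, 36), rng.normal(0, 1, 14)]
labels = np.r_[np.ones(36, int), np.zeros(14, int)]
auroc = auroc_trapezoid(scores, labels)
p = exact_mw_test(scores, labels)
lo, hi = bca_ci(scores, labels, B=2000, rng=rng)
dl = delong_ci(scores, labels)
print(f"cohort AUROC={auroc:.3f}, exact one-sided p={p:.4f}")
print(f"  95% BCa CI    = ({lo:.3f}, {hi:.3f})")
print(f"  95% DeLong CI = ({dl.ci[0]:.3f}, {dl.ci[1]:.3f})")

# 3. subgroup performance with age split at the median
ages = rng.normal(70, 6, 50)
groups = {f"age_{k}": v for k, v in median_split(ages).items()}
for name, res in subgroup_performance(scores, labels, groups).items():
    print(f"  {name}: AUROC={res.auroc:.3f} CI={tuple(round(c, 3) for c in res.ci)}")

# 4. minimization randomization of 100 patients over 6 balancing factors
levels = [{f: f"L{rng.integers(2)}" for f in DEFAULT_FACTORS}
          for _ in range(100)]
arms = minimization_assign(levels, AllocationState(), rng=rng)
print(f"minimization: {arms.count('training')} training / "
      f"{arms.count('validation')} validation")
# marginal factor counts stay nearly equal between arms, unlike a coin flip
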