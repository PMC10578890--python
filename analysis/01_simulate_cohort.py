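#!/usr/bin/env python
"""Generate the default synthetic cohort (14 favorable / 6 unfavorable TBI
coma patients, 2-hourly pupil observations) and write it under
results/cohort/.

The cohort emulates the study conditions of the reference analysis: stay
17 +/- 9 days, sedation 9 +/- 6 days, stable normal dynamics for the
favorable group and unstable-then-pathological dynamics for the unfavorable
group.
"""

import argparse

import numpy as np

from pupildyn.io import write_cohort
from pupildyn.simulate import CohortConfig, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", default="results/cohort")
args = parser.parse_args()

config = CohortConfig(seed=args.seed)
cohort = generate_cohort(config)
write_cohort(cohort, args.out, config=config)

n_obs = [len(p.observations) for p in cohort]
print(f"wrote {len(cohort)} patients to {args.out}")
print(f"observations per patient: mean {np.mean(n_obs):.1f}, "
      f"range {min(n_obs)}-{max(n_obs)}")
print(f"favorable: {sum(p.outcome.value == 'FAVORABLE' for p in cohort)}, "
      f"unfavorable: {sum(p.outcome.value == 'UNFAVORABLE' for p in cohort)}")
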