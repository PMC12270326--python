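"""Estimate post-removal sensor offsets at each anchor and compare with truth.

The residual reading after catheter exit is the drift itself, so averaging a
short window at the anchor recovers the per-sensor offset; the table prints
the worst absolute error against the simulator's closed-form drift at each
of the four anchor times (0 = formal compensation; 1, 5, 10 s = late
anchors).  Errors are small but nonzero: the estimator averages 0.5 s of a
curved post-exit drift shape.
"""

import numpy as np

from manodrift.core_model import TCCondition
from manodrift.synthetic_cohort import DriftModel, simulate_study
from manodrift.thermal_compensation import estimate_offsets

study = simulate_study("nem", DriftModel(), seed=5)

print(f"{'anchor (s)':>10}{'mean offset':>14}{'worst |err|':>14}")
for anchor in (0, 1, 5, 10):
    ov = estimate_offsets(study, TCCondition(mode="anchored", anchor_offset=float(anchor)))
    truth = np.array(study.ground_truth["true_drift_at_anchor"][str(anchor)])
    print(f"{anchor:>10}{ov.o.mean():>14.2f}{np.abs(ov.o - truth).max():>14.3f}")
print()
print("Mean offsets differ across anchors because post-exit drift is not flat:")
print("anchoring late subtracts a slightly different baseline than anchoring")
print("at the waterfall end, which is how anchor timing perturbs the metrics.")
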