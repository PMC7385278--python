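"""Simulate a longitudinal BLM-vs-saline imaging study and summarize it.

Seven animals per group imaged at days 7, 14, 21 and 28; the fibrotic
burden rises to its day-14 peak and partially resolves afterwards. The
estimated poorly-aerated fraction is computed per scan through the full
segmentation pipeline and summarized as group mean ± s.e.m.
"""
import pandas as pd

import fibroct as fc
from fibroct.phantom import CohortSpec, GroupSpec, simulate_cohort

spec = fc.PhantomSpec(grid_shape=(64, 64, 64))  # reduced grid for speed
cohort = CohortSpec(
    groups=(
        GroupSpec("saline", route="none", bleomycin=False, n_animals=7),
        GroupSpec("BLM", route="OA", n_animals=7),
    ),
    rng_seed=1,
)
data = simulate_cohort(cohort, spec)

profiles = []
for scan in data.scans:
    seg = fc.segment(scan.ct)
    profiles.append(fc.quantify_volume(scan.ct, seg.lung_mask))

table = fc.aeration_timecourse(profiles, data.design)
poor = table[table.compartment == "poor"]
print(poor.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# The BLM group mean peaks at day 14 and declines at days 21/28 —
# the longitudinal signature of bleomycin fibrosis with partial
# resolution; saline stays under 1%.
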