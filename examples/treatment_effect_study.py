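"""A three-arm anti-fibrotic efficacy study read out by micro-CT.

Saline, BLM, and BLM+drug (a 0.5 burden multiplier from treatment start)
with seven animals each, imaged at day 21. Group differences are tested
with one-way ANOVA + Dunnett versus BLM, the treatment effect is the
percent inhibition of the BLM-induced increase, and the CT readout is
correlated against the linked ex vivo measurements.
"""
import pandas as pd

import fibroct as fc
from fibroct.phantom import CohortSpec, GroupSpec, simulate_cohort

spec = fc.PhantomSpec(grid_shape=(64, 64, 64))
cohort = CohortSpec(
    groups=(
        GroupSpec("saline", route="none", bleomycin=False, n_animals=7),
        GroupSpec("BLM", route="OA", n_animals=7),
        GroupSpec("BLM+drug", route="OA", treatment="drug", n_animals=7),
    ),
    days=(21,),
    drug_burden_factor=0.5,
    rng_seed=1,
)
data = simulate_cohort(cohort, spec)

rows = []
for scan in data.scans:
    seg = fc.segment(scan.ct)
    rows.append(
        {
            "animal_id": scan.animal_id,
            "group": scan.group,
            "frac_poor": fc.quantify_volume(scan.ct, seg.lung_mask).frac_poor,
        }
    )
df = pd.DataFrame(rows)
groups = {g: sub["frac_poor"].to_numpy() for g, sub in df.groupby("group")}
res = fc.one_way_anova_dunnett(groups, control="BLM")
print(f"one-way ANOVA F = {res.omnibus_statistic:.1f}, p = {res.omnibus_p:.2e}")
for name, p in res.pairwise:
    print(f"  Dunnett {name}: adjusted p = {p:.4f}")

means = df.groupby("group")["frac_poor"].mean()
effect = fc.treatment_effect(means["saline"], means["BLM"], means["BLM+drug"])
print(f"inhibition of poorly-aerated increase: {effect.percent:.1f}%")

hyp = data.exvivo.groupby("animal_id")["hydroxyproline_ug"].first()
merged = df.set_index("animal_id").join(hyp)
fit = fc.linear_fit(merged["frac_poor"], merged["hydroxyproline_ug"])
print(f"frac_poor vs hydroxyproline: R^2 = {fit.r_squared:.3f} (n={fit.n})")
# The recovered inhibition sits near the generating 50% multiplier, and
# the CT surrogate tracks the collagen readout across animals.
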