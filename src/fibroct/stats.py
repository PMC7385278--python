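"""Correlation, group-comparison and treatment-effect statistics.

The study's analysis toolkit: ordinary least-squares correlations
(R² on per-animal points), one- and two-way ANOVA with Dunnett's
many-to-one post hoc, Tukey's all-pairs HSD, Kruskal-Wallis with Dunn's
rank-based pairwise comparisons for non-normal data, and percent
treatment-effect summaries (inhibition of the disease-induced increase,
or plain reduction versus the disease group).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))
        if self.n < 3:
            raise ValueError("need at least 3 points")


@dataclass
class GroupComparisonResult:
    test_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        for p in [self.omnibus_p] + [p for _, p in self.pairwise]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p value {p} outside [0, 1]")

    def significant_pairs(self) -> list[str]:
        return [name for name, p in self.pairwise if p < self.alpha]


@dataclass
class TreatmentEffect:
    mode: str
    percent: float
    saline_mean: float
    disease_mean: float
    treated_mean: float


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, float).ravel() for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for name, vals in out.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least two observations")
    return out


def linear_fit(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Ordinary least squares of y on x with R² = 1 - SSres/SStot.

    A constant y gives SStot = 0; R² is then reported as 0 with a warning
    (the fit explains nothing that varies).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; reporting R² = 0", stacklevel=2)
        return CorrelationResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(x))
    res = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def one_way_anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = ALPHA_DEFAULT,
) -> GroupComparisonResult:
    """One-way ANOVA with Dunnett's many-to-one comparisons vs control."""
    data = _as_groups(groups)
    if control not in data:
        raise ValueError(f"control group {control!r} not among {sorted(data)}")
    others = [name for name in data if name != control]
    if np.ptp(np.concatenate(list(data.values()))) == 0:
        # zero variance everywhere: no evidence of any difference
        return GroupComparisonResult(
            test_name="one-way ANOVA + Dunnett",
            omnibus_statistic=0.0,
            omnibus_p=1.0,
            pairwise=[(f"{name} vs {control}", 1.0) for name in others],
            alpha=alpha,
        )
    f_stat, f_p = sps.f_oneway(*data.values())
    res = sps.dunnett(*[data[name] for name in others], control=data[control], rng=0)
    pairwise = [
        (f"{name} vs {control}", float(p)) for name, p in zip(others, res.pvalue)
    ]
    return GroupComparisonResult(
        test_name="one-way ANOVA + Dunnett",
        omnibus_statistic=float(f_stat),
        omnibus_p=float(f_p),
        pairwise=pairwise,
        alpha=alpha,
    )


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
) -> GroupComparisonResult:
    """One-way ANOVA omnibus with Tukey's HSD all-pairs comparisons."""
    data = _as_groups(groups)
    names = list(data)
    pairs = list(itertools.combinations(range(len(names)), 2))
    if np.ptp(np.concatenate(list(data.values()))) == 0:
        return GroupComparisonResult(
            test_name="one-way ANOVA + Tukey HSD",
            omnibus_statistic=0.0,
            omnibus_p=1.0,
            pairwise=[(f"{names[i]} vs {names[j]}", 1.0) for i, j in pairs],
            alpha=alpha,
        )
    f_stat, f_p = sps.f_oneway(*data.values())
    res = sps.tukey_hsd(*data.values())
    pairwise = []
    for i, j in pairs:
        pairwise.append((f"{names[i]} vs {names[j]}", float(res.pvalue[i, j])))
    return GroupComparisonResult(
        test_name="one-way ANOVA + Tukey HSD",
        omnibus_statistic=float(f_stat),
        omnibus_p=float(f_p),
        pairwise=pairwise,
        alpha=alpha,
    )


def kruskal_wallis_h(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and its chi-square p value.

    All observations identical across groups is a degenerate null case:
    H = 0, p = 1 by convention.
    """
    data = _as_groups(groups)
    pooled = np.concatenate(list(data.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*data.values())
    return float(h), float(p)


def dunn_pairwise(
    groups: Mapping[str, Sequence[float]],
    adjustment: str = "bonferroni",
) -> list[tuple[str, float]]:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie correction T = sum(t³ - t) / (12 (N - 1)); two-sided normal
    p values, multiplied by the number of comparisons for the Bonferroni
    family adjustment (capped at 1), or left unadjusted.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    data = _as_groups(groups)
    names = list(data)
    pooled = np.concatenate([data[name] for name in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name in names:
        n_i = len(data[name])
        mean_ranks[name] = float(ranks[start : start + n_i].mean())
        start += n_i
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out = []
    for a, b in pairs:
        se2 = var_base * (1.0 / len(data[a]) + 1.0 / len(data[b]))
        if se2 <= 0:  # fully tied data
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2)
            p = 2.0 * float(sps.norm.sf(abs(z)))
            if adjustment == "bonferroni":
                p = min(1.0, p * len(pairs))
        out.append((f"{a} vs {b}", p))
    return out


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
    adjustment: str = "bonferroni",
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus followed by Dunn's multiple comparisons."""
    h, p = kruskal_wallis_h(groups)
    pairwise = dunn_pairwise(groups, adjustment=adjustment)
    return GroupComparisonResult(
        test_name="Kruskal-Wallis + Dunn",
        omnibus_statistic=h,
        omnibus_p=p,
        pairwise=pairwise,
        alpha=alpha,
    )


@dataclass
class TwoWayAnovaResult:
    """Two-factor ANOVA (group, day, interaction) with per-day Dunnett
    comparisons versus the control group."""

    anova_table: pd.DataFrame
    group_p: float
    day_p: float
    interaction_p: float
    per_day: dict[int, GroupComparisonResult]


def two_way_anova_dunnett(
    data: pd.DataFrame,
    control: str,
    value: str = "value",
    group: str = "group",
    day: str = "day",
    alpha: float = ALPHA_DEFAULT,
) -> TwoWayAnovaResult:
    """Two-way ANOVA over a group×day design plus per-day Dunnett tests.

    Requires every group×day cell to contain observations (the
    longitudinal designs here are balanced); with a single day present
    the per-day result coincides with the one-way analysis.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value, group, day):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    cells = data.groupby([group, day], observed=True).size()
    all_groups = data[group].unique()
    all_days = data[day].unique()
    missing = [
        (g, d)
        for g in all_groups
        for d in all_days
        if (g, d) not in cells.index
    ]
    if missing:
        raise ValueError(f"empty group×day cells: {missing}")
    if control not in set(all_groups):
        raise ValueError(f"control group {control!r} not present")

    df = data.rename(columns={value: "_y", group: "_g", day: "_d"})
    if len(all_days) > 1:
        model = smf.ols("_y ~ C(_g) * C(_d)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        group_p = float(table.loc["C(_g)", "PR(>F)"])
        day_p = float(table.loc["C(_d)", "PR(>F)"])
        interaction_p = float(table.loc["C(_g):C(_d)", "PR(>F)"])
    else:
        model = smf.ols("_y ~ C(_g)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        group_p = float(table.loc["C(_g)", "PR(>F)"])
        day_p = float("nan")
        interaction_p = float("nan")

    per_day = {}
    for d in sorted(all_days):
        sub = df[df["_d"] == d]
        groups_d = {g: sub.loc[sub["_g"] == g, "_y"].to_numpy() for g in all_groups}
        per_day[d] = one_way_anova_dunnett(groups_d, control=control, alpha=alpha)
    return TwoWayAnovaResult(
        anova_table=table,
        group_p=group_p,
        day_p=day_p,
        interaction_p=interaction_p,
        per_day=per_day,
    )


def treatment_effect(
    saline_mean: float,
    disease_mean: float,
    treated_mean: float,
    mode: str = "inhibition_of_increase",
) -> TreatmentEffect:
    """Percent treatment effect from the three group means.

    ``inhibition_of_increase``: 100·(disease − treated)/(disease − saline),
    the share of the disease-induced increase abolished by treatment
    (100% returns the readout to the saline level).
    ``reduction_vs_disease``: 100·(disease − treated)/disease, the plain
    percent reduction versus the untreated disease group.
    """
    if mode == "inhibition_of_increase":
        denom = disease_mean - saline_mean
        if denom == 0:
            raise ValueError("disease and saline means coincide; inhibition undefined")
    elif mode == "reduction_vs_disease":
        denom = disease_mean
        if denom == 0:
            raise ValueError("disease mean is zero; reduction undefined")
    else:
        raise ValueError("mode must be 'inhibition_of_increase' or 'reduction_vs_disease'")
    percent = 100.0 * (disease_mean - treated_mean) / denom
    return TreatmentEffect(
        mode=mode,
        percent=float(percent),
        saline_mean=float(saline_mean),
        disease_mean=float(disease_mean),
        treated_mean=float(treated_mean),
    )


def null_familywise_error(
    test: str,
    n_groups: int = 3,
    n_per_group: int = 7,
    reps: int = 2000,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 1,
    n_days: int = 2,
) -> float:
    """Monte-Carlo familywise type-I error of a comparison procedure
    under its Gaussian/exchangeable null.

    ``test`` is one of ``dunnett``, ``tukey``, ``kruskal_dunn`` (the
    Kruskal-Wallis omnibus gate) or ``twoway_interaction``. Returns the
    fraction of replicates declaring any (adjusted) comparison — or the
    gated omnibus — significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    names = [f"g{i}" for i in range(n_groups)]
    for _ in range(reps):
        if test == "twoway_interaction":
            rows = []
            for g in names:
                for d in range(n_days):
                    for v in rng.standard_normal(n_per_group):
                        rows.append({"group": g, "day": d, "value": v})
            res = two_way_anova_dunnett(pd.DataFrame(rows), control=names[0])
            hits += res.interaction_p < alpha
            continue
        samples = {name: rng.standard_normal(n_per_group) for name in names}
        if test == "dunnett":
            res = one_way_anova_dunnett(samples, control=names[0], alpha=alpha)
            hits += min(p for _, p in res.pairwise) < alpha
        elif test == "tukey":
            res = tukey_hsd(samples, alpha=alpha)
            hits += min(p for _, p in res.pairwise) < alpha
        elif test == "kruskal_dunn":
            h, p = kruskal_wallis_h(samples)
            hits += p < alpha
        else:
            raise ValueError(f"unknown test {test!r}")
    return hits / reps
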