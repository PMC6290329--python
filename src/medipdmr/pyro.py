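"""Pyrosequencing-style group statistics and concordance with region calls.

Bisulfite pyrosequencing reports percent methylation per CpG per animal.
Group summaries average per-animal DMR means (mean over that animal's CpGs)
within group, per age or pooled.  The mean PAE-minus-control change carries a
normal-approximation 95% CI (change +/- 1.96 * se; the published summary's
"SD" column behaves arithmetically as a standard error and is treated as
one).  A change is flagged biologically meaningful when |change| exceeds the
conventional 5-percentage-point cutoff, and direction concordance compares
the sign of the pyrosequencing change with the sign of the region-level
log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_stats",
    "mean_change_ci",
    "flag_significant_change",
    "direction_concordance",
    "cpg_tests",
]

Z95 = 1.96


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"animal_id", "group", "age", "cpg", "percent"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"pyro table missing columns: {sorted(missing)}")
    if ((table["percent"] < 0) | (table["percent"] > 100)).any():
        raise ValueError("percent methylation must lie in [0, 100]")
    return table


def group_stats(table: pd.DataFrame, by: str = "age") -> dict[str, pd.DataFrame]:
    """Per-CpG and DMR-mean group means.

    ``by='age'`` stratifies by age; ``by='pooled'`` collapses ages.  The DMR
    mean is the mean over animals of each animal's mean over its available
    CpGs (animals with missing CpGs are averaged over what was measured and
    flagged).  Requires >= 2 animals per group per stratum.
    """
    table = _validate(table)
    if by not in ("age", "pooled"):
        raise ValueError("by must be 'age' or 'pooled'")
    strat = table.copy()
    if by == "pooled":
        strat["age"] = "all"

    n_cpgs = strat.groupby(["age", "group", "animal_id"])["cpg"].nunique()
    full = n_cpgs.max()
    incomplete = n_cpgs[n_cpgs < full]

    per_animal = strat.groupby(["age", "group", "animal_id"])["percent"].mean()
    counts = per_animal.groupby(["age", "group"]).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 animals per group per stratum; too few in {bad}")
    dmr_means = per_animal.groupby(["age", "group"]).mean().unstack("group")
    cpg_means = (
        strat.groupby(["age", "cpg", "group"])["percent"].mean().unstack("group")
    )
    dmr_means.attrs["incomplete_animals"] = [tuple(i) for i in incomplete.index]
    return {"dmr": dmr_means, "cpg": cpg_means, "per_animal": per_animal}


def mean_change_ci(change: float, se: float, z: float = Z95) -> tuple[float, float, float]:
    """Normal-approximation CI around a mean change: change +/- z * se."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return change, change - z * se, change + z * se


def pooled_change(dmr_means_by_age: pd.DataFrame, treat: str = "PAE",
                  control: str = "C") -> dict[str, float]:
    """All-ages change under both conventions.

    'mean_of_age_changes' averages the per-age PAE-minus-control differences
    (equal age weighting); 'pooled_mean_difference' differences the pooled
    group means (per-animal weighting when group sizes differ by age).
    """
    per_age = dmr_means_by_age[treat] - dmr_means_by_age[control]
    return {
        "mean_of_age_changes": float(per_age.mean()),
        "pooled_mean_difference": float(
            dmr_means_by_age[treat].mean() - dmr_means_by_age[control].mean()
        ),
    }


def flag_significant_change(change: float, threshold: float = 5.0) -> bool:
    """Biological-significance flag: strictly |change| > threshold points."""
    if not np.isfinite(change):
        raise ValueError("change must be finite")
    return bool(abs(change) > threshold)


def direction_concordance(pyro_change: float, region_log2fc: float) -> str:
    """'concordant' | 'discordant' | 'indeterminate' by sign agreement."""
    s1, s2 = np.sign(pyro_change), np.sign(region_log2fc)
    if s1 == 0 or s2 == 0:
        return "indeterminate"
    return "concordant" if s1 == s2 else "discordant"


def cpg_tests(table: pd.DataFrame, treat: str = "PAE", control: str = "C") -> pd.DataFrame:
    """Per-CpG group comparisons.

    Within each age: Welch two-sample t-test on per-animal percent values.
    Pooled across ages: OLS percent ~ group + age (group effect corrected
    for age), per CpG.
    """
    import statsmodels.formula.api as smf

    table = _validate(table)
    sub = table[table["group"].isin([treat, control])].copy()
    rows = []
    for cpg, g in sub.groupby("cpg"):
        for age, ga in g.groupby("age"):
            a = ga.loc[ga["group"] == treat, "percent"]
            b = ga.loc[ga["group"] == control, "percent"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((cpg, str(age), float(a.mean() - b.mean()), float(p)))
        d = g.copy()
        d["is_treat"] = (d["group"] == treat).astype(float)
        d["age"] = d["age"].astype(str)
        fit = smf.ols("percent ~ is_treat + C(age)", data=d).fit()
        rows.append((cpg, "all_ages_adjusted",
                     float(fit.params["is_treat"]), float(fit.pvalues["is_treat"])))
    return pd.DataFrame(rows, columns=["cpg", "age", "change", "p"])
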