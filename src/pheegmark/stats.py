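"""Two-way ANOVA and one-tailed t-tests on pharmacodynamic features.

The default observation unit is one (animal x channel) sample, i.e. 50
observations per strain-day cell under the full design.  Channels within
an animal are pseudo-replicates; this follows the grouping convention of
the upstream outlier stage and is documented rather than "fixed" — a
mixed-effects model with animal random effects would be the stricter
design and is out of scope.

* ``two_way_anova``: crossed experimental-condition (day) x strain design.
  Balanced designs use the textbook sums-of-squares decomposition (Type I,
  which coincides with Type II when balanced); unbalanced designs — e.g.
  after outlier removal — delegate to statsmodels' Type II ANOVA.
* ``ttest_vs_vehicle``: two-sample Student t (pooled variance; Welch
  optional) between an agent condition and the vehicle day within a
  strain, reported one-tailed in the direction of the observed mean
  difference together with that direction's sign.

No multiple-testing correction is applied by default (per-test marks at
alpha = 0.05 / 0.01); a Benjamini-Hochberg helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaRow",
    "two_way_anova",
    "anova_table",
    "TTestResult",
    "one_tailed_ttest",
    "ttest_vs_vehicle",
    "ttest_table",
    "benjamini_hochberg",
    "significance_mark",
]


def significance_mark(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """'**' below alpha2, '*' below alpha1, '' otherwise."""
    if p <= alpha2:
        return "**"
    if p <= alpha1:
        return "*"
    return ""


@dataclass
class AnovaRow:
    """F statistics, p-values and degrees of freedom of one two-way ANOVA."""

    f_condition: float
    f_strain: float
    f_interaction: float
    p_condition: float
    p_strain: float
    p_interaction: float
    df_condition: int
    df_strain: int
    df_interaction: int
    df_error: int

    def marks(self) -> dict[str, str]:
        return {
            "condition": significance_mark(self.p_condition),
            "strain": significance_mark(self.p_strain),
            "interaction": significance_mark(self.p_interaction),
        }


def _balanced_anova(values, cond_codes, strain_codes, n_a, n_b) -> AnovaRow:
    """Textbook SS decomposition for a balanced a x b design with r reps."""
    g = values.mean()
    n = values.size
    r = n // (n_a * n_b)

    cell_sum = np.zeros((n_a, n_b))
    np.add.at(cell_sum, (cond_codes, strain_codes), values)
    cell_mean = cell_sum / r
    a_mean = cell_mean.mean(axis=1)
    b_mean = cell_mean.mean(axis=0)

    ss_a = r * n_b * ((a_mean - g) ** 2).sum()
    ss_b = r * n_a * ((b_mean - g) ** 2).sum()
    ss_cells = r * ((cell_mean - g) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((values - g) ** 2).sum()
    ss_err = ss_tot - ss_cells

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n - n_a * n_b
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / ms_err if ms_err > 0 else 0.0
        f_b = (ss_b / df_b) / ms_err if ms_err > 0 else 0.0
        f_ab = (ss_ab / df_ab) / ms_err if ms_err > 0 else 0.0
    f_a, f_b, f_ab = (max(v, 0.0) for v in (f_a, f_b, f_ab))
    return AnovaRow(
        f_condition=f_a,
        f_strain=f_b,
        f_interaction=f_ab,
        p_condition=float(sps.f.sf(f_a, df_a, df_err)),
        p_strain=float(sps.f.sf(f_b, df_b, df_err)),
        p_interaction=float(sps.f.sf(f_ab, df_ab, df_err)),
        df_condition=df_a,
        df_strain=df_b,
        df_interaction=df_ab,
        df_error=df_err,
    )


def _type2_anova(values, cond, strain) -> AnovaRow:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "cond": cond, "strain": strain})
    model = smf.ols("y ~ C(cond) * C(strain)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    get = lambda k: tab.loc[k]
    c, s, i, e = get("C(cond)"), get("C(strain)"), get("C(cond):C(strain)"), get("Residual")
    return AnovaRow(
        f_condition=float(c["F"]),
        f_strain=float(s["F"]),
        f_interaction=float(i["F"]),
        p_condition=float(c["PR(>F)"]),
        p_strain=float(s["PR(>F)"]),
        p_interaction=float(i["PR(>F)"]),
        df_condition=int(c["df"]),
        df_strain=int(s["df"]),
        df_interaction=int(i["df"]),
        df_error=int(e["df"]),
    )


def two_way_anova(values, factor_condition, factor_strain) -> AnovaRow:
    """Two-way crossed ANOVA of ``values`` over condition x strain factors.

    Requires at least 2 observations in every cell (the interaction term
    is always included).  Balanced data take the closed-form path;
    unbalanced data use Type II sums of squares.
    """
    values = np.asarray(values, dtype=float)
    cond = np.asarray(factor_condition)
    strain = np.asarray(factor_strain)
    if not (values.shape == cond.shape == strain.shape) or values.ndim != 1:
        raise ValueError("values and both factors must be equal-length 1-D arrays")
    a_levels, cond_codes = np.unique(cond, return_inverse=True)
    b_levels, strain_codes = np.unique(strain, return_inverse=True)
    n_a, n_b = len(a_levels), len(b_levels)
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = np.zeros((n_a, n_b), dtype=int)
    np.add.at(counts, (cond_codes, strain_codes), 1)
    if (counts < 2).any():
        i, j = np.argwhere(counts < 2)[0]
        raise ValueError(
            f"cell (condition={a_levels[i]!r}, strain={b_levels[j]!r}) has "
            f"{counts[i, j]} observation(s); need >= 2 for the interaction term"
        )
    if (counts == counts.flat[0]).all():
        return _balanced_anova(values, cond_codes, strain_codes, n_a, n_b)
    return _type2_anova(values, cond, strain)


def anova_table(feature_table: pd.DataFrame, parameters=("slope", "intercept", "mPower")) -> pd.DataFrame:
    """Per-(band, parameter) two-way ANOVA over day x strain.

    Mirrors the layout of a per-band F-value table: one row per band and
    parameter with F, p, and significance marks for the condition, strain
    and interaction terms.
    """
    rows = []
    for band, sub in feature_table.groupby("band", sort=False):
        for param in parameters:
            r = two_way_anova(sub[param].to_numpy(), sub["day"].to_numpy(), sub["strain"].to_numpy())
            m = r.marks()
            rows.append(
                {
                    "band": band,
                    "parameter": param,
                    "f_condition": r.f_condition,
                    "p_condition": r.p_condition,
                    "mark_condition": m["condition"],
                    "f_strain": r.f_strain,
                    "p_strain": r.p_strain,
                    "mark_strain": m["strain"],
                    "f_interaction": r.f_interaction,
                    "p_interaction": r.p_interaction,
                    "mark_interaction": m["interaction"],
                    "df_condition": r.df_condition,
                    "df_strain": r.df_strain,
                    "df_interaction": r.df_interaction,
                    "df_error": r.df_error,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    """One-tailed two-sample t-test, direction taken from the observed difference."""

    t: float
    p_one_tailed: float
    direction: int  # +1 if group1 mean >= group2 mean, else -1
    df: float
    mark: str

    def bucket(self, levels=(0.05, 0.005, 0.001, 1e-5, 1e-10)) -> float | None:
        """Finest significance level met, or None."""
        met = [lv for lv in sorted(levels, reverse=True) if self.p_one_tailed <= lv]
        return met[-1] if met else None


def one_tailed_ttest(group1, group2, welch: bool = False) -> TTestResult:
    """Two-sample t-test reported one-tailed in the observed direction.

    Pooled-variance Student t by default; Welch optional.  Degenerate
    zero-variance inputs follow the convention: equal means -> p = 1,
    unequal means with zero variance -> p = 0.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = x.mean() - y.mean()
    direction = 1 if diff >= 0 else -1
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if diff == 0:
            return TTestResult(t=0.0, p_one_tailed=1.0, direction=1, df=x.size + y.size - 2, mark="")
        p = 0.0
        t = np.inf * direction
        return TTestResult(t=float(t), p_one_tailed=p, direction=direction,
                           df=x.size + y.size - 2, mark="**")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    p_one = float(res.pvalue) / 2.0
    return TTestResult(
        t=float(res.statistic),
        p_one_tailed=p_one,
        direction=direction,
        df=float(res.df),
        mark=significance_mark(p_one),
    )


def ttest_vs_vehicle(
    feature_table: pd.DataFrame,
    parameter: str,
    band: str,
    strain: str,
    condition: str,
    vehicle: str = "D1",
    welch: bool = False,
) -> TTestResult:
    """t-test of one agent condition against the vehicle day within a strain."""
    sub = feature_table[(feature_table["band"] == band) & (feature_table["strain"] == strain)]
    g1 = sub.loc[sub["day"] == condition, parameter].to_numpy()
    g2 = sub.loc[sub["day"] == vehicle, parameter].to_numpy()
    if g1.size == 0 or g2.size == 0:
        raise ValueError(
            f"no samples for strain={strain!r}, band={band!r}, "
            f"day={condition if g1.size == 0 else vehicle!r}"
        )
    return one_tailed_ttest(g1, g2, welch=welch)


def ttest_table(
    feature_table: pd.DataFrame,
    parameters=("slope", "intercept", "mPower"),
    vehicle: str = "D1",
    welch: bool = False,
) -> pd.DataFrame:
    """All (strain, band, parameter, condition-vs-vehicle) one-tailed t-tests."""
    rows = []
    days = [d for d in sorted(feature_table["day"].unique()) if d != vehicle]
    for strain in feature_table["strain"].unique():
        for band in feature_table["band"].unique():
            for param in parameters:
                for day in days:
                    r = ttest_vs_vehicle(
                        feature_table, param, band, strain, day, vehicle=vehicle, welch=welch
                    )
                    rows.append(
                        {
                            "strain": strain,
                            "band": band,
                            "parameter": param,
                            "condition": day,
                            "vehicle": vehicle,
                            "t": r.t,
                            "p_one_tailed": r.p_one_tailed,
                            "direction": r.direction,
                            "mark": r.mark,
                        }
                    )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]
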