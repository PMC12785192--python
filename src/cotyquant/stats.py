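"""Cohort statistics: factorial ANOVA, per-condition t-tests, representatives.

Measurements are pooled across experiment replicates into a tidy
per-cotyledon table and analyzed per Ca condition with

* a two-way factorial ANOVA — response ~ day + genotype + day:genotype,
  both explanatory variables categorical, sequential (Type I) sums of
  squares in that order (the default of common statistical environments);
* two-sided pooled-variance (Student) two-sample t-tests between the two
  genotypes within each (Ca, day) cell, annotated with the conventional
  significance stars; and
* a representative-image selector: per condition, the sample minimizing
  the root sum of squared deviations of (largest necrotic spot area,
  x_rel, y_rel) from their group medians.

Degenerate inputs (zero variance, empty comparison cells) yield flagged
NaN rows rather than exceptions, so cohort sweeps never abort.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "t_test_per_condition",
    "p_to_stars",
    "select_representative",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnovaResult:
    """Two-way factorial ANOVA table.

    ``table`` has rows day, genotype, day:genotype, residual with columns
    df, sum_sq, F, p. ``degenerate`` marks a zero-variance response whose
    F ratios are undefined (reported as NaN).
    """

    table: pd.DataFrame
    response: str
    ss_type: str
    degenerate: bool = False

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def p_genotype(self) -> float:
        return float(self.table.loc["genotype", "p"])


def _check_factorial(table: pd.DataFrame, factors: Sequence[str]) -> None:
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, has {table[f].nunique()}")
    cells = table.groupby(list(factors), observed=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(table[f].unique()) for f in factors], names=list(factors)
    )
    empty = [idx for idx in full if idx not in cells.index]
    if empty:
        raise ValueError(
            f"singular design: empty cells {empty} make the interaction inestimable"
        )


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("day", "genotype"),
    ss: str = "sequential",
) -> AnovaResult:
    """Factorial ANOVA of ``response`` on two categorical factors.

    Sequential (Type I) sums of squares in the order first factor,
    second factor, interaction; ``ss="marginal"`` gives Type II for
    sensitivity analysis on unbalanced data. Rows with missing response
    are dropped with a logged count. F is the term mean square over the
    residual mean square; p the upper tail of the F distribution.
    """
    if ss not in ("sequential", "marginal"):
        raise ValueError("ss must be 'sequential' or 'marginal'")
    f1, f2 = factors
    data = table[[f1, f2, response]].copy()
    n_missing = int(data[response].isna().sum())
    if n_missing:
        logger.info("two_way_anova: dropping %d rows with missing %s", n_missing, response)
        data = data.dropna(subset=[response])
    _check_factorial(data, (f1, f2))
    n_cells = data.groupby([f1, f2], observed=True).ngroups
    if len(data) - n_cells < 1:
        raise ValueError("residual degrees of freedom < 1; need replication")

    data = data.rename(columns={response: "_y", f1: "_f1", f2: "_f2"})
    data["_f1"] = data["_f1"].astype(str)
    data["_f2"] = data["_f2"].astype(str)
    degenerate = bool(np.isclose(data["_y"].var(ddof=0), 0.0))
    model = smf.ols("_y ~ C(_f1) + C(_f2) + C(_f1):C(_f2)", data=data).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = sm.stats.anova_lm(model, typ=1 if ss == "sequential" else 2)
    rename = {
        "C(_f1)": f1,
        "C(_f2)": f2,
        "C(_f1):C(_f2)": f"{f1}:{f2}",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename)
    order = [f1, f2, f"{f1}:{f2}", "residual"]
    out = pd.DataFrame(
        {
            "df": aov["df"].astype(float),
            "sum_sq": aov["sum_sq"].astype(float),
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    ).loc[order]
    if degenerate:
        out.loc[out.index != "residual", ["F", "p"]] = np.nan
    return AnovaResult(table=out, response=response, ss_type=ss, degenerate=degenerate)


def p_to_stars(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05, else ns."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*" if p < 0.05 else "ns"


def t_test_per_condition(
    table: pd.DataFrame,
    response: str,
    group_col: str = "genotype",
    cell_cols: Sequence[str] = ("ca_mM", "day"),
) -> pd.DataFrame:
    """Student t-test between the two genotypes in every (Ca, day) cell.

    Two-sided pooled-variance two-sample t-test (df = n1 + n2 - 2); the
    sign of t follows the sorted genotype order (first minus second).
    Cells with a genotype absent or n < 2 on either side are skipped with
    a log entry. Returns one row per tested cell with t, df, p and the
    star annotation.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, has {groups}")
    g1, g2 = groups
    rows = []
    for keys, cell in table.groupby(list(cell_cols), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        x1 = cell.loc[cell[group_col] == g1, response].dropna().to_numpy()
        x2 = cell.loc[cell[group_col] == g2, response].dropna().to_numpy()
        if len(x1) < 2 or len(x2) < 2:
            logger.info(
                "t_test_per_condition: skipping cell %s (n=%d vs %d)",
                dict(zip(cell_cols, keys)), len(x1), len(x2),
            )
            continue
        if np.var(x1, ddof=0) == 0 and np.var(x2, ddof=0) == 0:
            t, p = (0.0, 1.0) if np.mean(x1) == np.mean(x2) else (np.nan, np.nan)
        else:
            t, p = sps.ttest_ind(x1, x2, equal_var=True)
        rows.append(
            {
                **dict(zip(cell_cols, keys)),
                "group1": g1,
                "group2": g2,
                "n1": len(x1),
                "n2": len(x2),
                "t": float(t),
                "df": len(x1) + len(x2) - 2,
                "p": float(p),
                "stars": p_to_stars(float(p)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[*cell_cols, "group1", "group2", "n1", "n2", "t", "df", "p", "stars"],
    )


def select_representative(
    table: pd.DataFrame,
    area_col: str = "largest_spot_area_px",
    x_col: str = "x_rel",
    y_col: str = "y_rel",
    group_cols: Sequence[str] = ("genotype", "ca_mM", "day"),
    standardize: bool = False,
) -> pd.DataFrame:
    """Per-group representative: smallest root-sum-of-squares from medians.

    For each group the score of a sample is
    sqrt((area - median_area)² + (x - median_x)² + (y - median_y)²) on
    raw values; the minimizer is the representative, ties going to the
    smallest image_id. Because raw areas (thousands of px) dominate the
    coordinates (<= 1), ``standardize=True`` divides each deviation by
    the group's median absolute deviation of that component (components
    with zero MAD are left unscaled).
    """
    rows = []
    for keys, grp in table.groupby(list(group_cols), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        grp = grp.dropna(subset=[area_col, x_col, y_col])
        if grp.empty:
            logger.info(
                "select_representative: group %s has no complete triples",
                dict(zip(group_cols, keys)),
            )
            continue
        vals = grp[[area_col, x_col, y_col]].to_numpy(dtype=float)
        med = np.median(vals, axis=0)
        dev = vals - med
        if standardize:
            mad = np.median(np.abs(dev), axis=0)
            dev = dev / np.where(mad > 0, mad, 1.0)
        score = np.sqrt((dev**2).sum(axis=1))
        cand = grp.assign(_score=score).sort_values(["_score", "image_id"])
        best = cand.iloc[0]
        rows.append(
            {
                **dict(zip(group_cols, keys)),
                "image_id": best["image_id"],
                "score": float(best["_score"]),
            }
        )
    return pd.DataFrame(rows, columns=[*group_cols, "image_id", "score"])
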