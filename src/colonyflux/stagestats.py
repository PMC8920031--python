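"""Stage-level statistics.

Linear models of per-bird outcomes (time-activity budgets, DEE, free
T3) on sex and breeding stage, with type III ANOVA under sum-to-zero
contrasts for the interactive model and type II for main effects;
least-squares means (LSM) with Tukey-adjusted pairwise stage contrasts;
a paired t-test for tagging effects on body mass.  Significance is
judged at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .config import BEHAVIOURS, STAGES
from .containers import BirdRecord, DeeEstimate, TimeActivityBudget

ALPHA = 0.05


def average_t3(samples: Sequence[float]) -> float:
    """Mean of the available (initial/final) free-T3 samples; NaN when none."""
    vals = [v for v in samples if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def build_outcome_table(
    birds: Sequence[BirdRecord],
    budgets: Sequence[TimeActivityBudget],
    dees: Optional[Sequence[DeeEstimate]] = None,
) -> pd.DataFrame:
    """One row per bird: design factors, budgets, DEE, mean T3, masses."""
    bud = {b.bird_id: b for b in budgets}
    dee = {d.bird_id: d for d in dees} if dees is not None else {}
    rows = []
    for b in birds:
        tb = bud.get(b.bird_id)
        if tb is None:
            continue
        row = {
            "bird_id": b.bird_id,
            "sex": b.sex,
            "stage": b.stage,
            "mass_pre": b.mass_pre,
            "mass_post": b.mass_post,
            "duration_h": (b.deployment_end - b.deployment_start).total_seconds() / 3600.0,
            "t3": average_t3(b.t3_samples),
        }
        for i, beh in enumerate(BEHAVIOURS):
            row[f"T_{beh}"] = tb.proportions[i]
        if b.bird_id in dee:
            row["dee_act"] = dee[b.bird_id].dee_act
        rows.append(row)
    df = pd.DataFrame(rows)
    df["stage"] = pd.Categorical(df["stage"], categories=STAGES)
    return df


@dataclass
class AnovaResult:
    """ANOVA table plus the fitted OLS model for downstream LSM work."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, PR(>F)
    anova_type: str  # "II" or "III"
    response: str
    factors: tuple
    model: object = field(repr=False, default=None)

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def _term(factor: str) -> str:
    return f"C({factor}, Sum)"


def fit_lm_anova(
    table: pd.DataFrame,
    response: str,
    factors: tuple = ("sex", "stage"),
    interaction: bool = True,
) -> AnovaResult:
    """OLS fit and ANOVA for a response on categorical factors.

    ``interaction=True`` fits the interactive model and reports type III
    sums of squares under sum-to-zero contrasts; ``interaction=False``
    fits main effects only and reports type II.
    """
    data = table.dropna(subset=[response, *factors]).copy()
    for f in factors:
        levels = data[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels, got {list(levels)}")
    op = " * " if interaction else " + "
    formula = f"{response} ~ " + op.join(_term(f) for f in factors)
    fit = smf.ols(formula, data=data).fit()
    exog = fit.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        cells = pd.crosstab(*(data[f] for f in factors[:2]))
        raise ValueError(f"rank-deficient design (empty cell?):\n{cells}")
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    aov = anova_lm(fit, typ=3 if interaction else 2)
    aov = aov.rename(index=lambda s: s.replace(", Sum", ""))
    # a constant response has no variance to partition: report F=0, p=1
    if np.ptp(data[response].to_numpy(float)) == 0.0:
        effects = aov.index != "Residual"
        aov.loc[effects, "F"] = 0.0
        aov.loc[effects, "PR(>F)"] = 1.0
    return AnovaResult(
        table=aov,
        anova_type="III" if interaction else "II",
        response=response,
        factors=tuple(factors),
        model=fit,
    )


@dataclass
class LsmContrast:
    """Least-squares means for one factor and pairwise level contrasts."""

    factor: str
    means: pd.DataFrame  # index level; columns lsm, se
    contrasts: pd.DataFrame  # columns: a, b, diff, se, t, df, p_adj
    adjust: str


def _lsm_rows(fit, factor: str, factors: tuple, data: pd.DataFrame) -> dict:
    """Per-level design rows averaged equally over the other factors' levels."""
    design_info = fit.model.data.design_info
    others = [f for f in factors if f != factor]
    rows = {}
    for level in pd.unique(data[factor].dropna()):
        grid = {factor: [], **{f: [] for f in others}}
        combos = [()]
        for f in others:
            combos = [c + (lv,) for c in combos for lv in pd.unique(data[f].dropna())]
        for combo in combos:
            grid[factor].append(level)
            for f, lv in zip(others, combo):
                grid[f].append(lv)
        (X,) = build_design_matrices([design_info], pd.DataFrame(grid))
        rows[level] = np.asarray(X).mean(axis=0)
    return rows


def lsm_pairwise(
    result: AnovaResult,
    factor: str = "stage",
    adjust: str = "tukey",
) -> LsmContrast:
    """LSMs (predictions equally weighted over the other factor's levels)
    and pairwise differences with Tukey-adjusted p-values (or ``adjust="none"``)."""
    if factor not in result.factors:
        raise ValueError(f"factor {factor!r} not in the fitted model {result.factors}")
    fit = result.model
    data = fit.model.data.frame
    rows = _lsm_rows(fit, factor, result.factors, data)
    beta = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    df_resid = float(fit.df_resid)

    means = pd.DataFrame(
        {
            "lsm": {lv: float(r @ beta) for lv, r in rows.items()},
            "se": {lv: float(np.sqrt(r @ cov @ r)) for lv, r in rows.items()},
        }
    )
    levels = list(rows)
    k = len(levels)
    recs = []
    for a, b in combinations(levels, 2):
        L = rows[a] - rows[b]
        diff = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        if adjust == "tukey":
            p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df_resid))
        elif adjust == "none":
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        recs.append({"a": a, "b": b, "diff": diff, "se": se, "t": t,
                     "df": df_resid, "p_adj": min(p, 1.0)})
    return LsmContrast(
        factor=factor, means=means, contrasts=pd.DataFrame(recs), adjust=adjust
    )


def paired_t(pre: Sequence[float], post: Sequence[float]) -> tuple[float, int, float]:
    """Two-tailed paired t-test on d = pre - post (positive t = decline).

    Returns (t, df, p).  Zero-variance differences give t = 0, p = 1
    when the mean difference is zero, otherwise an infinite t (p = 0).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = pre - post
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def stage_summary(
    table: pd.DataFrame,
    columns: Sequence[str] = ("T_flight", "T_colony", "T_water", "dee_act", "t3"),
) -> pd.DataFrame:
    """Per-stage (and overall) mean, sample s.d. and n for each outcome.

    Groups of a single bird report NaN for the s.d. (undefined)."""
    cols = [c for c in columns if c in table.columns]
    parts = []
    groups = [(s, table[table["stage"] == s]) for s in STAGES] + [("all", table)]
    for name, sub in groups:
        if len(sub) == 0:
            continue
        for c in cols:
            vals = sub[c].dropna()
            parts.append(
                {
                    "stage": name,
                    "variable": c,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(parts)
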