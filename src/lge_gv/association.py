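"""Change-score correlation and weight-adjusted regression analysis.

For each participant, change scores are week-16 minus week-0: percentage
points for LGE, kg for weight, and — following the convention of reporting GV
effects as percent changes — 100 x (post - pre)/pre for each GV measure
(absolute changes are carried alongside).  Associations are Pearson
product-moment correlations of dLGE with each dGV%, and ordinary least
squares of dGV% on dLGE and dweight (with intercept) to test whether the LGE
association is independent of concurrent weight change.  The per-10-pp effect
is 10 x the LGE coefficient.  No multiple-testing correction is applied to
the primary p-values (exploratory analysis); a Benjamini-Hochberg column is
emitted alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, SingularDesignError, UndefinedResultError


@dataclass(frozen=True)
class AssociationResult:
    measure: str
    pearson_r: float
    r_p_value: float
    beta_lge: float
    beta_lge_p: float
    beta_weight: float
    beta_weight_p: float
    adjusted_r2: float
    n: int

    @property
    def effect_per_10pp(self) -> float:
        """Modeled change in the outcome per 10-percentage-point LGE increase."""
        return 10.0 * self.beta_lge


def compute_changes(
    measures: pd.DataFrame,
    gv_columns: list[str] | None = None,
    weeks: tuple[int, int] = (0, 16),
) -> pd.DataFrame:
    """Week-16 minus week-0 change scores per participant.

    ``measures`` is long format with ``participant_id``, ``week``,
    ``lge_percent``, ``weight_kg`` and GV measure columns.  Unpaired
    participants are excluded.  Output columns: ``delta_lge`` (pp),
    ``delta_weight`` (kg), and per GV measure ``d<name>_pct`` (NaN when the
    week-0 value is 0, flagged in ``<name>_pct_undefined``) and ``d<name>``.
    """
    pre_w, post_w = weeks
    if gv_columns is None:
        gv_columns = [c for c in measures.columns
                      if c not in ("participant_id", "week", "lge_percent", "weight_kg")]
    pre = measures[measures["week"] == pre_w].set_index("participant_id")
    post = measures[measures["week"] == post_w].set_index("participant_id")
    paired = pre.index.intersection(post.index)
    out = pd.DataFrame(index=paired)
    out.index.name = "participant_id"
    out["delta_lge"] = post.loc[paired, "lge_percent"] - pre.loc[paired, "lge_percent"]
    if "weight_kg" in measures.columns:
        out["delta_weight"] = post.loc[paired, "weight_kg"] - pre.loc[paired, "weight_kg"]
    for col in gv_columns:
        v0 = pre.loc[paired, col].astype(float)
        v1 = post.loc[paired, col].astype(float)
        out[f"d{col}"] = v1 - v0
        pct = 100.0 * (v1 - v0) / v0.where(v0 != 0)
        out[f"d{col}_pct"] = pct
        out[f"{col}_pct_undefined"] = v0 == 0
    return out


def summarize_change(values: pd.Series | np.ndarray, confidence: float = 0.95) -> dict:
    """Cohort mean change with a t-based confidence interval."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise InsufficientDataError("need >= 2 values for a CI")
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * se)
    return {"mean": m, "ci_low": m - half, "ci_high": m + half, "n": n}


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("pearson needs n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedResultError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedResultError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def adjusted_regression(
    measure: str,
    delta_gv: np.ndarray,
    delta_lge: np.ndarray,
    delta_weight: np.ndarray,
) -> AssociationResult:
    """OLS of a GV change score on dLGE and dweight with intercept.

    A constant (typically all-zero) weight column collapses the model to the
    simple regression on dLGE, whose coefficient t-test p equals the Pearson
    p for the same pair.  Near-singular two-predictor designs raise.
    """
    y = np.asarray(delta_gv, dtype=float)
    x1 = np.asarray(delta_lge, dtype=float)
    x2 = np.asarray(delta_weight, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    n = len(y)
    if n < 4:
        raise InsufficientDataError("adjusted regression needs n >= 4")
    r, r_p = pearson(x1, y)
    weight_constant = np.ptp(x2) == 0
    if weight_constant:
        X = sm.add_constant(x1[:, None])
    else:
        X = sm.add_constant(np.column_stack([x1, x2]))
        if np.linalg.cond(X) > 1e10:
            raise SingularDesignError(f"{measure}: collinear predictors")
    fit = sm.OLS(y, X).fit()
    if weight_constant:
        beta_w, p_w = 0.0, float("nan")
    else:
        beta_w, p_w = float(fit.params[2]), float(fit.pvalues[2])
    return AssociationResult(
        measure=measure, pearson_r=r, r_p_value=r_p,
        beta_lge=float(fit.params[1]), beta_lge_p=float(fit.pvalues[1]),
        beta_weight=beta_w, beta_weight_p=p_w,
        adjusted_r2=float(fit.rsquared_adj), n=n)


def associate_all(
    changes: pd.DataFrame,
    gv_measures: list[str],
    scale: str = "percent",
) -> pd.DataFrame:
    """Run the correlation + adjusted-regression analysis per GV measure.

    ``scale`` selects the ``d<name>_pct`` (default) or absolute ``d<name>``
    change columns.  Adds Benjamini-Hochberg adjusted p-value columns.
    """
    rows = []
    for m in gv_measures:
        col = f"d{m}_pct" if scale == "percent" else f"d{m}"
        res = adjusted_regression(m, changes[col].to_numpy(),
                                  changes["delta_lge"].to_numpy(),
                                  changes["delta_weight"].to_numpy())
        rows.append({
            "measure": m, "pearson_r": res.pearson_r, "r_p_value": res.r_p_value,
            "beta_lge": res.beta_lge, "beta_lge_p": res.beta_lge_p,
            "beta_weight": res.beta_weight, "beta_weight_p": res.beta_weight_p,
            "effect_per_10pp": res.effect_per_10pp,
            "adjusted_r2": res.adjusted_r2, "n": res.n,
        })
    df = pd.DataFrame(rows).set_index("measure")
    df["r_p_bh"] = multipletests(df["r_p_value"], method="fdr_bh")[1]
    df["beta_lge_p_bh"] = multipletests(df["beta_lge_p"], method="fdr_bh")[1]
    return df
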