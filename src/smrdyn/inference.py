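"""Group-level statistics: stepwise regressions of segment-mean features on
group/age/gender/trial-count, KS normality gating, and post-hoc two-sample
t-tests.

All reported p-values are uncorrected; output tables carry an explicit
``uncorrected`` flag rather than any multiplicity adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

PREDICTORS = ("group", "age", "gender", "n_trials")

P_ENTER = 0.05
P_REMOVE = 0.10


@dataclass
class RegressionResult:
    selected: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    skipped: list[str] = field(default_factory=list)


def _candidate_p(y: np.ndarray, x_current: np.ndarray, x_new: np.ndarray) -> float:
    """p-value of the new column's coefficient when added to the model."""
    x = np.column_stack([x_current, x_new])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return np.nan
    fit = sm.OLS(y, x).fit()
    return float(fit.pvalues[-1])


def stepwise_regression(
    table: pd.DataFrame,
    criterion: str = "value",
    predictors: tuple[str, ...] = PREDICTORS,
    p_enter: float = P_ENTER,
    p_remove: float = P_REMOVE,
) -> RegressionResult:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the most significant excluded predictor enters if its
    coefficient p-value is below ``p_enter``; any included predictor whose
    p-value rises above ``p_remove`` is removed.  Iterates to a fixed
    point.  Collinear candidates are skipped with a warning.  The reported
    fit statistic is the ordinary coefficient of determination of the final
    model.
    """
    if len(table) < 8:
        raise ValueError("need at least 8 rows for stepwise regression")
    y = table[criterion].to_numpy(dtype=float)
    cols = {}
    skipped = []
    for p in predictors:
        x = table[p]
        if p == "group":
            x = x.map({"A": 0.0, "B": 1.0}) if x.dtype == object else x
        elif p == "gender":
            x = x.map({"F": 0.0, "M": 1.0}) if x.dtype == object else x
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            logger.warning("predictor %s is constant; excluded", p)
            skipped.append(p)
            continue
        cols[p] = x
    selected: list[str] = []
    seen_states = set()
    while True:
        state = tuple(selected)
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False
        x_current = np.column_stack(
            [np.ones(len(y))] + [cols[p] for p in selected]
        )
        # forward step
        best_p, best_name = np.inf, None
        for name, x_new in cols.items():
            if name in selected:
                continue
            pv = _candidate_p(y, x_current, x_new)
            if np.isnan(pv):
                if name not in skipped:
                    warnings.warn(f"predictor {name} collinear with model; skipped")
                    skipped.append(name)
                continue
            if pv < best_p:
                best_p, best_name = pv, name
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            changed = True
        # backward step(s)
        while selected:
            x = np.column_stack([np.ones(len(y))] + [cols[p] for p in selected])
            fit = sm.OLS(y, x).fit()
            pvs = fit.pvalues[1:]
            worst = int(np.argmax(pvs))
            if pvs[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    x = np.column_stack([np.ones(len(y))] + [cols[p] for p in selected])
    fit = sm.OLS(y, x).fit()
    coefficients = dict(zip(selected, fit.params[1:]))
    p_values = dict(zip(selected, fit.pvalues[1:]))
    r2 = float(fit.rsquared) if selected else 0.0
    return RegressionResult(
        selected=selected,
        coefficients=coefficients,
        p_values=p_values,
        r_squared=r2,
        residuals=np.asarray(fit.resid),
        skipped=skipped,
    )


def ks_normality(sample: np.ndarray, standardize: bool = True) -> float:
    """One-sample Kolmogorov-Smirnov test against the standard normal.

    With ``standardize=True`` (default) the sample is z-scored first; note
    that using estimated moments makes the test conservative.  Set
    ``standardize=False`` only when the sample is already on the standard
    normal scale.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance sample")
        x = (x - x.mean()) / sd
    return float(stats.kstest(x, "norm").pvalue)


def posthoc_ttest(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float, str]:
    """Two-sample pooled-variance t-test with a direction label.

    Returns ``(t, two-sided p, direction)`` with direction ``'A>B'``,
    ``'B>A'`` or ``'A=B'``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    diff = a.mean() - b.mean()
    direction = "A>B" if diff > 0 else ("B>A" if diff < 0 else "A=B")
    return float(res.statistic), float(res.pvalue), direction


def run_feature_regressions(
    features: pd.DataFrame,
    cell_columns: tuple[str, ...] = ("feature", "condition", "band", "segment"),
    predictors: tuple[str, ...] = PREDICTORS,
    p_enter: float = P_ENTER,
    p_remove: float = P_REMOVE,
) -> pd.DataFrame:
    """Stepwise regression per feature cell, with post-hoc tests on group.

    ``features`` is a long-format table with one row per participant and
    cell, carrying ``value`` plus the predictor columns.  Wherever the
    group predictor survives the stepwise rule, a KS normality check and a
    pooled two-sample t-test between groups are appended.  All p-values
    are uncorrected (flagged in the output).
    """
    rows = []
    for keys, cell in features.groupby(list(cell_columns), sort=True):
        rec = dict(zip(cell_columns, keys))
        try:
            res = stepwise_regression(
                cell, predictors=predictors, p_enter=p_enter, p_remove=p_remove
            )
        except ValueError as e:
            logger.warning("cell %s skipped: %s", rec, e)
            continue
        rec.update(
            {
                "selected": ",".join(res.selected),
                "r2": res.r_squared,
                "regression_p": min(res.p_values.values()) if res.p_values else np.nan,
                "group_p": res.p_values.get("group", np.nan),
                "uncorrected": True,
                "ks_p": np.nan,
                "ttest_t": np.nan,
                "ttest_p": np.nan,
                "direction": "",
            }
        )
        if "group" in res.selected:
            va = cell.loc[cell["group"] == "A", "value"].to_numpy(dtype=float)
            vb = cell.loc[cell["group"] == "B", "value"].to_numpy(dtype=float)
            try:
                rec["ks_p"] = ks_normality(np.concatenate([va, vb]))
                t, p, direction = posthoc_ttest(va, vb)
                rec.update({"ttest_t": t, "ttest_p": p, "direction": direction})
            except ValueError as e:
                logger.warning("post-hoc test skipped for cell %s: %s", rec, e)
        rows.append(rec)
    return pd.DataFrame(rows)
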