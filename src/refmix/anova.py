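"""Full-factorial fixed-effects variance decomposition of Cq responses.

The crossover design is (by construction) a balanced complete factorial, so
the sum of squares for every main effect and interaction has a closed form:
the effect of a term T at each observation is the inclusion–exclusion
combination of cell means over the subsets of T, and its SS is the squared
effect summed over observations.  Mean squares (SS/df) are used
descriptively — as the average contribution of each factor or interaction to
the variability of the experiment — not inferentially, so no F statistics or
p-values are produced.

Unbalanced data fall back to sequential (Type-I) sums of squares in the
factor order given, computed by ordinary least squares via statsmodels, with
a logged caveat that the decomposition is then order-dependent.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _is_balanced(df: pd.DataFrame, factors: Sequence[str]) -> bool:
    counts = df.groupby(list(factors), sort=False).size()
    full = np.prod([df[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


def _balanced_ss(df: pd.DataFrame, factors: Sequence[str], response: str) -> pd.DataFrame:
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    # cell-mean vector per subset of factors, broadcast to observations
    means: dict[frozenset, np.ndarray] = {frozenset(): np.full(n, grand)}
    for r in range(1, len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            means[frozenset(sub)] = (
                df.groupby(list(sub), sort=False)[response].transform("mean").to_numpy()
            )
    rows = []
    for r in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, r):
            tset = frozenset(term)
            effect = np.zeros(n)
            for k in range(r + 1):
                for sub in itertools.combinations(term, k):
                    effect += (-1) ** (r - k) * means[frozenset(sub)]
            ss = float(effect @ effect)
            dof = int(np.prod([df[f].nunique() - 1 for f in term]))
            rows.append({"term": ":".join(term), "df": dof, "ss": ss})
    total_ss = float(((y - grand) ** 2).sum())
    model_ss = sum(r["ss"] for r in rows)
    model_df = sum(r["df"] for r in rows)
    rows.append(
        {"term": "residual", "df": n - 1 - model_df, "ss": max(total_ss - model_ss, 0.0)}
    )
    return pd.DataFrame(rows)


def _sequential_ss(df: pd.DataFrame, factors: Sequence[str], response: str) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    logger.warning(
        "unbalanced design: using sequential (Type-I) SS in factor order %s",
        list(factors),
    )
    work = df.rename(columns={response: "_y"}).copy()
    rhs = "*".join(f"C({f})" for f in factors)
    model = smf.ols(f"_y ~ {rhs}", data=work).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(model, typ=1)

    def clean(term: str) -> str:
        return ":".join(
            t[2:-1] if t.startswith("C(") and t.endswith(")") else t
            for t in term.split(":")
        )

    rows = [
        {"term": clean(idx) if idx != "Residual" else "residual",
         "df": int(r["df"]), "ss": float(r["sum_sq"])}
        for idx, r in table.iterrows()
    ]
    return pd.DataFrame(rows)


def factorial_anova(
    observations: pd.DataFrame,
    factors: Sequence[str],
    response: str = "cq",
) -> pd.DataFrame:
    """Variance table (term, df, ss, ms) over all factor interactions.

    Terms are ordered by descending mean square, the residual row last.  MS
    is NaN for zero-df terms (e.g. the residual of a saturated design).
    """
    missing = [f for f in factors if f not in observations.columns]
    if missing:
        raise KeyError(f"factor columns not in data: {missing}")
    if response not in observations.columns:
        raise KeyError(f"response column {response!r} not in data")
    if _is_balanced(observations, factors):
        table = _balanced_ss(observations, factors, response)
    else:
        table = _sequential_ss(observations, factors, response)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ms"] = np.where(table["df"] > 0, table["ss"] / table["df"], np.nan)
    resid = table[table["term"] == "residual"]
    terms = table[table["term"] != "residual"].sort_values(
        "ms", ascending=False, kind="mergesort"
    )
    return pd.concat([terms, resid], ignore_index=True)


def filter_report(table: pd.DataFrame, ms_threshold: float = 1.0) -> pd.DataFrame:
    """Rows whose mean square is at least the threshold, order preserved.

    Mirrors the reporting convention of dropping factors or interactions
    whose mean square falls below one (on the Cq² scale).
    """
    keep = table["ms"].fillna(0.0) >= ms_threshold
    return table.loc[keep].reset_index(drop=True)
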