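"""Decoupling disease from age, one component at a time.

Mouse scores along a human component are explained by two nested linear
models with treatment-coded categorical factors:

* null:        score ~ intercept + age
* alternative: score ~ intercept + age + disease

and compared with

    F = ((RSS_null - RSS_alt) / (p_alt - p_null)) / (RSS_alt / (N - p_alt - 1))

where p counts non-intercept model degrees of freedom. The p-value comes
from the F distribution with (p_alt - p_null, N - p_alt - 1) degrees of
freedom; a component "passes" when p falls below the threshold (default
0.01), meaning disease explains score variation beyond what age already
accounts for.

Age levels (e.g. 2/4/8/18 months) and disease levels (dose 0/1/2) both
enter as factors, never as numeric trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgeDecouplingResult", "age_disease_ftest", "age_decoupling_table"]


class ConfoundingError(ValueError):
    """Age and disease factors are aliased; the nested test is undefined."""


@dataclass
class AgeDecouplingResult:
    """Nested-model comparison for one component."""

    rss_null: float
    rss_alt: float
    p_null: int  # non-intercept df of the null model
    p_alt: int  # non-intercept df of the alternative model
    n: int
    f_stat: float
    p_value: float
    threshold: float
    passed: bool


def _factor_design(*factors: tuple[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded indicator columns for each factor."""
    n = len(factors[0][1])
    cols = [np.ones(n)]
    names = ["intercept"]
    for name, values in factors:
        values = np.asarray(values)
        levels = sorted(pd.unique(values).tolist())
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels, has {levels}")
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def age_disease_ftest(
    scores_on_component,
    age,
    disease,
    threshold: float = 0.01,
) -> AgeDecouplingResult:
    """Nested F-test of disease beyond age for one component's scores."""
    y = np.asarray(scores_on_component, dtype=float)
    age = np.asarray(age)
    disease = np.asarray(disease)
    n = len(y)
    if len(age) != n or len(disease) != n:
        raise ValueError("scores, age and disease must have equal length")

    X_null, _ = _factor_design(("age", age))
    X_alt, names_alt = _factor_design(("age", age), ("disease", disease))
    p_null = X_null.shape[1] - 1
    p_alt = X_alt.shape[1] - 1
    if n <= p_alt + 1:
        raise ValueError(f"need N > p_alt + 1 = {p_alt + 1}, have N = {n}")
    if np.linalg.matrix_rank(X_alt) < X_alt.shape[1]:
        aliased = _aliased(X_alt, names_alt)
        raise ConfoundingError(
            f"age and disease are confounded; aliased columns: {aliased}"
        )

    rss_null = _rss(X_null, y)
    rss_alt = _rss(X_alt, y)
    df1 = p_alt - p_null
    df2 = n - p_alt - 1
    num = max(rss_null - rss_alt, 0.0) / df1  # nesting: clip float jitter at 0
    if rss_alt > 0:
        f_stat = num / (rss_alt / df2)
        p_value = float(stats.f.sf(f_stat, df1, df2))
    else:
        f_stat = np.inf if num > 0 else 0.0
        p_value = 0.0 if num > 0 else 1.0
    return AgeDecouplingResult(
        rss_null=rss_null,
        rss_alt=rss_alt,
        p_null=p_null,
        p_alt=p_alt,
        n=n,
        f_stat=f_stat,
        p_value=p_value,
        threshold=threshold,
        passed=bool(p_value < threshold),
    )


def _aliased(X: np.ndarray, names: list[str]) -> list[str]:
    full = np.linalg.matrix_rank(X)
    out = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full:
            out.append(names[j])
    return out


def age_decoupling_table(
    scores: pd.DataFrame,
    age,
    disease,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Apply the nested F-test to every column of a score table.

    Returns a frame indexed by component with columns ``rss_null``,
    ``rss_alt``, ``f``, ``p``, ``passed``.
    """
    rows = []
    for comp in scores.columns:
        res = age_disease_ftest(scores[comp].to_numpy(), age, disease, threshold)
        rows.append(
            {
                "component": comp,
                "rss_null": res.rss_null,
                "rss_alt": res.rss_alt,
                "f": res.f_stat,
                "p": res.p_value,
                "passed": res.passed,
            }
        )
    return pd.DataFrame(rows).set_index("component")
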