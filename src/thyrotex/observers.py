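"""Observer-variability statistics for cystic-percentage tables.

The central quantity is the variance percentage between two observers,

    VP = (obs1 - obs2) / obs1 * 100,

computed per nodule with the first observer as reference; VP is undefined
(NA) when the reference reports 0% but the second observer does not, and 0
when both report 0% (no deviation exists). Composition categories on the
cystic percentage support classification-match percentages and a Pearson
chi-squared test of whether observers distribute nodules over categories
differently.

Observer tables are plain pandas DataFrames indexed by nodule id with one
column per observer (e.g. P1, P2, P3, DSS), entries in [0, 100].
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositionScheme",
    "DEFAULT_SCHEME",
    "variance_percentage",
    "variance_table",
    "render_truncated",
    "composition_category",
    "classification_match_percentage",
    "all_observer_match_percentage",
    "chi_squared_variance_test",
]


@dataclasses.dataclass(frozen=True)
class CompositionScheme:
    """Ordered breakpoints partitioning [0, 100] into named categories.

    Breakpoints are the interior bin edges; a boundary value belongs to
    the upper interval.
    """

    breakpoints: tuple[float, ...] = (10.0, 50.0, 90.0)
    names: tuple[str, ...] = (
        "solid",
        "predominantly solid",
        "predominantly cystic",
        "cystic",
    )

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if not all(0.0 < b < 100.0 for b in bp):
            raise ValueError("breakpoints must lie inside (0, 100)")
        if len(self.names) != len(bp) + 1:
            raise ValueError("need exactly len(breakpoints) + 1 category names")


DEFAULT_SCHEME = CompositionScheme()


def _check_pct(value: float, what: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0 or math.isnan(value):
        raise ValueError(f"{what} must lie in [0, 100], got {value}")
    return value


def variance_percentage(obs1: float, obs2: float) -> float:
    """Per-nodule disagreement of obs2 against reference obs1, in percent.

    Returns NaN (NA) for the undefined 0-denominator case obs1 = 0 < obs2,
    and 0.0 when both observers report 0 (no deviation exists).
    """
    obs1 = _check_pct(obs1, "obs1")
    obs2 = _check_pct(obs2, "obs2")
    if obs1 == 0.0:
        return 0.0 if obs2 == 0.0 else float("nan")
    return (obs1 - obs2) / obs1 * 100.0


def variance_table(table: pd.DataFrame, reference_column: str) -> pd.DataFrame:
    """Variance percentage of every non-reference observer vs the reference.

    Cell (i, j) = variance_percentage(table[i, j], table[i, reference]);
    NA cells are NaN. Use :func:`render_truncated` for printed-style output.
    """
    if reference_column not in table.columns:
        raise ValueError(f"reference column {reference_column!r} not in table")
    others = [c for c in table.columns if c != reference_column]
    out = pd.DataFrame(index=table.index, columns=others, dtype=float)
    for col in others:
        out[col] = [
            variance_percentage(o1, o2)
            for o1, o2 in zip(table[col], table[reference_column])
        ]
    return out


def render_truncated(value: float, decimals: int = 1) -> float:
    """Truncate toward zero at the given number of decimals (97.77 -> 97.7)."""
    if math.isnan(value):
        return float("nan")
    scale = 10.0**decimals
    return math.trunc(value * scale) / scale


def composition_category(cystic_percent: float, scheme: CompositionScheme = DEFAULT_SCHEME) -> str:
    """Name of the composition bin containing the given cystic percentage."""
    p = _check_pct(cystic_percent, "cystic_percent")
    idx = int(np.searchsorted(scheme.breakpoints, p, side="right"))
    return scheme.names[idx]


def _categorize(col: pd.Series, scheme: CompositionScheme) -> pd.Series:
    return col.map(lambda v: composition_category(v, scheme))


def classification_match_percentage(
    table: pd.DataFrame,
    observer: str,
    reference: str,
    scheme: CompositionScheme = DEFAULT_SCHEME,
) -> float:
    """Percent of nodules the observer and the reference place in the same
    composition category."""
    for col in (observer, reference):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    a = _categorize(table[observer], scheme)
    b = _categorize(table[reference], scheme)
    return 100.0 * float((a == b).mean())


def all_observer_match_percentage(
    table: pd.DataFrame,
    observers: Sequence[str],
    reference: str,
    scheme: CompositionScheme = DEFAULT_SCHEME,
) -> dict[str, float]:
    """Agreement of a whole observer panel with the reference.

    Two readings are returned because the underlying notion is ambiguous:
    ``all_agree_pct`` (primary) counts rows where every observer and the
    reference share one category; ``mean_observer_pct`` averages the
    pairwise match percentages of the individual observers.
    """
    if len(observers) < 2:
        raise ValueError("need at least 2 observers")
    cats = {c: _categorize(table[c], scheme) for c in (*observers, reference)}
    ref = cats[reference]
    agree_all = np.logical_and.reduce([cats[c] == ref for c in observers])
    pairwise = [
        classification_match_percentage(table, c, reference, scheme) for c in observers
    ]
    return {
        "all_agree_pct": 100.0 * float(np.mean(agree_all)),
        "mean_observer_pct": float(np.mean(pairwise)),
    }


def chi_squared_variance_test(
    table: pd.DataFrame,
    scheme: CompositionScheme = DEFAULT_SCHEME,
    observers: Sequence[str] | None = None,
) -> dict:
    """Pearson chi-squared on the observers x composition-categories
    contingency table of category counts (uncorrected, df = (r-1)(c-1)).

    A degenerate table with a single realized category returns statistic 0
    and p = 1 with a warning.
    """
    observers = list(observers) if observers is not None else list(table.columns)
    if len(observers) < 2:
        raise ValueError("need at least 2 observers")
    counts = pd.DataFrame(
        {
            c: _categorize(table[c], scheme).value_counts().reindex(scheme.names, fill_value=0)
            for c in observers
        }
    ).T
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2:
        warnings.warn("single realized composition category; test degenerate", stacklevel=2)
        return {"statistic": 0.0, "df": 0, "p_value": 1.0}
    res = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return {
        "statistic": float(res.statistic),
        "df": int(res.dof),
        "p_value": float(res.pvalue),
    }
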