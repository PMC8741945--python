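"""Group-comparison statistics for diversity tables.

The Mann-Whitney U test is exact (full enumeration of rank assignments)
for small samples without ties and otherwise uses the tie-corrected normal
approximation. Raw two-sided p-values are reported without multiplicity
adjustment by default; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

EXACT_MAX_N = 12  # exact enumeration when n_a + n_b <= this and no ties


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float  # U for group_a
    p_two_sided: float
    n_a: int
    n_b: int
    method: str  # "exact" or "approximate"


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= EXACT_MAX_N) and not ties
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=float(res.statistic),
        p_two_sided=float(min(1.0, res.pvalue)),
        n_a=len(x),
        n_b=len(y),
        method="exact" if exact else "approximate",
    )


def comparison_table(
    values: pd.DataFrame,
    grouping: dict[str, str],
    value_col: str,
    sample_col: str = "sample",
    by: list[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise group comparisons of a per-individual statistic.

    ``values`` is a long table with one row per individual (and optionally
    per stratum named in ``by``, e.g. the diversity order q); ``grouping``
    maps sample ID -> group label. One output row per unordered group pair
    per stratum. ``adjust=True`` appends Benjamini-Hochberg adjusted
    p-values; raw p-values are always reported.
    """
    by = by or []
    t = values.copy()
    t["_group"] = t[sample_col].map(grouping)
    if t["_group"].isna().any():
        missing = sorted(t.loc[t["_group"].isna(), sample_col].unique())
        raise ValueError(f"samples without a group: {missing}")
    groups = sorted(t["_group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    strata = t.groupby(by) if by else [((), t)]
    for key, sub in strata:
        key = key if isinstance(key, tuple) else (key,)
        for ga, gb in combinations(groups, 2):
            xa = sub.loc[sub["_group"] == ga, value_col].to_numpy()
            xb = sub.loc[sub["_group"] == gb, value_col].to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError(f"group {ga if len(xa) == 0 else gb} empty in stratum {key}")
            cmp = mann_whitney_u(xa, xb, ga, gb)
            rows.append(
                key + (ga, gb, cmp.n_a, cmp.n_b, cmp.statistic,
                       cmp.p_two_sided, cmp.method)
            )
    out = pd.DataFrame(
        rows,
        columns=by + ["group_a", "group_b", "n_a", "n_b", "U", "p", "method"],
    )
    if adjust:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)
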