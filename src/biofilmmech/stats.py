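"""Group statistics: one-way ANOVA with Tukey HSD post hoc comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InsufficientReplicatesError

__all__ = ["GroupComparison", "compare_groups"]


@dataclass
class GroupComparison:
    """One metric compared across treatment groups.

    ``group_stats``: one row per group (group, n, mean, sd).
    ``pairwise``: one row per unordered group pair with the mean difference,
    Tukey-adjusted and pooled-t unadjusted p-values, and a significance flag
    at ``alpha``.
    """

    metric: str
    group_stats: pd.DataFrame
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    alpha: float


def compare_groups(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05, metric: str = ""
) -> GroupComparison:
    """One-way ANOVA F/p plus Tukey honestly-significant-difference table.

    Every group needs n ≥ 2.  The unadjusted pairwise p-values use the
    pooled residual mean square from the full ANOVA (so Tukey-adjusted
    p ≥ unadjusted p for every pair).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise InsufficientReplicatesError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise InsufficientReplicatesError(f"group {g!r} has n={v.size} < 2")

    labels = list(groups)
    arrays = [groups[g] for g in labels]
    f_stat, p_val = sps.f_oneway(*arrays)

    values = np.concatenate(arrays)
    codes = np.concatenate([[g] * groups[g].size for g in labels])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)

    # pooled residual mean square for unadjusted pairwise t-tests
    df_resid = values.size - len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrays) / df_resid

    order = {g: i for i, g in enumerate(tukey.groupsunique)}
    pair_index = {
        pair: k for k, pair in enumerate(combinations(tukey.groupsunique, 2))
    }
    rows = []
    for a, b in combinations(sorted(labels, key=order.get), 2):
        k = pair_index[(a, b)]
        na, nb = groups[a].size, groups[b].size
        diff = groups[b].mean() - groups[a].mean()
        if mse > 0:
            t = abs(diff) / np.sqrt(mse * (1.0 / na + 1.0 / nb))
            p_unadj = 2.0 * sps.t.sf(t, df_resid)
        else:
            p_unadj = 1.0 if diff == 0 else 0.0
        p_adj = float(tukey.pvalues[k])
        rows.append({
            "group_a": a, "group_b": b, "mean_diff": float(diff),
            "p_tukey": p_adj, "p_unadjusted": float(p_unadj),
            "significant": bool(p_adj < alpha),
        })

    group_stats = pd.DataFrame({
        "group": labels,
        "n": [groups[g].size for g in labels],
        "mean": [groups[g].mean() for g in labels],
        "sd": [groups[g].std(ddof=1) for g in labels],
    })
    return GroupComparison(
        metric=metric,
        group_stats=group_stats,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )
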