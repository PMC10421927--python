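"""Group comparisons and survival utilities.

Route-level contrasts use the two-sided Mann-Whitney U test (exact
enumeration at small sample sizes without ties, tie-corrected normal
approximation otherwise; Welch's t test is selectable).  Raw p-values
are reported with no multiplicity adjustment.  Overall survival is
compared with the log-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GroupComparison

EXACT_N_LIMIT = 12  # exact Mann-Whitney enumeration up to n_a + n_b = 12


def route_comparison(values: dict[str, float], labels: dict[str, str],
                     group_a: str, group_b: str,
                     metric_name: str = "value",
                     method: str = "mann_whitney") -> GroupComparison:
    """Compare a per-sample metric between two route groups.

    ``values`` maps sample id to the metric; ``labels`` maps sample id to
    its group.  Exact Mann-Whitney enumeration is used when the combined
    sample size is at most 12 and there are no ties.
    """
    a = np.array([v for s, v in values.items() if labels.get(s) == group_a],
                 dtype=float)
    b = np.array([v for s, v in values.items() if labels.get(s) == group_b],
                 dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"empty group: {group_a} (n={len(a)}), {group_b} (n={len(b)})")

    if method == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        mw_method = ("exact" if len(a) + len(b) <= EXACT_N_LIMIT and not has_ties
                     else "asymptotic")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "t_test":
        res = sps.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "a_higher"
    elif med_b > med_a:
        direction = "b_higher"
    else:
        direction = "none"
    return GroupComparison(
        metric_name=metric_name, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b), statistic=statistic,
        p_value=min(p, 1.0), direction=direction,
    )


def logrank_test(survival: pd.DataFrame, group_field: str) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across survival groups.

    ``survival`` needs columns ``time`` (days), ``event`` (bool) and the
    grouping column.  Requires at least two groups and one event.
    """
    from lifelines.statistics import multivariate_logrank_test

    if (survival["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    groups = survival[group_field].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if not survival["event"].any():
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(
        survival["time"], survival[group_field],
        survival["event"].astype(int))
    return float(res.test_statistic), float(res.p_value)
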