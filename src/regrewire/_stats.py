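"""Small-sample statistical primitives shared across modules.

The exact Wilcoxon rank-sum branch enumerates all C(n1+n2, n1) group-label
assignments of the pooled average ranks, so it is valid with ties (scipy's
exact method refuses tied data).  Above the enumeration cutoff the normal
approximation with tie correction from scipy's Mann-Whitney U is used; the
two tests are equivalent (W = U + n1(n1+1)/2).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

#: Largest pooled sample size for which the exact permutation null is enumerated.
EXACT_LIMIT = 12

_ALTERNATIVES = ("two-sided", "greater", "less")


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value; exact by enumeration for n1+n2 <= 12.

    ``greater`` means the *x* population tends to larger values.  The exact
    two-sided p is the permutation probability of a rank sum at least as far
    from its null mean as observed.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    if n <= EXACT_LIMIT:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2.0
        total = 0
        count = 0
        dev_obs = abs(w_obs - mu)
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if alternative == "two-sided":
                count += abs(w - mu) >= dev_obs - 1e-12
            elif alternative == "greater":
                count += w >= w_obs - 1e-12
            else:
                count += w <= w_obs + 1e-12
        return count / total
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)
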