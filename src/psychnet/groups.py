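"""Kruskal-Wallis rank test with Dunn's Bonferroni-corrected post-hoc pairs.

Used for contrasts such as depression severity across medication groups,
where the outcome is an ordinal questionnaire total and normality cannot be
assumed.  The omnibus H statistic (tie-corrected) is referred to a
chi-square distribution with (groups - 1) degrees of freedom; pairwise
follow-ups use Dunn's z on the pooled ranks,

    z_ab = (Rbar_a - Rbar_b) / sqrt( (N(N+1)/12 - T) (1/n_a + 1/n_b) ),

with tie correction T = sum(t^3 - t) / (12 (N - 1)), and p-values adjusted
by Bonferroni over all pairs (adjusted p = min(1, p * n_pairs)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SpecError


@dataclass
class GroupTestResult:
    """Omnibus Kruskal-Wallis result plus Dunn's pairwise post-hoc table."""

    H: float
    df: int
    p: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def kruskal_wallis_bonferroni(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis test with Dunn/Bonferroni post-hoc.

    Parameters
    ----------
    values : 1-d numeric array
    groups : 1-d label array, same length; every group needs >= 2 rows

    The all-tied degenerate case returns H = 0, p = 1 and all adjusted
    post-hoc p-values 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise SpecError("values and groups must have the same length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise SpecError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise SpecError(f"group {g!r} has fewer than 2 observations")

    n = values.size
    df = len(labels) - 1
    if np.all(values == values[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*samples)
        H, p = float(H), float(p)

    ranks = stats.rankdata(values, method="average")
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(range(len(labels)), 2):
        ra = ranks[groups == labels[a]]
        rb = ranks[groups == labels[b]]
        denom = np.sqrt(var_base * (1.0 / ra.size + 1.0 / rb.size))
        z = 0.0 if denom == 0 else float((ra.mean() - rb.mean()) / denom)
        raw = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "group_a": labels[a],
                "group_b": labels[b],
                "z": z,
                "p_raw": raw,
                "p_bonferroni": min(1.0, raw * n_pairs),
            }
        )
    posthoc = pd.DataFrame(rows)
    return GroupTestResult(H=H, df=df, p=p, posthoc=posthoc)


__all__ = ["GroupTestResult", "kruskal_wallis_bonferroni"]
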