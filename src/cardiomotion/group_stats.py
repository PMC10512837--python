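"""Inter-group comparison of segmental CD_A and TMI with the Mann-Whitney U test.

Group sizes in small-animal studies are typically around seven per group,
where the normal approximation to the U distribution is poor.  The test
therefore enumerates all C(n_a + n_b, n_a) group labelings exactly
(midranks handle ties, counting half to each side) up to a combined sample
size of 16 and falls back to the tie-corrected normal approximation above
that.  Comparisons are reported per (group pair x segment x metric) at
alpha = 0.05 with no multiplicity correction by default; a
Benjamini-Hochberg option exists but defaults off.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: combined sample size up to which the exact permutation null is enumerated
EXACT_ENUMERATION_LIMIT = 16


@lru_cache(maxsize=32)
def _labelings(n_total: int, n_a: int) -> np.ndarray:
    """All index sets of size n_a out of n_total, as an (m, n_a) array."""
    return np.array(list(combinations(range(n_total), n_a)), dtype=np.intp)


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U statistic and p-value.

    U counts pairs where a > b, plus half of the tied pairs.  For combined
    sample sizes up to 16 the p-value is exact: every labeling of the
    pooled values is enumerated and the two-sided p is the probability,
    under random labeling, of a U at least as far from its null mean
    n_a n_b / 2 as observed.  Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("each sample must be 1-D with at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")

    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - offset)

    if n_a + n_b <= EXACT_ENUMERATION_LIMIT:
        combs = _labelings(n_a + n_b, n_a)
        u_all = ranks[combs].sum(axis=1) - offset
        mu = n_a * n_b / 2.0
        eps = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(u_all >= u_obs - eps))
        else:
            p = float(np.mean(u_all <= u_obs + eps))
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return u_obs, min(p, 1.0)


def compare_all(
    results_table: pd.DataFrame,
    comparisons: Iterable[tuple[str, str]],
    alpha: float = 0.05,
    metrics: Sequence[str] | None = None,
    alternative: str = "two-sided",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """U test for every requested (group pair x segment x metric).

    ``results_table`` is long format with one row per subject x segment x
    metric: columns ``group``, ``segment``, ``metric``, ``value``.
    Returns one row per comparison with U, p and a significance flag at
    ``alpha``.  ``bh_correction=True`` applies Benjamini-Hochberg across
    all rows before flagging (off by default).
    """
    required = {"group", "segment", "metric", "value"}
    missing_cols = required - set(results_table.columns)
    if missing_cols:
        raise ValueError(f"results table lacks columns: {sorted(missing_cols)}")
    available = sorted(results_table["group"].unique())
    if metrics is None:
        metrics = sorted(results_table["metric"].unique())
    segments = sorted(results_table["segment"].unique())

    rows = []
    for group_a, group_b in comparisons:
        for g in (group_a, group_b):
            if g not in available:
                raise ValueError(f"group {g!r} not in table; available: {available}")
        for segment in segments:
            for metric in metrics:
                sel = (results_table["segment"] == segment) & (results_table["metric"] == metric)
                va = results_table.loc[sel & (results_table["group"] == group_a), "value"].to_numpy()
                vb = results_table.loc[sel & (results_table["group"] == group_b), "value"].to_numpy()
                u, p = mann_whitney_u(va, vb, alternative=alternative)
                rows.append(
                    {
                        "group_a": group_a,
                        "group_b": group_b,
                        "segment": segment,
                        "metric": metric,
                        "n_a": va.size,
                        "n_b": vb.size,
                        "U": u,
                        "p": p,
                    }
                )
    report = pd.DataFrame(rows)
    if bh_correction and len(report):
        report["p_adjusted"] = stats.false_discovery_control(report["p"], method="bh")
        report["significant"] = report["p_adjusted"] < alpha
    else:
        report["significant"] = report["p"] < alpha
    return report
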