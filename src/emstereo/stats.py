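"""Per-animal aggregation and two-group comparison of ultrastructural endpoints.

The animal (not the synapse or the frame) is the statistical unit.
Before testing, extreme per-animal values — more than three
interquartile ranges above the 75th or below the 25th percentile — are
excluded, in a single pass over both groups pooled.  Group comparison
uses Student's pooled-variance two-sample t-test, two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnimalSummary",
    "GroupComparison",
    "GroupStatsError",
    "exclude_extremes",
    "compare_groups",
    "compare_endpoint",
]

#: exclusion fence in interquartile ranges beyond the quartiles
IQR_FENCE = 3.0


class GroupStatsError(ValueError):
    """Raised when a comparison cannot be formed (e.g. a group emptied)."""


@dataclass(frozen=True)
class AnimalSummary:
    """One animal's endpoint vector (densities per μm³, lengths/widths in μm)."""

    animal_id: str
    group: str
    endpoints: dict[str, float]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Student's t-test result for one endpoint."""

    endpoint: str
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: int
    p: float
    excluded: tuple[str, ...] = ()


def exclude_extremes(values, ids=None):
    """Drop extreme values beyond ``quartile ± 3·IQR``.

    Quartiles use linear interpolation between order statistics (the
    common statistics-package default).  Fences are computed once over
    the input and applied in a single pass; no re-computation after
    removal, so the rule is idempotent.  With fewer than four values
    quartiles are not meaningful and nothing is excluded (a warning is
    emitted).

    Returns ``(retained values, excluded values)`` as arrays, or, when
    ``ids`` is given, ``(retained ids, excluded ids)`` alongside.
    """
    vals = np.asarray(values, dtype=float)
    if ids is not None and len(ids) != len(vals):
        raise ValueError("ids and values must have equal length")
    if len(vals) < 4:
        if len(vals):
            warnings.warn(
                "fewer than 4 values: quartiles undefined, no exclusion performed",
                stacklevel=2,
            )
        keep = np.ones(len(vals), dtype=bool)
    else:
        q1, q3 = np.percentile(vals, [25.0, 75.0])  # linear interpolation
        iqr = q3 - q1
        keep = (vals >= q1 - IQR_FENCE * iqr) & (vals <= q3 + IQR_FENCE * iqr)
    if ids is None:
        return vals[keep], vals[~keep]
    ids = np.asarray(ids, dtype=object)
    return vals[keep], vals[~keep], list(ids[keep]), list(ids[~keep])


def compare_groups(
    a,
    b,
    endpoint: str = "",
    group_a: str = "A",
    group_b: str = "B",
    excluded: tuple[str, ...] = (),
) -> GroupComparison:
    """Student's (pooled-variance) two-sample t-test, two-sided.

    Means ± SEM per group are reported; df = n_a + n_b − 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise GroupStatsError(
            f"endpoint {endpoint!r}: need at least 2 values per group "
            f"after exclusion (got {len(a)} and {len(b)})"
        )
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        endpoint=endpoint,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(np.mean(a)),
        sem_a=float(sps.sem(a)),
        n_a=len(a),
        mean_b=float(np.mean(b)),
        sem_b=float(sps.sem(b)),
        n_b=len(b),
        t=float(res.statistic),
        df=len(a) + len(b) - 2,
        p=float(res.pvalue),
        excluded=tuple(excluded),
    )


def compare_endpoint(
    summaries: list[AnimalSummary],
    endpoint: str,
    group_a: str,
    group_b: str,
    pooled_exclusion: bool = True,
) -> GroupComparison:
    """Full endpoint comparison: gather per-animal values, exclude extremes,
    run the pooled t-test.

    ``pooled_exclusion=True`` (default) computes the IQR fences over both
    groups pooled, so exclusion cannot by itself create a group
    difference; ``False`` applies the rule within each group.
    """
    rows = [
        (s.animal_id, s.group, s.endpoints[endpoint])
        for s in summaries
        if s.group in (group_a, group_b) and endpoint in s.endpoints
        and np.isfinite(s.endpoints[endpoint])
    ]
    if not rows:
        raise GroupStatsError(f"endpoint {endpoint!r}: no values available")
    ids = [r[0] for r in rows]
    grp = np.array([r[1] for r in rows], dtype=object)
    vals = np.array([r[2] for r in rows], dtype=float)
    if pooled_exclusion:
        _, _, kept_ids, dropped_ids = exclude_extremes(vals, ids=ids)
    else:
        kept_ids, dropped_ids = [], []
        for g in (group_a, group_b):
            m = grp == g
            _, _, k, d = exclude_extremes(vals[m], ids=list(np.array(ids, dtype=object)[m]))
            kept_ids += k
            dropped_ids += d
    kept = set(kept_ids)
    a = [v for i, g, v in rows if g == group_a and i in kept]
    b = [v for i, g, v in rows if g == group_b and i in kept]
    if not a or not b:
        raise GroupStatsError(f"endpoint {endpoint!r}: a group was emptied by exclusion")
    return compare_groups(
        a, b, endpoint=endpoint, group_a=group_a, group_b=group_b,
        excluded=tuple(dropped_ids),
    )
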