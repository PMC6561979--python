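"""Test-retest repeatability and redundancy filtering of feature panels.

Features are first filtered by Lin's concordance correlation coefficient
(CCC) between test and retest extractions (default threshold 0.7), then
collapsed by grouping features whose pairwise coefficient of determination
R^2 is at or above 0.95 and keeping one representative per group — the
member with the largest dynamic range.  Grouping uses connected components
of the R^2 graph, which is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class UndefinedCCCError(ValueError):
    """Both input vectors are constant; concordance is undefined."""


def concordance_correlation(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), using
    1/n variances; lies in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1D vectors of length >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise UndefinedCCCError("both vectors constant")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def dynamic_range(x_test, x_retest) -> float:
    """DR = 1 - mean|test - retest| / (pooled max - pooled min), in [0, 1].

    A feature with zero pooled range carries no information; its DR is 0.
    """
    x = np.asarray(x_test, dtype=float)
    y = np.asarray(x_retest, dtype=float)
    if x.shape != y.shape:
        raise ValueError("test and retest vectors must have equal length")
    pooled = np.concatenate([x, y])
    rng = pooled.max() - pooled.min()
    if rng == 0:
        return 0.0
    return float(np.clip(1.0 - np.abs(x - y).mean() / rng, 0.0, 1.0))


def coefficient_of_determination(x, y) -> float:
    """Squared Pearson correlation, in [0, 1]; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need equal-length vectors of length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r**2)


@dataclass
class RepeatabilityReport:
    """Per-feature CCC, dynamic range and pass flag at ``ccc_min``."""

    ccc: pd.Series
    dynamic_range: pd.Series
    passed: pd.Series
    ccc_min: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ccc": self.ccc, "dynamic_range": self.dynamic_range,
                             "passed": self.passed})


@dataclass
class RedundancyGrouping:
    """Partition of feature names into R^2-linked groups with representatives."""

    groups: list[list[str]]
    representatives: list[str]
    r2_min: float

    def __post_init__(self) -> None:
        for g, rep in zip(self.groups, self.representatives):
            if rep not in g:
                raise ValueError("representative must belong to its group")


def filter_repeatable(table_test: pd.DataFrame, table_retest: pd.DataFrame,
                      ccc_min: float = 0.7
                      ) -> tuple[RepeatabilityReport, pd.DataFrame]:
    """Keep exactly the features with test-retest CCC >= ``ccc_min``.

    Features for which the CCC is undefined (both replicates constant) are
    flagged failed.  Subject order must match between the two tables.
    """
    if list(table_test.columns) != list(table_retest.columns):
        raise ValueError("feature columns of test and retest tables differ")
    if len(table_test) != len(table_retest):
        raise ValueError("test and retest tables have different subject counts")
    ccc, dr, passed = {}, {}, {}
    for name in table_test.columns:
        x = table_test[name].to_numpy(float)
        y = table_retest[name].to_numpy(float)
        dr[name] = dynamic_range(x, y)
        try:
            c = concordance_correlation(x, y)
        except UndefinedCCCError:
            c = np.nan
        ccc[name] = c
        passed[name] = bool(np.isfinite(c) and c >= ccc_min)
    report = RepeatabilityReport(pd.Series(ccc), pd.Series(dr),
                                 pd.Series(passed), ccc_min)
    kept = [n for n in table_test.columns if passed[n]]
    return report, table_test[kept].copy()


def group_redundant(table: pd.DataFrame, dr: pd.Series | dict,
                    r2_min: float = 0.95
                    ) -> tuple[RedundancyGrouping, pd.DataFrame]:
    """Collapse R^2-linked groups to their maximal-dynamic-range member.

    Groups are connected components of the graph with an edge wherever the
    pairwise R^2 is >= ``r2_min``.  Ties in DR break by larger variance,
    then lexicographic name.
    """
    names = list(table.columns)
    dr = pd.Series(dr)
    missing = [n for n in names if n not in dr.index]
    if missing:
        raise ValueError(f"dynamic range missing for features: {missing}")
    x = table.to_numpy(float)
    p = len(names)
    if p == 0:
        return RedundancyGrouping([], [], r2_min), table.copy()
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    adj = (r2 >= r2_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    groups: list[list[str]] = []
    reps: list[str] = []
    for c in range(n_comp):
        members = [names[i] for i in range(p) if labels[i] == c]
        order = sorted(members,
                       key=lambda n: (-dr[n], -sd[names.index(n)], n))
        groups.append(members)
        reps.append(order[0])
    kept = [n for n in names if n in set(reps)]
    grouping = RedundancyGrouping(groups, reps, r2_min)
    return grouping, table[kept].copy()


def qc_pipeline(table_test: pd.DataFrame, table_retest: pd.DataFrame,
                ccc_min: float = 0.7, r2_min: float = 0.95):
    """Full repeatability + redundancy reduction.

    Returns ``(report, grouping, reduced_table, counts)`` where ``counts``
    records the feature-count waterfall (initial -> post-CCC ->
    post-redundancy) and satisfies
    ``counts['final'] == counts['post_ccc'] - sum(group size - 1)``.
    """
    report, kept = filter_repeatable(table_test, table_retest, ccc_min)
    grouping, reduced = group_redundant(kept, report.dynamic_range, r2_min)
    counts = {"initial": table_test.shape[1], "post_ccc": kept.shape[1],
              "final": reduced.shape[1]}
    return report, grouping, reduced, counts
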