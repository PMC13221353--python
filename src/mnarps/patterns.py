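"""Missingness patterns and the minimum-cell-size pooling rule.

A missingness pattern is the binary indicator vector (1 ⇔ missing) of a row.
The pooling rule keeps every pattern with at least ``min_size`` members as its
own group, untouched. The remaining small patterns are pooled among
themselves: repeatedly, the smallest cluster merges with the closest other
small cluster (Euclidean distance between the representative — largest —
pattern vectors; ties go to the larger cluster, then the lexicographically
smaller pattern) until every pooled cluster reaches ``min_size``. A final
undersized leftover cluster is absorbed into the nearest large-pattern group
when one exists; with no large pattern and not enough rows to reach
``min_size`` at all, all rows form a single group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PatternTable:
    """Distinct missingness patterns ordered by member count (descending)."""

    patterns: np.ndarray  # (k, p) binary rows, count-descending
    counts: np.ndarray  # (k,)
    row_pattern: np.ndarray  # (n,) pattern index per data row

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


@dataclass
class PatternPooling:
    """Mapping of patterns into pooled groups satisfying the size rule."""

    group_of_pattern: np.ndarray  # (k,) group id per pattern
    group_counts: np.ndarray  # (g,)
    min_size: int

    @property
    def n_groups(self) -> int:
        return self.group_counts.size

    def row_groups(self, table: PatternTable) -> np.ndarray:
        """Group id per data row."""
        return self.group_of_pattern[table.row_pattern]


def extract_patterns(S: np.ndarray) -> PatternTable:
    """Enumerate distinct rows of the indicator table with counts."""
    S = np.asarray(S, dtype=int)
    if S.ndim != 2:
        raise ValueError("S must be 2-D")
    uniq, inverse, counts = np.unique(
        S, axis=0, return_inverse=True, return_counts=True
    )
    # order by count descending, lexicographic pattern as a deterministic tie-break
    order = np.lexsort(tuple(uniq[:, j] for j in range(uniq.shape[1] - 1, -1, -1)))
    order = order[np.argsort(-counts[order], kind="stable")]
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return PatternTable(
        patterns=uniq[order], counts=counts[order], row_pattern=rank[inverse]
    )


def pool_patterns(table: PatternTable, min_size: int = 100) -> PatternPooling:
    """Apply the minimum-cell-size pooling rule (default 100 observations)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    k = table.n_patterns
    counts = table.counts.astype(int)

    def dist2(a: int, b: int) -> float:
        return float(((table.patterns[a] - table.patterns[b]) ** 2).sum())

    # clusters: member pattern indices; representative = largest member
    clusters: list[dict] = [
        {"members": [i], "count": int(counts[i]), "rep": i, "large": counts[i] >= min_size}
        for i in range(k)
    ]

    def merge(dst: dict, src: dict) -> None:
        dst["members"].extend(src["members"])
        dst["count"] += src["count"]
        if counts[src["rep"]] > counts[dst["rep"]]:
            dst["rep"] = src["rep"]
        clusters.remove(src)

    # pool small patterns among themselves, smallest cluster first
    while True:
        small = [c for c in clusters if not c["large"] and c["count"] < min_size]
        if not small:
            break
        src = min(small, key=lambda c: (c["count"], tuple(table.patterns[c["rep"]])))
        peers = [c for c in small if c is not src]
        if peers:
            dst = min(
                peers,
                key=lambda c: (dist2(c["rep"], src["rep"]), -c["count"],
                               tuple(table.patterns[c["rep"]])),
            )
            merge(dst, src)
            continue
        # leftover undersized cluster: absorb into the nearest settled group
        others = [c for c in clusters if c is not src]
        if others:
            dst = min(
                others,
                key=lambda c: (dist2(c["rep"], src["rep"]), -c["count"],
                               tuple(table.patterns[c["rep"]])),
            )
            merge(dst, src)
        break  # nothing to merge with: the cluster stands alone

    clusters.sort(key=lambda c: (-c["count"], tuple(table.patterns[c["rep"]])))
    group_of_pattern = np.empty(k, dtype=int)
    for g, c in enumerate(clusters):
        for i in c["members"]:
            group_of_pattern[i] = g
    return PatternPooling(
        group_of_pattern=group_of_pattern,
        group_counts=np.array([c["count"] for c in clusters], dtype=int),
        min_size=min_size,
    )


def pooling_report(table: PatternTable, pooling: PatternPooling):
    """Long-format diagnostics: one row per pattern with its pooled group."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pattern": ["".join(map(str, row)) for row in table.patterns],
            "count": table.counts,
            "group": pooling.group_of_pattern,
        }
    )
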