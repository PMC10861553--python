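"""Independent brute-force oracles used to check pipeline operations.

Everything here deliberately recomputes results from first principles via
a different code path than the implementation: naive O(n^3) agglomeration
that rescans the original distance matrix, distinct-column enumeration by
set-of-tuples, and per-cell contingency scoring without any duplicate
collapse.
"""

from __future__ import annotations

import math

import numpy as np


def naive_complete_linkage(d: np.ndarray):
    """O(n^3) complete-linkage agglomeration, rescanning original distances.

    Returns a merge list [(left, right, height, count), ...] using the
    same node numbering and lexicographic tie-break as the implementation,
    but computes every inter-cluster distance directly as the max over
    original pairwise distances.
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or dist < best[0] or (dist == best[0] and (a, b) < best[1:]):
                    best = (dist, a, b)
        dist, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, float(dist), len(members)))
        clusters[next_id] = members
        next_id += 1
    return merges


def distinct_columns(matrix: np.ndarray) -> int:
    """Number of distinct columns, by direct set-of-tuples enumeration."""
    return len({tuple(matrix[:, j]) for j in range(matrix.shape[1])})


def brute_force_enrichment(labels: dict[str, int], frame) -> dict[tuple[int, str], float]:
    """log10 odds-ratio per (cluster, KO) with zero cells replaced by 0.5.

    Scores every KO column of the full (never deduplicated) matrix by
    explicit counting loops; unassigned isolates (label 0) are excluded.
    """
    scores: dict[tuple[int, str], float] = {}
    isolates = [i for i in frame.index if labels[i] != 0]
    cluster_ids = sorted({labels[i] for i in isolates})
    for cid in cluster_ids:
        for ko in frame.columns:
            a = b = c = d = 0
            for iso in isolates:
                present = frame.at[iso, ko] == 1
                if labels[iso] == cid:
                    a, b = a + present, b + (not present)
                else:
                    c, d = c + present, d + (not present)
            cells = [x if x else 0.5 for x in (a, b, c, d)]
            scores[(cid, ko)] = math.log10(cells[0] * cells[3] / (cells[1] * cells[2]))
    return scores


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (pair counting)."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    from collections import Counter

    ab = Counter(zip(labels_a, labels_b))
    a_count = Counter(labels_a)
    b_count = Counter(labels_b)
    comb = lambda x: x * (x - 1) // 2
    sum_ab = sum(comb(v) for v in ab.values())
    sum_a = sum(comb(v) for v in a_count.values())
    sum_b = sum(comb(v) for v in b_count.values())
    total = comb(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ab - expected) / (max_index - expected)
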