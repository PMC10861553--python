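"""Contingency odds-ratio scoring of KO content per isolate cluster.

For each cluster *i* and KO *j* a 2x2 table is tallied over the assigned
isolates — (a) in cluster with the KO, (b) in cluster without it, (c)
outside with it, (d) outside without it — and summarised by the odds ratio
``ad/bc``.  Cells equal to zero are replaced by 0.5 so the ratio stays
finite (Haldane–Anscombe style correction; by default only zero cells are
corrected, the classical all-cells form is available via ``correction``).
``log10(OR)`` ranks KOs by how characteristic they are of a cluster:
positive scores mark over-representation, negative under-representation.

KO columns collapsed as duplicates during clustering inherit the score of
their representative pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ko_profiles import ClusterAssignment, DuplicateMap, KOProfileMatrix

__all__ = ["ContingencyScore", "contingency_counts", "odds_ratio", "rank_cluster_kos"]


@dataclass(frozen=True)
class ContingencyScore:
    """Odds-ratio score of one (cluster, KO) pair."""

    cluster_id: int | None
    ko_id: str | None
    a: int
    b: int
    c: int
    d: int
    or_value: float
    score: float
    is_duplicate_of: str | None = None


def contingency_counts(
    assign: ClusterAssignment, m: KOProfileMatrix, cluster_id: int, ko_id: str
) -> tuple[int, int, int, int]:
    """Tally the 2x2 table for one cluster and one KO.

    Unassigned isolates (label 0) are excluded from both margins, so
    a+b+c+d equals the number of assigned isolates.
    """
    if cluster_id not in assign.cluster_ids():
        raise KeyError(f"unknown cluster {cluster_id}")
    if ko_id not in m.ko_ids:
        raise KeyError(f"unknown KO {ko_id}")
    j = m.ko_ids.index(ko_id)
    col = m.values[:, j]
    labels = np.array([assign.labels.get(iso, 0) for iso in m.isolate_ids])
    assigned = labels != 0
    inside = assigned & (labels == cluster_id)
    outside = assigned & (labels != cluster_id)
    a = int(col[inside].sum())
    b = int(inside.sum() - a)
    c = int(col[outside].sum())
    d = int(outside.sum() - c)
    return a, b, c, d


def odds_ratio(
    a: float, b: float, c: float, d: float, correction: str = "zero-cells"
) -> ContingencyScore:
    """Odds ratio ``ad/bc`` with a zero-cell correction.

    ``correction`` is ``"zero-cells"`` (add 0.5 only to cells that are 0),
    ``"all-cells"`` (classical: add 0.5 to every cell whenever any is 0)
    or ``"none"``.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (cells == 0).all():
        raise ValueError("all four contingency cells are zero")
    if correction not in ("zero-cells", "all-cells", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "zero-cells":
        cells = np.where(cells == 0, 0.5, cells)
    elif correction == "all-cells" and (cells == 0).any():
        cells = cells + 0.5
    ca, cb, cc, cd = cells
    if correction == "none" and (cb == 0 or cc == 0):
        raise ValueError("zero cell with correction disabled leaves OR undefined")
    or_value = (ca * cd) / (cb * cc)
    return ContingencyScore(None, None, int(a), int(b), int(c), int(d),
                            float(or_value), float(np.log10(or_value)))


def rank_cluster_kos(
    assign: ClusterAssignment,
    m: KOProfileMatrix,
    dup_maps: list[DuplicateMap] | None = None,
    correction: str = "zero-cells",
) -> pd.DataFrame:
    """Score every (cluster, KO) pair and rank KOs within each cluster.

    Returns a long-format frame with columns ``cluster_id, ko_id, a, b, c,
    d, or_value, log10_or, is_duplicate_of``, sorted per cluster by
    descending ``log10_or`` with ties broken by KO id.  Duplicate KOs (from
    ``dup_maps``) inherit their representative's score.
    """
    labels = np.array([assign.labels.get(iso, 0) for iso in m.isolate_ids])
    assigned = labels != 0
    if not assigned.any():
        raise ValueError("no assigned isolates")
    vals = m.values[assigned].astype(np.int64)
    labs = labels[assigned]
    n_assigned = int(assigned.sum())
    col_tot = vals.sum(axis=0)

    frames = []
    for cid in sorted(set(labs)):
        in_mask = labs == cid
        n_in = int(in_mask.sum())
        if n_in == 0:  # pragma: no cover - cluster_ids come from labels
            warnings.warn(f"cluster {cid} empty after excluding unassigned; skipped")
            continue
        a = vals[in_mask].sum(axis=0)
        b = n_in - a
        c = col_tot - a
        d = (n_assigned - n_in) - c
        cells = np.stack([a, b, c, d]).astype(float)
        if correction == "zero-cells":
            cells = np.where(cells == 0, 0.5, cells)
        elif correction == "all-cells":
            any_zero = (cells == 0).any(axis=0)
            cells = cells + 0.5 * any_zero
        ors = (cells[0] * cells[3]) / (cells[1] * cells[2])
        frames.append(pd.DataFrame({
            "cluster_id": cid,
            "ko_id": m.ko_ids,
            "a": a, "b": b, "c": c, "d": d,
            "or_value": ors,
            "log10_or": np.log10(ors),
            "is_duplicate_of": None,
        }))
    table = pd.concat(frames, ignore_index=True)

    if dup_maps:
        scored = set(m.ko_ids)
        member_of = {mem: g.representative_ko for g in dup_maps for mem in g.members}
        # members still present in the matrix keep their (identical) scores
        # and are only annotated; absent members inherit the representative's rows
        table["is_duplicate_of"] = table["ko_id"].map(member_of)
        extra = []
        for g in dup_maps:
            rep_rows = table[table["ko_id"] == g.representative_ko]
            for member in g.members:
                if member in scored:
                    continue
                inherited = rep_rows.copy()
                inherited["ko_id"] = member
                inherited["is_duplicate_of"] = g.representative_ko
                extra.append(inherited)
        if extra:
            table = pd.concat([table] + extra, ignore_index=True)

    table = table.sort_values(
        ["cluster_id", "log10_or", "ko_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table
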