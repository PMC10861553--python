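"""Gene-content profiles of bacterial isolates.

An isolate collection is summarised as a binary matrix of KEGG Orthology
(KO) annotations: rows are isolates, columns are KO identifiers, and an
entry of 1 records that the KO was called in that isolate's genome.  This
module loads and validates such matrices, removes uninformative columns
(zero-variance KOs and duplicate presence/absence patterns), and clusters
the isolates on Manhattan (Hamming) distance with complete linkage.  An
adaptive dendrogram cut then yields the gene-content clusters that stand in
for a whole-genome phylogeny of the collection.

All operations here are deterministic; no randomness is involved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KOProfileMatrix",
    "DuplicateMap",
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "load_ko_matrix",
    "filter_zero_variance",
    "collapse_duplicate_kos",
    "manhattan_distance",
    "complete_linkage",
    "dynamic_tree_cut",
    "split_cluster",
    "to_newick",
]

_KO_ID = re.compile(r"^K\d{5}$")


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what} id(s): {sorted(dups)[:5]}")
    return ids


@dataclass(frozen=True)
class KOProfileMatrix:
    """Binary isolate x KO presence/absence matrix.

    Parameters
    ----------
    isolate_ids : list of str
        Unique row identifiers.
    ko_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_isolates, n_kos)
        Entries in {0, 1}; 1 means the KO is present in the isolate.
    """

    isolate_ids: list[str]
    ko_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "isolate_ids", _check_unique(self.isolate_ids, "isolate"))
        object.__setattr__(self, "ko_ids", _check_unique(self.ko_ids, "KO"))
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.isolate_ids), len(self.ko_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.isolate_ids)} isolates x {len(self.ko_ids)} KOs"
            )
        if v.size and not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))][:3]
            raise ValueError(f"matrix entries must be 0/1; found {bad.tolist()}")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def n_isolates(self) -> int:
        return len(self.isolate_ids)

    @property
    def n_kos(self) -> int:
        return len(self.ko_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.isolate_ids, columns=self.ko_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KOProfileMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass(frozen=True)
class DuplicateMap:
    """One group of KO columns sharing an identical presence/absence pattern.

    ``members`` lists the collapsed columns; the representative (first in
    column order) is kept in the reduced matrix.
    """

    representative_ko: str
    members: list[str]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with named objects."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", _check_unique(self.ids, "object"))
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if (d < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence.

    ``merges`` holds one tuple per merge, ``(left, right, height, count)``,
    using the usual linkage numbering: leaves are ``0..n-1`` and the node
    created by merge *i* is ``n + i``.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self):
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights are not non-decreasing")
        if self.merges and self.merges[-1][3] != n:
            raise ValueError("final merge does not contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_linkage(self) -> np.ndarray:
        """Return the merge list as a scipy-style (n-1, 4) linkage array."""
        return np.array([[l, r, h, c] for l, r, h, c in self.merges], dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    """Map isolate id -> integer cluster label; 0 means unassigned."""

    labels: dict[str, int]

    def cluster_ids(self) -> list[int]:
        return sorted({v for v in self.labels.values() if v != 0})

    def members(self, cluster_id: int) -> list[str]:
        return [k for k, v in self.labels.items() if v == cluster_id]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids())


# ---------------------------------------------------------------------------
# loading / filtering

def load_ko_matrix(path, orientation: str = "auto", truthy: dict | None = None) -> KOProfileMatrix:
    """Load a tab-delimited binary KO matrix.

    The file has a header row and an id column.  ``orientation`` is one of
    ``"isolates_by_kos"``, ``"kos_by_isolates"`` or ``"auto"`` (rows whose
    ids look like KO accessions, ``K#####``, are taken to be KOs).
    ``truthy`` optionally maps raw cell values onto 0/1 before validation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if truthy:
        df = df.map(lambda x: truthy.get(x, x))
    if orientation not in ("auto", "isolates_by_kos", "kos_by_isolates"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        rows_are_kos = all(_KO_ID.match(i) for i in df.index)
        cols_are_kos = all(_KO_ID.match(c) for c in df.columns)
        if rows_are_kos and not cols_are_kos:
            df = df.T
    elif orientation == "kos_by_isolates":
        df = df.T
    vals = df.to_numpy()
    try:
        vals = vals.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in KO matrix: {err}") from None
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("KO matrix cells must be 0/1 after truthy mapping")
    return KOProfileMatrix(list(df.index), list(df.columns), vals.astype(np.uint8))


def filter_zero_variance(m: KOProfileMatrix) -> tuple[KOProfileMatrix, list[str]]:
    """Drop KO columns that are present in all isolates or in none."""
    col_sums = m.values.sum(axis=0)
    constant = (col_sums == 0) | (col_sums == m.n_isolates)
    removed = [ko for ko, c in zip(m.ko_ids, constant) if c]
    kept = [ko for ko, c in zip(m.ko_ids, constant) if not c]
    return KOProfileMatrix(m.isolate_ids, kept, m.values[:, ~constant]), removed


def collapse_duplicate_kos(m: KOProfileMatrix) -> tuple[KOProfileMatrix, list[DuplicateMap]]:
    """Reduce identical presence/absence columns to single representatives.

    The representative of each pattern is the first column in file order;
    the returned maps record every collapsed member.
    """
    first_idx: dict[bytes, int] = {}
    groups: dict[int, list[str]] = {}
    for j, ko in enumerate(m.ko_ids):
        key = m.values[:, j].tobytes()
        if key in first_idx:
            groups.setdefault(first_idx[key], []).append(ko)
        else:
            first_idx[key] = j
    keep = sorted(first_idx.values())
    reduced = KOProfileMatrix(m.isolate_ids, [m.ko_ids[j] for j in keep], m.values[:, keep])
    dup_maps = [DuplicateMap(m.ko_ids[j], members) for j, members in sorted(groups.items())]
    return reduced, dup_maps


def expand_duplicate_kos(m: KOProfileMatrix, dup_maps: list[DuplicateMap]) -> KOProfileMatrix:
    """Inverse of :func:`collapse_duplicate_kos` up to column order."""
    df = m.to_frame()
    extra = {}
    for g in dup_maps:
        for member in g.members:
            extra[member] = df[g.representative_ko]
    out = pd.concat([df, pd.DataFrame(extra, index=df.index)], axis=1) if extra else df
    return KOProfileMatrix.from_frame(out)


# ---------------------------------------------------------------------------
# distances and linkage

def manhattan_distance(m: KOProfileMatrix) -> DistanceMatrix:
    """Pairwise Manhattan distance between isolate rows.

    For a binary matrix this is the Hamming distance: the number of KO
    columns on which two isolates differ.
    """
    if m.n_isolates < 2:
        raise ValueError("need at least 2 isolates for a distance matrix")
    v = m.values.astype(np.int32)
    # |x - y| summed over binary columns == x + y - 2*x.y
    gram = v @ v.T
    sums = v.sum(axis=1)
    d = sums[:, None] + sums[None, :] - 2 * gram
    return DistanceMatrix(m.isolate_ids, d.astype(float))


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    Inter-cluster distance is the maximum pairwise distance between
    members (Lance-Williams update ``d_new = max(d_i, d_j)``).  Ties in
    the minimum inter-cluster distance are broken by the lexicographically
    smallest pair of node indices, so the merge sequence is
    bit-reproducible across runs and platforms.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 objects")
    cur = d.d.copy()
    np.fill_diagonal(cur, np.inf)
    node_ids = list(range(n))          # linkage node id per active row
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        m = len(node_ids)
        iu = np.triu_indices(m, k=1)
        flat = cur[iu]
        h = flat.min()
        # candidates at the exact minimum; break ties on node-id pairs
        cand = np.flatnonzero(flat == h)
        best = min(cand, key=lambda c: (node_ids[iu[0][c]], node_ids[iu[1][c]]))
        i, j = int(iu[0][best]), int(iu[1][best])
        li, lj = node_ids[i], node_ids[j]
        count = sizes[i] + sizes[j]
        merges.append((min(li, lj), max(li, lj), float(h), count))
        new_row = np.maximum(cur[i], cur[j])
        keep = [t for t in range(m) if t not in (i, j)]
        cur = cur[np.ix_(keep, keep)]
        new_row = new_row[keep]
        cur = np.pad(cur, ((0, 1), (0, 1)), constant_values=np.inf)
        cur[-1, :-1] = new_row
        cur[:-1, -1] = new_row
        node_ids = [node_ids[t] for t in keep] + [n + step]
        sizes = [sizes[t] for t in keep] + [count]
    return Dendrogram(list(d.ids), merges)


def to_newick(t: Dendrogram) -> str:
    """Serialise a dendrogram to Newick; branch lengths are height differences."""
    n = t.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (l, r, h, _c) in enumerate(t.merges):
        node = n + k
        height[node] = h
        children[node] = (l, r)

    def fmt(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{t.leaf_ids[node]}:{bl:.6g}"
        l, r = children[node]
        return f"({fmt(l, height[node])},{fmt(r, height[node])}):{bl:.6g}"

    root = n + len(t.merges) - 1
    l, r = children[root]
    h = height[root]
    return f"({fmt(l, h)},{fmt(r, h)});"


# ---------------------------------------------------------------------------
# adaptive tree cut

#: deep-split level -> (minimum gap as a fraction of the subtree's merge-
#: height range, minimum ratio of joining height to branch-internal height);
#: higher levels split more aggressively.
_DEEP_SPLIT_GAP = {
    0: (0.50, 1.35),
    1: (0.40, 1.27),
    2: (0.30, 1.20),
    3: (0.20, 1.12),
    4: (0.12, 1.05),
}


@dataclass
class _Node:
    idx: int
    height: float
    left: "_Node | None" = None
    right: "_Node | None" = None
    _leaves: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.idx]
        if not self._leaves:
            self._leaves = self.left.leaves() + self.right.leaves()
        return self._leaves

    def internal_heights(self) -> list[float]:
        if self.is_leaf:
            return []
        return self.left.internal_heights() + self.right.internal_heights() + [self.height]


def _build_tree(t: Dendrogram) -> _Node:
    n = t.n_leaves
    nodes: dict[int, _Node] = {i: _Node(i, 0.0) for i in range(n)}
    for k, (l, r, h, _c) in enumerate(t.merges):
        nodes[n + k] = _Node(n + k, h, nodes[l], nodes[r])
    return nodes[n + len(t.merges) - 1]


def _components_below(node: _Node, cut_h: float) -> list[_Node]:
    """Maximal subtrees whose top merge lies strictly below ``cut_h``."""
    if node.height < cut_h or node.is_leaf:
        return [node]
    return _components_below(node.left, cut_h) + _components_below(node.right, cut_h)


def dynamic_tree_cut(
    t: Dendrogram,
    d: DistanceMatrix,
    min_cluster_size: int = 3,
    deep_split: int = 2,
) -> ClusterAssignment:
    """Adaptive extraction of clusters from a dendrogram.

    Rather than cutting at one fixed height, each branch is examined for a
    significant gap in its internal merge heights.  A branch is cut in the
    widest such gap when (i) the gap is a large fraction of the branch's
    merge-height range and (ii) the merges above the gap sit well above
    those below it (joining/internal height ratio) — both thresholds set
    by ``deep_split`` (0 = conservative .. 4 = aggressive) — and the
    procedure recurses into the resulting branches.  Branches smaller than
    ``min_cluster_size`` are assigned to the nearest detected cluster by
    average distance when that distance is within the cut height, and are
    otherwise labelled 0 (unassigned).  Cluster labels are numbered 1.. by
    decreasing cluster size.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    if min_cluster_size > t.n_leaves:
        raise ValueError("min_cluster_size exceeds the number of objects")
    if deep_split not in _DEEP_SPLIT_GAP:
        raise ValueError(f"deep_split must be in {sorted(_DEEP_SPLIT_GAP)}")
    if list(t.leaf_ids) != list(d.ids):
        raise ValueError("dendrogram and distance matrix ids disagree")
    tau_gap, tau_ratio = _DEEP_SPLIT_GAP[deep_split]
    root = _build_tree(t)
    clusters: list[list[int]] = []
    orphans: list[tuple[list[int], float]] = []   # (leaves, cut height at orphaning)

    def descend(node: _Node) -> None:
        leaves = node.leaves()
        if node.is_leaf or len(leaves) < 2 * min_cluster_size or node.height <= 0:
            clusters.append(leaves)
            return
        hs = sorted(node.internal_heights())
        gaps = sorted(
            ((hs[i + 1] - hs[i], i) for i in range(len(hs) - 1)),
            key=lambda g: (-g[0], g[1]),
        )
        span = hs[-1] - hs[0] if hs[-1] > hs[0] else node.height
        for gap, i in gaps:
            if span <= 0 or gap / span < tau_gap:
                break
            if hs[i] > 0 and hs[i + 1] / hs[i] < tau_ratio:
                continue
            cut_h = (hs[i] + hs[i + 1]) / 2.0
            comps = _components_below(node, cut_h)
            big = [c for c in comps if len(c.leaves()) >= min_cluster_size]
            if len(big) < 2:
                continue
            for c in big:
                descend(c)
            for c in comps:
                if len(c.leaves()) < min_cluster_size:
                    orphans.append((c.leaves(), cut_h))
            return
        clusters.append(leaves)

    descend(root)

    # attach small branches to their nearest cluster, else leave unassigned
    labels = np.zeros(t.n_leaves, dtype=int)
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), min(clusters[k])))
    for rank, k in enumerate(order, start=1):
        labels[clusters[k]] = rank
    for leaves, cut_h in orphans:
        best_lab, best_avg = 0, np.inf
        for rank, k in enumerate(order, start=1):
            avg = d.d[np.ix_(leaves, clusters[k])].mean()
            if avg < best_avg:
                best_lab, best_avg = rank, avg
        if best_lab and best_avg <= cut_h:
            labels[leaves] = best_lab
    # renumber by decreasing size in case orphan attachment changed sizes
    sizes = {lab: int((labels == lab).sum()) for lab in set(labels) if lab != 0}
    remap = {lab: r for r, lab in enumerate(
        sorted(sizes, key=lambda x: (-sizes[x], x)), start=1)}
    final = {lid: (remap[lab] if lab else 0) for lid, lab in zip(t.leaf_ids, labels)}
    return ClusterAssignment(final)


def split_cluster(
    a: ClusterAssignment, cluster_id: int, partition: dict[str, int]
) -> ClusterAssignment:
    """Split one cluster into two by an explicit member partition.

    ``partition`` maps every member of ``cluster_id`` to 1 or 2; both
    parts must be non-empty.  Other labels are untouched; the two parts
    receive fresh labels above the current maximum.
    """
    members = set(a.members(cluster_id))
    if not members:
        raise ValueError(f"cluster {cluster_id} does not exist or is empty")
    if set(partition) != members:
        raise ValueError("partition must cover exactly the cluster's members")
    parts = set(partition.values())
    if parts != {1, 2}:
        raise ValueError("partition must place members in both part 1 and part 2")
    top = max(a.labels.values())
    new = dict(a.labels)
    for iso, part in partition.items():
        new[iso] = top + part
    return ClusterAssignment(new)
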