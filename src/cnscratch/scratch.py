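"""Transition-point fingerprinting and the SCRATCH clustering algorithm.

A transition point is a genomic boundary at which the copy number of
adjacent segments changes; the set of transition points is a fingerprint of
the dominant clone in a sample.  SCRATCH (Start of Copy number change for
Relationship Assessment and Testing Clone Histories) builds, per patient,
the samples x union-of-boundaries matrix of copy-number values, clusters
samples hierarchically on correlation distance, selects the number of
clusters by mean silhouette width, and merges any cluster with fewer than
two samples into the cluster sharing its most recent common ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import silhouette_score

from .profiles import SegmentProfile, DataError


@dataclass(frozen=True)
class TransitionPoint:
    """A segment boundary with a copy-number change across it."""

    chrom: str
    pos: int            # bp, a bin edge
    left: float
    right: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.right - self.left))


@dataclass
class TransitionMatrix:
    """Samples x union-of-boundary copy-number values."""

    sample_ids: list[str]
    boundaries: list[tuple[str, int]]   # (chrom, pos) ordered
    values: np.ndarray                  # shape (n_samples, n_boundaries)


@dataclass
class SampleTree:
    """Rooted dendrogram over sample leaves with cluster assignments.

    Leaves are node ids ``0..n-1`` in ``leaf_names`` order; internal nodes
    get higher ids with ``children`` and merge ``height``.
    """

    leaf_names: list[str]
    children: dict[int, tuple[int, ...]]
    height: dict[int, float]
    root: int
    linkage: np.ndarray | None = None
    labels: dict[str, int] | None = None
    k: int | None = None
    silhouette: float | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @classmethod
    def from_linkage(cls, z: np.ndarray, leaf_names: list[str]) -> "SampleTree":
        n = len(leaf_names)
        children = {}
        height = {i: 0.0 for i in range(n)}
        for i in range(len(z)):
            children[n + i] = (int(z[i, 0]), int(z[i, 1]))
            height[n + i] = float(z[i, 2])
        return cls(list(leaf_names), children, height, root=n + len(z) - 1,
                   linkage=z)

    def parent_map(self) -> dict[int, int]:
        return {c: p for p, kids in self.children.items() for c in kids}

    def clade_leaves(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if v >= self.n_leaves:
                stack.extend(self.children[v])
        return order[::-1]


# ---------------------------------------------------------------------------
# transition points
# ---------------------------------------------------------------------------

def _resolve_chroms(grid, chrom_subset) -> list[str]:
    if chrom_subset in (None, "autosomes"):
        return [c for c in grid.chrom_names if c != "chrX"]
    if chrom_subset == "chrX":
        return ["chrX"]
    if chrom_subset == "all":
        return list(grid.chrom_names)
    return list(chrom_subset)


def extract_transition_points(seg: SegmentProfile, chrom_subset="autosomes",
                              use: str = "cn") -> list[TransitionPoint]:
    """One transition point per internal segment boundary with a value change;
    chromosome-end boundaries are excluded."""
    if use == "cn" and "cn" not in seg.segments.columns:
        raise DataError("absolute CN not called; use='ratio' or call_absolute_cn")
    out = []
    for chrom in _resolve_chroms(seg.grid, chrom_subset):
        sub = seg.for_chrom(chrom).sort_values("start")
        vals = sub[use].to_numpy()
        pos = sub["start"].to_numpy()
        for i in range(1, len(sub)):
            if vals[i] != vals[i - 1]:
                out.append(TransitionPoint(chrom, int(pos[i]),
                                           float(vals[i - 1]), float(vals[i])))
    return out


def build_transition_matrix(profiles: list[SegmentProfile],
                            chrom_subset="autosomes",
                            use: str = "cn") -> TransitionMatrix:
    """Union of all samples' boundary positions (exact bin-edge matching on
    the shared grid); entry (s, b) is the value of the segment of sample s
    covering position b, i.e. the value immediately right of the boundary."""
    if len(profiles) < 1:
        raise DataError("need at least one profile")
    grid = profiles[0].grid
    if any(p.grid != grid for p in profiles):
        raise DataError("profiles do not share one bin grid")
    chroms = _resolve_chroms(grid, chrom_subset)
    boundaries: set[tuple[str, int]] = set()
    for p in profiles:
        for tp in extract_transition_points(p, chroms, use=use):
            boundaries.add((tp.chrom, tp.pos))
    ordered = sorted(boundaries, key=lambda b: (grid.chrom_names.index(b[0]), b[1]))
    values = np.empty((len(profiles), len(ordered)))
    by_chrom: dict[str, list[int]] = {}
    for j, (chrom, pos) in enumerate(ordered):
        by_chrom.setdefault(chrom, []).append(j)
    for i, p in enumerate(profiles):
        for chrom, cols in by_chrom.items():
            sub = p.for_chrom(chrom).sort_values("start")
            starts = sub["start"].to_numpy()
            vals = sub[use].to_numpy()
            pos = np.array([ordered[j][1] for j in cols])
            idx = np.searchsorted(starts, pos, side="right") - 1
            values[i, cols] = vals[idx]
    return TransitionMatrix([p.sample_id for p in profiles], ordered, values)


# ---------------------------------------------------------------------------
# distances & clustering
# ---------------------------------------------------------------------------

def correlation_distance(tm: TransitionMatrix, method: str = "pearson") -> np.ndarray:
    """d(i, j) = 1 - correlation of the two samples' transition-point values."""
    x = tm.values
    n = x.shape[0]
    if x.shape[1] < 2:
        raise DataError("need at least two transition-point columns")
    sd = x.std(axis=1)
    d = np.zeros((n, n))
    corr = {"pearson": pearsonr, "spearman": spearmanr}[method]
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                warnings.warn(f"zero-variance profile in pair ({i},{j}); "
                              "distance set to maximum")
                d[i, j] = d[j, i] = 2.0
            else:
                r = corr(x[i], x[j]).statistic
                d[i, j] = d[j, i] = 1.0 - r
    return np.clip(d, 0.0, 2.0)


def _merge_small_clusters(tree: SampleTree, labels: np.ndarray) -> np.ndarray:
    """Merge clusters with fewer than two leaves into the cluster sharing the
    most recent common ancestor on the dendrogram."""
    labels = labels.copy()
    parent = tree.parent_map()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) <= 1 or counts.min() >= 2:
            return labels
        small = ids[np.argmin(counts)]
        leaf = int(np.where(labels == small)[0][0])
        node = leaf
        target = None
        while node in parent:
            node = parent[node]
            clade = tree.clade_leaves(node)
            other = [labels[v] for v in clade if labels[v] != small]
            if other:
                vals, cnts = np.unique(other, return_counts=True)
                target = vals[np.argmax(cnts)]
                break
        if target is None:   # degenerate: no other cluster reachable
            return labels
        labels[labels == small] = target


def scratch_cluster(d: np.ndarray, sample_ids: list[str],
                    linkage: str = "complete", k_max: int = 8) -> SampleTree:
    """Agglomerative clustering with silhouette model selection.

    k* maximizes mean silhouette width over k in [2, min(k_max, n-1)]
    (smallest k on ties); clusters of size < 2 are then merged into their
    sibling clade until every cluster has at least two members or a single
    cluster remains.
    """
    n = len(sample_ids)
    if d.shape != (n, n):
        raise DataError("distance matrix does not match sample list")
    if n < 3:
        warnings.warn("fewer than 3 samples: returning a single cluster")
        if n == 1:
            tree = SampleTree(list(sample_ids), {}, {0: 0.0}, root=0)
        else:
            z = np.array([[0.0, 1.0, float(d[0, 1]), 2.0]])
            tree = SampleTree.from_linkage(z, list(sample_ids))
        tree.labels = {s: 1 for s in sample_ids}
        tree.k, tree.silhouette = 1, None
        return tree
    z = scipy_linkage(squareform(d, checks=False), method=linkage)
    tree = SampleTree.from_linkage(z, list(sample_ids))
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(d, labels, metric="precomputed")
        if sil > best_sil:
            best_k, best_sil, best_labels = k, float(sil), labels
    if best_labels is None:   # all-identical samples
        best_labels = np.ones(n, dtype=int)
        best_k, best_sil = 1, None
    merged = _merge_small_clusters(tree, np.asarray(best_labels))
    # renumber clusters consecutively in leaf order
    remap, relabeled = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(merged):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        relabeled[i] = remap[lab]
    tree.labels = {s: int(relabeled[i]) for i, s in enumerate(sample_ids)}
    tree.k = len(remap)
    tree.silhouette = best_sil
    return tree


# ---------------------------------------------------------------------------
# transition-point sharing
# ---------------------------------------------------------------------------

def _tp_keys(seg: SegmentProfile, chrom_subset, match_direction: bool,
             use: str = "cn") -> set:
    tps = extract_transition_points(seg, chrom_subset, use=use)
    if match_direction:
        return {(tp.chrom, tp.pos, tp.direction) for tp in tps}
    return {(tp.chrom, tp.pos) for tp in tps}


def shared_transition_fraction(query: SegmentProfile, targets: list[SegmentProfile],
                               mode: str = "any", match_direction: bool = True,
                               chrom_subset="autosomes", use: str = "cn") -> float:
    """Fraction of the query's transition points present in >=1 target
    (mode='any') or in every target (mode='all'); NaN when the query has no
    transition points."""
    q = _tp_keys(query, chrom_subset, match_direction, use)
    if not q:
        warnings.warn(f"{query.sample_id} has no transition points")
        return float("nan")
    tsets = [_tp_keys(t, chrom_subset, match_direction, use) for t in targets]
    if mode == "any":
        hit = set().union(*tsets) if tsets else set()
        return len(q & hit) / len(q)
    if mode == "all":
        return sum(1 for tp in q if all(tp in t for t in tsets)) / len(q)
    raise ValueError("mode must be 'any' or 'all'")


SHARING_BINS = ((0.0, 0.2, "<20%"), (0.2, 0.8, "20-80%"), (0.8, 1.0001, ">80%"))


def bin_shared_fraction(f: float) -> str:
    """Categorical bin for a shared fraction: <20%, 20-80% (inclusive), >80%."""
    if f < 0.2:
        return "<20%"
    if f <= 0.8:
        return "20-80%"
    return ">80%"


def pairwise_shared_matrix(profiles: list[SegmentProfile],
                           chrom_subset="autosomes", match_direction: bool = True,
                           use: str = "cn") -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of pairwise shared transition-point fractions
    (|intersection| / smaller set size) plus the categorical binning."""
    if len(profiles) < 2:
        raise DataError("need at least two profiles")
    keys = [_tp_keys(p, chrom_subset, match_direction, use) for p in profiles]
    n = len(profiles)
    frac = np.ones((n, n))
    cats = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            if i != j:
                denom = min(len(keys[i]), len(keys[j]))
                frac[i, j] = (len(keys[i] & keys[j]) / denom) if denom else np.nan
            cats[i, j] = bin_shared_fraction(frac[i, j]) if np.isfinite(frac[i, j]) else "NA"
    return frac, cats
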