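"""Topological agreement between two dendrograms over the same samples.

Two measures are provided: Baker's Gamma — the rank correlation
(Goodman-Kruskal gamma by default) between the merge levels at which leaf
pairs first co-cluster in each tree — and the congruence index I_cong, the
observed maximum agreement subtree (MAST) size relative to its expectation
under random leaf relabelings, with a Monte-Carlo permutation p-value.

The MAST statistic takes few integer values, so the permutation null is
heavily tied; `congruence_index` therefore defaults to the randomized
(tie-broken) Monte-Carlo p-value, which is exactly uniform under the null.
The conservative (1 + #{>= obs}) / (B + 1) rule remains available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .scratch import SampleTree
from .profiles import DataError


@dataclass
class CongruenceResult:
    bakers_gamma: float
    gamma_p: float | None
    mast_size: int
    i_cong: float
    icong_p: float
    n_permutations: int
    seed: int
    congruent: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Baker's Gamma
# ---------------------------------------------------------------------------

def merge_levels(tree: SampleTree) -> np.ndarray:
    """For each leaf pair (i<j, in leaf-name order), the number of clusters
    present when the pair first co-clusters, scanning cuts from n down to 1."""
    n = tree.n_leaves
    order = sorted((node for node in tree.children), key=lambda v: tree.height[v])
    # cluster count at the cut through each node's height; merges at tied
    # heights count together, so mirrored trees give identical levels
    heights = np.array([tree.height[v] for v in order])
    sizes = np.array([len(tree.children[v]) - 1 for v in order])
    level_of_node = {}
    for node in order:
        h = tree.height[node]
        level_of_node[node] = n - int(sizes[heights <= h].sum())
    # MRCA per leaf pair via clade sweep (small n; quadratic is fine)
    name_pos = {name: i for i, name in enumerate(tree.leaf_names)}
    levels = np.empty(n * (n - 1) // 2)
    pair_index = lambda i, j: i * n - i * (i + 1) // 2 + (j - i - 1)
    filled = np.zeros(n * (n - 1) // 2, dtype=bool)
    for node in order:   # ascending height: first co-clustering wins
        kids = tree.children[node]
        kid_leaves = [tree.clade_leaves(c) for c in kids]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for u in kid_leaves[a]:
                    for v in kid_leaves[b]:
                        i, j = sorted((name_pos[tree.leaf_names[u]],
                                       name_pos[tree.leaf_names[v]]))
                        idx = pair_index(i, j)
                        if not filled[idx]:
                            levels[idx] = level_of_node[node]
                            filled[idx] = True
    if not filled.all():
        raise DataError("tree does not connect all leaves")
    return levels


def goodman_kruskal_gamma(x: np.ndarray, y: np.ndarray) -> float:
    """(C - D) / (C + D) over concordant/discordant pairs."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    c = np.sum(prod > 0) // 2
    d = np.sum(prod < 0) // 2
    if c + d == 0:
        return 1.0 if np.array_equal(x, y) else 0.0
    return float((c - d) / (c + d))


def bakers_gamma(t1: SampleTree, t2: SampleTree, method: str = "gamma") -> float:
    """Rank correlation between the two trees' pairwise merge-level vectors."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise DataError("trees must share an identical leaf set")
    if t1.n_leaves < 3:
        raise DataError("need at least 3 leaves")
    # align t2's pair ordering to t1's leaf-name order
    l1 = _levels_in_order(t1, t1.leaf_names)
    l2 = _levels_in_order(t2, t1.leaf_names)
    if method == "gamma":
        return goodman_kruskal_gamma(l1, l2)
    if method == "spearman":
        return float(spearmanr(l1, l2).statistic)
    raise ValueError("method must be 'gamma' or 'spearman'")


def _levels_in_order(tree: SampleTree, name_order: list[str]) -> np.ndarray:
    n = tree.n_leaves
    raw = merge_levels(tree)
    pos = {name: i for i, name in enumerate(tree.leaf_names)}
    pair_index = lambda i, j: i * n - i * (i + 1) // 2 + (j - i - 1)
    out = np.empty_like(raw)
    k = 0
    for a in range(n):
        for b in range(a + 1, n):
            i, j = sorted((pos[name_order[a]], pos[name_order[b]]))
            out[k] = raw[pair_index(i, j)]
            k += 1
    return out


# ---------------------------------------------------------------------------
# maximum agreement subtree
# ---------------------------------------------------------------------------

def _binarize(tree: SampleTree) -> tuple[list[tuple[int, int]], list[int], list[str]]:
    """Deterministic left-leaning binarization, children ordered by the
    smallest leaf label in their clade.  Returns (children list indexed by
    node id, postorder, leaf names); leaves are ids 0..n-1."""
    n = tree.n_leaves
    children: list[tuple[int, int] | None] = [None] * n
    min_label = {i: tree.leaf_names[i] for i in range(n)}

    def build(node: int) -> int:
        if node < n:
            return node
        kids = [build(c) for c in tree.children[node]]
        kids.sort(key=lambda c: min_label[c])
        left = kids[0]
        for right in kids[1:]:
            children.append((left, right))
            new = len(children) - 1
            min_label[new] = min(min_label[left], min_label[right])
            left = new
        return left

    root = build(tree.root)
    post: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        post.append(v)
        if children[v] is not None:
            stack.extend(children[v])
    return children, post[::-1], list(tree.leaf_names)


def mast_size(t1: SampleTree, t2: SampleTree, cap: int = 64) -> int:
    """Size of the rooted maximum agreement subtree by exact dynamic
    programming over node pairs; multifurcations are resolved by a
    deterministic left-leaning binarization."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise DataError("trees must share an identical leaf set")
    if t1.n_leaves > cap:
        raise DataError(f"{t1.n_leaves} leaves exceeds the DP cap ({cap}); "
                        "raise `cap` knowingly or subsample leaves")
    c1, post1, names1 = _binarize(t1)
    c2, post2, names2 = _binarize(t2)
    return _mast_dp(c1, post1, names1, c2, post2, names2)


def _mast_dp(c1, post1, names1, c2, post2, names2) -> int:
    n1, n2 = len(c1), len(c2)
    m = np.zeros((n1, n2), dtype=np.int64)
    for u in post1:
        u_leaf = c1[u] is None
        for v in post2:
            v_leaf = c2[v] is None
            if u_leaf and v_leaf:
                m[u, v] = 1 if names1[u] == names2[v] else 0
            elif u_leaf:
                vl, vr = c2[v]
                m[u, v] = max(m[u, vl], m[u, vr])
            elif v_leaf:
                ul, ur = c1[u]
                m[u, v] = max(m[ul, v], m[ur, v])
            else:
                ul, ur = c1[u]
                vl, vr = c2[v]
                m[u, v] = max(m[ul, vl] + m[ur, vr],
                              m[ul, vr] + m[ur, vl],
                              m[u, vl], m[u, vr],
                              m[ul, v], m[ur, v])
    return int(m[post1[-1], post2[-1]])


def permute_leaves(tree: SampleTree, rng: np.random.Generator) -> SampleTree:
    """A copy of the tree with leaf labels randomly permuted."""
    perm = rng.permutation(tree.n_leaves)
    names = [tree.leaf_names[i] for i in perm]
    return SampleTree(names, dict(tree.children), dict(tree.height), tree.root,
                      linkage=tree.linkage)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _p_value(obs: float, perm: np.ndarray, tie_break: str,
             rng: np.random.Generator) -> float:
    b = len(perm)
    if tie_break == "conservative":
        return float((1 + np.sum(perm >= obs)) / (b + 1))
    if tie_break == "randomized":
        greater = int(np.sum(perm > obs))
        equal = int(np.sum(perm == obs))
        return float((greater + rng.uniform() * (equal + 1)) / (b + 1))
    raise ValueError("tie_break must be 'conservative' or 'randomized'")


def permutation_p(statistic, t1: SampleTree, t2: SampleTree, n_perm: int = 999,
                  seed: int = 0, tie_break: str = "conservative") -> float:
    """Monte-Carlo p-value for `statistic(t1, t2)` against leaf-label
    permutations of t2 (larger statistic = more congruent)."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    obs = statistic(t1, t2)
    perm = np.array([statistic(t1, permute_leaves(t2, rng)) for _ in range(n_perm)])
    return _p_value(obs, perm, tie_break, rng)


def congruence_index(t1: SampleTree, t2: SampleTree, n_perm: int = 999,
                     seed: int = 0, tie_break: str = "randomized",
                     alpha: float = 0.01, mast_cap: int = 64) -> CongruenceResult:
    """I_cong = MAST size / mean MAST under leaf-label permutations, with a
    Monte-Carlo p-value from the same permutation distribution; the pair is
    declared congruent when p < 0.01."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    obs = mast_size(t1, t2, cap=mast_cap)
    perm = np.array([mast_size(t1, permute_leaves(t2, rng), cap=mast_cap)
                     for _ in range(n_perm)])
    i_cong = obs / float(perm.mean())
    p = _p_value(obs, perm, tie_break, rng)
    gamma = bakers_gamma(t1, t2)
    degenerate = t1.n_leaves <= 3
    return CongruenceResult(bakers_gamma=gamma, gamma_p=None, mast_size=obs,
                            i_cong=float(i_cong), icong_p=p,
                            n_permutations=n_perm, seed=seed,
                            congruent=bool(p < alpha), degenerate=degenerate)


def compare_trees(t1: SampleTree, t2: SampleTree, n_perm: int = 999,
                  seed: int = 0) -> CongruenceResult:
    """Full congruence report: Baker's Gamma with its own permutation p plus
    the MAST-based congruence index."""
    res = congruence_index(t1, t2, n_perm=n_perm, seed=seed)
    res.gamma_p = permutation_p(bakers_gamma, t1, t2, n_perm=n_perm,
                                seed=seed + 1, tie_break="randomized")
    return res


def random_tree(n: int, rng: np.random.Generator,
                prefix: str = "S") -> SampleTree:
    """A random binary dendrogram over n labeled leaves (random sequential
    joins with increasing heights); used for null simulations."""
    names = [f"{prefix}{i}" for i in range(n)]
    nodes = list(range(n))
    children: dict[int, tuple[int, ...]] = {}
    height = {i: 0.0 for i in range(n)}
    nxt, h = n, 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        h += float(rng.uniform(0.1, 1.0))
        children[nxt] = (a, b)
        height[nxt] = h
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    return SampleTree(names, children, height, root=nodes[0])
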