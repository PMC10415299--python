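"""Independent brute-force oracles used by the acceptance script.

These deliberately avoid the package's own algorithms: the MAST oracle
maximizes over explicit leaf subsets, and the transition-point oracle is a
plain adjacent-value diff over expanded bins.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from cnscratch import BinGrid
from cnscratch.profiles import SegmentProfile

ORACLE_GRID = BinGrid(chrom_names=("chr1", "chr2"), chrom_bins=(40, 40))


def restrict_topology(tree, subset):
    """Canonical rooted topology restricted to a leaf subset."""

    def rec(node):
        if node < tree.n_leaves:
            name = tree.leaf_names[node]
            return name if name in subset else None
        kids = [rec(c) for c in tree.children[node]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return frozenset(kids)

    return rec(tree.root)


def brute_force_mast(t1, t2) -> int:
    """Exhaustive rooted MAST over all leaf subsets (feasible for n <= 10)."""
    names = t1.leaf_names
    for size in range(len(names), 1, -1):
        for sub in combinations(names, size):
            s = set(sub)
            if restrict_topology(t1, s) == restrict_topology(t2, s):
                return size
    return 1


def seg_from_random_values(rng: np.random.Generator):
    """A random two-chromosome segment profile plus the expected transition
    points from a plain adjacent-value diff."""
    w = ORACLE_GRID.bin_width
    rows, expect = [], []
    for chrom in ORACLE_GRID.chrom_names:
        vals = rng.integers(0, 5, size=40)
        start = 0
        for i in range(1, 41):
            if i == 40 or vals[i] != vals[start]:
                rows.append((chrom, start * w, i * w, start, i, i - start,
                             float(vals[start]), float(vals[start])))
                start = i
        for i in range(1, 40):
            if vals[i] != vals[i - 1]:
                expect.append((chrom, i * w, float(vals[i - 1]), float(vals[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_bin",
                                     "end_bin", "n_bins", "ratio", "cn"])
    return SegmentProfile("oracle", ORACLE_GRID, df), expect
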