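"""Readers and writers for the plain-text interchange formats.

SEG-like TSV (sample, chrom, start, end, value[, cn]) for segment profiles,
BED for transition points, Newick for sample trees (via dendropy), and thin
TSV wrappers for SNP, mutation and expression tables.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .genome import BinGrid
from .profiles import SegmentProfile, DataError
from .scratch import SampleTree, TransitionPoint

SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]


def write_seg(profiles: list[SegmentProfile], path) -> None:
    rows = []
    for p in profiles:
        for r in p.segments.itertuples():
            row = [p.sample_id, r.chrom, int(r.start), int(r.end), float(r.ratio)]
            if "cn" in p.segments.columns:
                row.append(float(r.cn))
            rows.append(row)
    cols = SEG_COLUMNS + (["cn"] if rows and len(rows[0]) == 6 else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_seg(path, grid: BinGrid) -> list[SegmentProfile]:
    """Read a SEG-like TSV into per-sample SegmentProfiles; rows are sorted
    deterministically and coordinates validated against the grid."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty SEG file")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise DataError(f"{path}: no segment rows")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["chrom"] not in grid.chrom_names:
            raise DataError(f"{path}:{line}: unknown chromosome {row['chrom']!r}")
        for c in ("start", "end"):
            if row[c] % grid.bin_width != 0:
                raise DataError(f"{path}:{line}: {c}={row[c]} off the bin grid")
        if not row["start"] < row["end"]:
            raise DataError(f"{path}:{line}: start must be < end")
    chrom_order = {c: i for i, c in enumerate(grid.chrom_names)}
    df = df.sort_values(["sample", "chrom", "start"],
                        key=lambda s: s.map(chrom_order) if s.name == "chrom" else s)
    out = []
    for sid, sub in df.groupby("sample", sort=True):
        seg = sub.copy()
        seg["start_bin"] = seg["start"] // grid.bin_width
        seg["end_bin"] = seg["end"] // grid.bin_width
        seg["n_bins"] = seg["end_bin"] - seg["start_bin"]
        seg = seg.rename(columns={"value": "ratio"}).drop(columns=["sample"])
        cols = ["chrom", "start", "end", "start_bin", "end_bin", "n_bins", "ratio"]
        if "cn" in seg.columns:
            cols.append("cn")
        out.append(SegmentProfile(str(sid), grid, seg[cols].reset_index(drop=True)))
    return out


def write_transition_bed(tps: list[TransitionPoint], sample_id: str, path) -> None:
    """BED rows (chrom, pos-1, pos, sample, delta) for transition points."""
    with open(path, "w") as fh:
        for tp in tps:
            delta = tp.right - tp.left
            fh.write(f"{tp.chrom}\t{tp.pos - 1}\t{tp.pos}\t{sample_id}\t{delta:g}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def tree_to_newick(tree: SampleTree) -> str:
    def fmt(node: int, parent_h: float) -> str:
        bl = parent_h - tree.height[node]
        if node < tree.n_leaves:
            label = tree.leaf_names[node]
            if any(ch in label for ch in " ()[]:;,'"):
                label = "'" + label.replace("'", "''") + "'"
            return f"{label}:{bl:.10g}"
        inner = ",".join(fmt(c, tree.height[node]) for c in tree.children[node])
        return f"({inner}):{bl:.10g}"

    root_h = tree.height[tree.root]
    if tree.root < tree.n_leaves:
        return f"{tree.leaf_names[tree.root]};"
    inner = ",".join(fmt(c, root_h) for c in tree.children[tree.root])
    return f"({inner});"


def write_newick(tree: SampleTree, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def newick_to_tree(text: str) -> SampleTree:
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)
    leaves = [lf for lf in dt.leaf_node_iter()]
    names = [lf.taxon.label for lf in leaves]
    ids: dict = {}
    children: dict[int, tuple[int, ...]] = {}
    depth: dict[int, float] = {}

    for i, lf in enumerate(leaves):
        ids[lf] = i
    nxt = len(leaves)
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            continue
        ids[node] = nxt
        children[nxt] = tuple(ids[c] for c in node.child_nodes())
        nxt += 1
    # root distances -> heights above the deepest leaf in each clade
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            depth[ids[node]] = 0.0
        else:
            depth[ids[node]] = depth[ids[node.parent_node]] + (node.edge.length or 0.0)
    max_depth = {}
    for node in dt.postorder_node_iter():
        nid = ids[node]
        if node.is_leaf():
            max_depth[nid] = depth[nid]
        else:
            max_depth[nid] = max(max_depth[ids[c]] for c in node.child_nodes())
    height = {nid: max_depth[nid] - depth[nid] if nid in children else 0.0
              for nid in ids.values()}
    # leaves sit at height 0 in a dendrogram
    for i in range(len(leaves)):
        height[i] = 0.0
    return SampleTree(names, children, height, root=ids[dt.seed_node])


def read_newick(path) -> SampleTree:
    text = Path(path).read_text()
    if text.count("(") != text.count(")"):
        raise DataError(f"{path}: unbalanced parentheses in Newick")
    return newick_to_tree(text)


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_mutations(mutation_sets: dict[str, set[str]], path) -> None:
    rows = [(s, m) for s in sorted(mutation_sets) for m in sorted(mutation_sets[s])]
    pd.DataFrame(rows, columns=["sample", "mutation_id"]).to_csv(path, sep="\t",
                                                                 index=False)


def read_mutations(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {s: set(g["mutation_id"]) for s, g in df.groupby("sample")}
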