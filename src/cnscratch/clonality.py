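"""Breakpoint cancer-cell fractions, clonal-mutation overlap and the
cluster-level hypothesis tests.

The cancer cell fraction (CCF) of a structural-variant breakpoint adjusts
its allelic fraction for tumor content and local copy number:

    CCF = AF * (rho*CN_t + c_n*(1-rho)) / (rho*m)

with c_n = 2 on autosomes and 1 on (male) chrX, and m the variant-allele
multiplicity (default 1: the conservative choice when shallow data cannot
resolve it).  Values above the cap (default 1.0) arise from noise or
mis-specified copy number and are capped, with the raw value retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .profiles import DataError

SV_CLASSES = ("BND", "DEL", "DUP", "INV")


@dataclass
class BreakpointCall:
    sample_id: str
    sv_class: str
    chrom: str
    pos: int
    af: float
    cn_t: float | None = None
    multiplicity: int = 1
    ccf: float | None = None
    ccf_raw: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.af <= 1:
            raise ValueError("allelic fraction must lie in [0, 1]")
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"SV class must be one of {SV_CLASSES}")


def breakpoint_ccf(af: float, rho: float, cn_t: float, m: int = 1,
                   chrom: str = "autosome", ccf_cap: float = 1.0) -> float:
    """Breakpoint cancer cell fraction, capped at ``ccf_cap``."""
    if not 0 < rho <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    c_n = 1.0 if chrom == "chrX" else 2.0
    raw = af * (rho * cn_t + c_n * (1.0 - rho)) / (rho * m)
    return float(min(raw, ccf_cap))


def annotate_breakpoints(calls: list[BreakpointCall], rho: float,
                         ccf_cap: float = 1.0) -> list[BreakpointCall]:
    """Fill ccf/ccf_raw on each call (cn_t defaulting to the germline copy
    number of its chromosome when unknown)."""
    for c in calls:
        cn_t = c.cn_t if c.cn_t is not None else (1.0 if c.chrom == "chrX" else 2.0)
        c_n = 1.0 if c.chrom == "chrX" else 2.0
        c.ccf_raw = c.af * (rho * cn_t + c_n * (1.0 - rho)) / (rho * c.multiplicity)
        c.ccf = min(c.ccf_raw, ccf_cap)
    return calls


# ---------------------------------------------------------------------------
# clonal mutation overlap
# ---------------------------------------------------------------------------

def clonal_overlap(a: set[str], b: set[str]) -> float:
    """|a & b| / min(|a|, |b|); NaN (with a warning) for an empty set."""
    if not a or not b:
        warnings.warn("clonal overlap undefined for an empty mutation set")
        return float("nan")
    return len(a & b) / min(len(a), len(b))


def overlap_by_cluster_test(overlaps, same_cluster) -> float:
    """One-sided Wilcoxon rank-sum p for H1: same-cluster overlaps exceed
    cross-cluster overlaps (exact null for small tie-free groups)."""
    overlaps = np.asarray(overlaps, dtype=float)
    same_cluster = np.asarray(same_cluster, dtype=bool)
    x = overlaps[same_cluster]
    y = overlaps[~same_cluster]
    if len(x) == 0 or len(y) == 0:
        raise DataError("both overlap groups must be non-empty")
    ties = len(np.unique(overlaps)) < len(overlaps)
    method = "exact" if (max(len(x), len(y)) <= 12 and not ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def pairwise_overlaps(mutation_sets: dict[str, set[str]],
                      cluster_of: dict[str, int]) -> pd.DataFrame:
    """All sample-pair overlaps with their same-cluster flag."""
    ids = sorted(mutation_sets)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rows.append((a, b, clonal_overlap(mutation_sets[a], mutation_sets[b]),
                         cluster_of[a] == cluster_of[b]))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "overlap",
                                       "same_cluster"])


# ---------------------------------------------------------------------------
# AR-locus breakpoints
# ---------------------------------------------------------------------------

def count_ar_locus_breakpoints(calls: pd.DataFrame,
                               window: tuple[str, int, int]) -> pd.Series:
    """Unique breakpoint positions per patient inside the (half-open) window.

    ``calls`` columns: patient, chrom, pos.  Duplicated positions within a
    patient count once; a breakpoint at the window end is outside.
    """
    chrom, lo, hi = window
    if chrom != "chrX":
        raise DataError("the AR locus window must lie on chrX")
    inside = calls[(calls["chrom"] == chrom) & (calls["pos"] >= lo)
                   & (calls["pos"] < hi)]
    counts = inside.groupby("patient")["pos"].nunique()
    return counts.reindex(calls["patient"].unique(), fill_value=0)


def compare_breakpoint_counts(counts: pd.Series, group_of: dict[str, str],
                              alternative: str = "less") -> float:
    """Exact Mann-Whitney comparison of per-patient breakpoint counts between
    two patient groups (first group name in sorted order vs the other)."""
    groups = sorted(set(group_of.values()))
    if len(groups) != 2:
        raise DataError("need exactly two patient groups")
    x = counts[[p for p in counts.index if group_of[p] == groups[0]]]
    y = counts[[p for p in counts.index if group_of[p] == groups[1]]]
    ties = len(np.unique(counts)) < len(counts)
    method = "exact" if (max(len(x), len(y)) <= 12 and not ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_one_sided(table, alternative: str = "less") -> float:
    """Exact hypergeometric tail probability for a 2x2 table; degenerate
    margins give p = 1 with a warning."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(fisher_exact(t, alternative=alternative).pvalue)
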