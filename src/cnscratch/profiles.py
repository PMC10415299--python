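"""Binned copy-number profiles: normalization, segmentation, absolute copy
number, AR gain status and per-bin gain proportions.

The normalized ratio convention is genome-median: ratios are raw bin counts
divided by the median autosomal count, so the median autosomal ratio is 1.
The purity/ploidy transform uses the matching convention, with tumor ploidy
psi defined as the median autosomal tumor copy number:

    CN = (r*D - c_n*(1-rho)) / rho,   D = rho*psi + 2*(1-rho)

with c_n = 2 on autosomes and 1 on (male) chrX.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import BinGrid


class DataError(ValueError):
    pass


@dataclass
class BinnedProfile:
    """Per-bin raw counts and (after normalization) unitless ratios."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.grid.n_bins:
            raise DataError("profile length does not match the bin grid")


@dataclass
class SegmentProfile:
    """Constant-copy-number segments tiling the bin grid.

    ``segments`` columns: chrom, start, end (bp, half-open), start_bin,
    end_bin (chrom-local), n_bins, ratio and (after ``call_absolute_cn``) cn.
    """

    sample_id: str
    grid: BinGrid
    segments: pd.DataFrame
    purity: float | None = None
    ploidy: float | None = None

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.segments[self.segments["chrom"] == chrom]

    def values_per_bin(self, column: str = "ratio") -> np.ndarray:
        """Expand segment values back onto the bin grid."""
        out = np.empty(self.grid.n_bins)
        for row in self.segments.itertuples():
            idx = self.grid.global_bins(row.chrom, row.start_bin, row.end_bin)
            out[idx] = getattr(row, column)
        return out


def normalize_counts(profile: BinnedProfile) -> BinnedProfile:
    """Divide counts by the median autosomal count (median autosomal ratio = 1)."""
    auto = profile.counts[profile.grid.autosome_mask]
    med = np.median(auto.astype(float))
    if med <= 0:
        raise DataError("cannot normalize: median autosomal count is zero")
    return replace(profile, ratio=profile.counts / med)


def _greedy_segments(values: np.ndarray, merge_tol: float) -> list[tuple[int, int, float]]:
    """Left-to-right running-mean merge; then collapse adjacent segments whose
    means still lie within the tolerance, so the result is idempotent."""
    segs: list[tuple[int, int, float]] = []
    start, total = 0, values[0]
    for i in range(1, len(values)):
        mean = total / (i - start)
        if abs(values[i] - mean) <= merge_tol:
            total += values[i]
        else:
            segs.append((start, i, total / (i - start)))
            start, total = i, values[i]
    segs.append((start, len(values), total / (len(values) - start)))
    # post-pass: merge adjacent segments that are not distinguishable
    merged = [list(segs[0])]
    for s, e, m in segs[1:]:
        ps, pe, pm = merged[-1]
        if abs(m - pm) <= merge_tol:
            n1, n2 = pe - ps, e - s
            merged[-1] = [ps, e, (pm * n1 + m * n2) / (n1 + n2)]
        else:
            merged.append([s, e, m])
    return [tuple(m) for m in merged]


def segment_profile(profile: BinnedProfile, merge_tol: float = 0.3) -> SegmentProfile:
    """Merge consecutive bins with similar normalized ratios into segments.

    A bin joins the current segment iff its ratio is within ``merge_tol`` of
    the running segment mean; merging never crosses chromosome boundaries.
    Adjacent segments in the output differ by more than ``merge_tol``, which
    makes the operation idempotent.
    """
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    if profile.ratio is None:
        raise DataError("profile must be normalized before segmentation")
    grid = profile.grid
    rows = []
    for chrom in grid.chrom_names:
        vals = profile.ratio[grid.global_bins(chrom)]
        for s, e, m in _greedy_segments(vals, merge_tol):
            rows.append((chrom, s * grid.bin_width, e * grid.bin_width,
                         s, e, e - s, m))
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_bin",
                                           "end_bin", "n_bins", "ratio"])
    return SegmentProfile(profile.sample_id, grid, segments)


def call_absolute_cn(seg: SegmentProfile, rho: float, psi: float) -> SegmentProfile:
    """Convert segment ratios to absolute tumor copy number given purity and
    ploidy; negative values are clipped to zero with a warning."""
    if not 0 < rho <= 1:
        raise ValueError("purity must lie in (0, 1]")
    d = rho * psi + 2.0 * (1.0 - rho)
    c_n = np.where(seg.segments["chrom"] == "chrX", 1.0, 2.0)
    cn = (seg.segments["ratio"].to_numpy() * d - c_n * (1.0 - rho)) / rho
    if (cn < 0).any():
        warnings.warn(f"{int((cn < 0).sum())} segment(s) clipped to CN 0 "
                      f"in {seg.sample_id}")
        cn = np.clip(cn, 0.0, None)
    segments = seg.segments.copy()
    segments["cn"] = cn
    return SegmentProfile(seg.sample_id, seg.grid, segments, purity=rho, ploidy=psi)


def absolute_cn_bins(profile: BinnedProfile, rho: float, psi: float) -> BinnedProfile:
    """Per-bin absolute copy number (same transform as ``call_absolute_cn``
    applied to bin ratios rather than segment means)."""
    if not 0 < rho <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if profile.ratio is None:
        raise DataError("profile must be normalized first")
    d = rho * psi + 2.0 * (1.0 - rho)
    cn = (profile.ratio * d - profile.grid.normal_copies * (1.0 - rho)) / rho
    return replace(profile, ratio=cn)


def segment_absolute(profile: BinnedProfile, rho: float, psi: float,
                     merge_tol_cn: float = 0.5) -> SegmentProfile:
    """Segment purity/ploidy-corrected per-bin copy numbers.

    Working on the absolute-CN scale makes the merge tolerance a copy-number
    quantity, so event detectability does not shrink with tumor purity the
    way it does on the raw ratio scale; and because correlation distances
    are invariant to per-sample affine maps, downstream clustering is robust
    to purity misestimation.  Returns a SegmentProfile whose ``cn`` column is
    filled (equal to the segment means).
    """
    cn_prof = absolute_cn_bins(profile, rho, psi)
    seg = segment_profile(cn_prof, merge_tol_cn)
    seg.segments["cn"] = np.clip(seg.segments["ratio"], 0.0, None)
    seg.purity, seg.ploidy = rho, psi
    return seg


def ar_copy_number(seg: SegmentProfile, ar_interval: tuple[str, int, int] | None = None) -> float:
    """Overlap-length-weighted median copy number of the segment(s) covering
    the AR gene interval."""
    chrom, lo, hi = ar_interval if ar_interval is not None else seg.grid.ar_interval
    if chrom != "chrX":
        raise DataError("the AR interval must lie on chrX")
    sub = seg.for_chrom(chrom)
    if "cn" not in sub.columns:
        raise DataError("call_absolute_cn before ar_copy_number")
    ov = np.minimum(sub["end"], hi) - np.maximum(sub["start"], lo)
    keep = ov > 0
    if not keep.any():
        raise DataError("AR interval does not overlap any segment (off-grid?)")
    values = sub.loc[keep, "cn"].to_numpy()
    weights = ov[keep].to_numpy().astype(float)
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half, side="left"))
    if k + 1 < len(values) and np.isclose(cum[k], half):
        return float((values[k] + values[k + 1]) / 2.0)
    return float(values[k])


_EPS = 1e-9  # threshold comparisons tolerate float error in reconstructed CN


def xq_gained_fraction(seg: SegmentProfile, threshold: float = 2.0) -> float:
    """Fraction of Xq bins with absolute copy number >= threshold."""
    cn = seg.values_per_bin("cn")
    xq = seg.grid.xq_mask
    return float(np.mean(cn[xq] >= threshold - _EPS))


def classify_ar_gain(ar_cn: float, gained_fraction_of_xq: float,
                     cn_threshold: float = 2.0,
                     xq_fraction_cutoff: float = 0.80) -> bool:
    """AR gain: copy number >= 2 involving less than 80% of Xq.

    The >=2 criterion is applied to total copy number (one-copy male X
    baseline); both cutoffs are configurable.
    """
    if not (np.isfinite(ar_cn) and np.isfinite(gained_fraction_of_xq)):
        raise ValueError("inputs must be finite")
    return bool(ar_cn >= cn_threshold - _EPS
                and gained_fraction_of_xq < xq_fraction_cutoff)


def bin_gain_proportion(profiles: list[SegmentProfile], threshold: float = 2.0,
                        chrom: str = "chrX") -> np.ndarray:
    """Per-bin fraction of samples with absolute CN >= threshold on ``chrom``."""
    if not profiles:
        raise DataError("need at least one profile")
    grid = profiles[0].grid
    idx = grid.global_bins(chrom)
    gained = np.zeros(len(idx))
    for p in profiles:
        gained += p.values_per_bin("cn")[idx] >= threshold - _EPS
    return gained / len(profiles)


def filter_by_tumor_fraction(purities: dict[str, float],
                             min_tf: float = 0.2) -> list[str]:
    """Retain sample ids with purity >= min_tf (boundary inclusive)."""
    out = []
    for sid, rho in purities.items():
        if rho is None or not np.isfinite(rho):
            raise DataError(f"sample {sid} has no purity estimate")
        if rho >= min_tf:
            out.append(sid)
    return out
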