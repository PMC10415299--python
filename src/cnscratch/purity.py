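"""Tumor-content estimation from haplotype B-allele frequencies and a
penalized purity/ploidy grid fit, combined into a per-sample consensus.

The haplotype-BAF route exploits large "anchor" regions — segments with a
low read-depth ratio and allelic imbalance (e.g. an LOH arm) characterized
in a high-coverage, high-purity sample of the same patient.  Germline
phasing switch errors are corrected within anchors using the high-purity
sample, after which the pooled haplotype-A allele fraction B in a
low-coverage sample inverts to purity:

    B = (rho*n_A + (1-rho)) / (rho*(n_A+n_B) + 2*(1-rho))
    rho = (1 - 2B) / (B*(n_A + n_B - 2) - (n_A - 1))

assuming anchors keep the same allele-specific copies (n_A > n_B) across the
patient's samples.  The grid fit scores each (rho, psi) candidate by the
length-weighted distance of implied segment copy numbers from integers,
penalized toward high purity and near-diploid ploidy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import SegmentProfile, DataError

log = logging.getLogger(__name__)


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorRegion:
    """A purity anchor: an allelically imbalanced, low-ratio segment with
    known allele-specific tumor copies (n_a >= n_b, n_a != n_b)."""

    chrom: str
    start: int
    end: int
    n_a: int
    n_b: int
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.n_a == self.n_b:
            raise ValueError("anchor requires allelic imbalance (n_a != n_b)")
        if self.n_b < 0 or self.n_a < self.n_b:
            raise ValueError("anchor requires n_a >= n_b >= 0")


@dataclass
class PurityEstimate:
    sample_id: str
    rho_hapbaf: float | None = None
    rho_grid: float | None = None
    rho_consensus: float | None = None
    psi: float | None = None
    n_anchors_used: int = 0
    per_anchor: dict[int, float] = field(default_factory=dict)
    hapbaf_valid: bool = False
    discordant: bool = False
    degenerate: bool = False


# ---------------------------------------------------------------------------
# anchor selection (in the high-coverage sample)
# ---------------------------------------------------------------------------

def pooled_baf(snp_counts: pd.DataFrame) -> float:
    """Depth-weighted haplotype-A allele fraction from summed counts."""
    tot = snp_counts["a_count"].sum() + snp_counts["b_count"].sum()
    if tot == 0:
        raise DataError("no reads in region")
    return float(snp_counts["a_count"].sum() / tot)


def _block_corrected_baf(snps: pd.DataFrame) -> float:
    """Pooled haplotype BAF after flipping within-segment phase blocks whose
    mean lies below 0.5 (runs of per-SNP BAF on one side of 0.5)."""
    grp = snps.sort_values("pos")
    a = grp["a_count"].to_numpy().astype(float)
    b = grp["b_count"].to_numpy().astype(float)
    depth = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, a / depth, 0.5)
    side = baf > 0.5
    block = np.concatenate([[0], np.cumsum(side[1:] != side[:-1])])
    tot_a = 0.0
    for blk in np.unique(block):
        m = block == blk
        blk_a, blk_d = a[m].sum(), depth[m].sum()
        tot_a += blk_a if blk_d == 0 or blk_a / blk_d >= 0.5 else blk_d - blk_a
    return float(tot_a / depth.sum()) if depth.sum() else 0.5


# candidate allele-specific states tried when annotating an anchor
_ANCHOR_STATES = ((1, 0), (2, 0), (3, 0), (2, 1), (3, 1), (4, 1), (3, 2), (4, 2))


def select_anchor_regions(high_cov_seg: SegmentProfile, snp_table: pd.DataFrame,
                          rho: float | None = None, psi: float = 2.0, *,
                          ratio_margin: float = 0.1, baf_margin: float = 0.08,
                          min_length_bp: float = 10e6, ratio_tol: float = 0.1,
                          min_anchors: int = 3) -> list[AnchorRegion]:
    """Select anchors from a characterized high-coverage sample.

    Keeps maximal autosomal segments whose mean ratio lies below the sample's
    length-weighted median by at least ``ratio_margin`` and whose pooled,
    block-corrected phased BAF deviates from 0.5 by more than ``baf_margin``.
    Each candidate is annotated with the allele-specific state (n_a, n_b)
    that jointly satisfies the ratio and BAF constraints: every small
    imbalanced state is inverted through the BAF equation to an implied
    purity, and the state whose implied purity best reproduces the observed
    read-depth ratio (within ``ratio_tol``, given ploidy ``psi``) is kept.
    ``rho``, when provided, only breaks ties toward the state whose implied
    purity is closest to it.  Fewer than ``min_anchors`` qualifying segments
    triggers a warning (the haplotype-BAF estimate is then marked invalid
    downstream).
    """
    segs = high_cov_seg.segments
    lengths = (segs["end"] - segs["start"]).to_numpy().astype(float)
    order = np.argsort(segs["ratio"].to_numpy())
    cum = np.cumsum(lengths[order])
    med_ratio = float(segs["ratio"].to_numpy()[order][np.searchsorted(cum, cum[-1] / 2)])

    anchors: list[AnchorRegion] = []
    for row in segs.itertuples():
        if row.chrom == "chrX":
            continue
        if row.end - row.start < min_length_bp:
            continue
        if row.ratio > med_ratio - ratio_margin:
            continue
        snps = snp_table[(snp_table["chrom"] == row.chrom)
                         & (snp_table["pos"] >= row.start)
                         & (snp_table["pos"] < row.end)]
        if snps.empty:
            continue
        b = _block_corrected_baf(snps)
        if b - 0.5 <= baf_margin:
            continue
        best = None
        for n_a, n_b in _ANCHOR_STATES:
            denom = b * (n_a + n_b - 2) - (n_a - 1)
            if abs(denom) < 1e-9:
                continue
            rho_i = (1.0 - 2.0 * b) / denom
            if not 0.0 < rho_i <= 1.0:
                continue
            d_i = rho_i * psi + 2.0 * (1.0 - rho_i)
            pred = (rho_i * (n_a + n_b) + 2.0 * (1.0 - rho_i)) / d_i
            err = abs(pred - row.ratio)
            tie = abs(rho_i - rho) if rho is not None else 0.0
            if err < ratio_tol and (best is None or (err, tie) < best[:2]):
                best = (err, tie, n_a, n_b)
        if best is None:
            continue
        anchors.append(AnchorRegion(row.chrom, int(row.start), int(row.end),
                                    best[2], best[3], float(row.ratio)))
    if len(anchors) < min_anchors:
        warnings.warn(f"only {len(anchors)} anchor region(s) qualified "
                      f"(minimum {min_anchors}); haplotype-BAF purity will be "
                      "marked invalid")
    return anchors


# ---------------------------------------------------------------------------
# switch-error correction
# ---------------------------------------------------------------------------

def correct_switch_errors(snp_table: pd.DataFrame, high_purity_sample: str,
                          ambig_margin: float = 0.05) -> tuple[pd.DataFrame, int]:
    """Correct germline phasing switch errors using a high-purity sample.

    Within each anchor the high-purity sample's per-SNP BAF splits into two
    well-separated modes (the retained vs lost haplotype).  Consecutive SNPs
    on the same side of 0.5 form a phase block; each block is re-assigned to
    the haplotype whose pooled BAF in the high-purity sample exceeds 0.5, so
    that haplotype A is the over-represented allele.  Blocks whose pooled BAF
    lies within ``ambig_margin`` of 0.5 are dropped.  The relabeling (flips
    and drops) is applied to every sample's counts.  Returns the corrected
    table and the number of dropped blocks.
    """
    hp = snp_table[snp_table["sample"] == high_purity_sample]
    if hp.empty:
        raise DataError(f"high-purity sample {high_purity_sample!r} absent")
    flip_keys: set[tuple[str, int]] = set()
    drop_keys: set[tuple[str, int]] = set()
    n_dropped = 0
    for aid, grp in hp.groupby("anchor_id"):
        grp = grp.sort_values("pos")
        depth = (grp["a_count"] + grp["b_count"]).to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            baf = np.where(depth > 0, grp["a_count"].to_numpy() / depth, 0.5)
        side = baf > 0.5
        # maximal runs of constant side = candidate phase blocks
        block_id = np.concatenate([[0], np.cumsum(side[1:] != side[:-1])])
        pos = grp["pos"].to_numpy()
        a = grp["a_count"].to_numpy()
        b = grp["b_count"].to_numpy()
        for blk in np.unique(block_id):
            m = block_id == blk
            tot = a[m].sum() + b[m].sum()
            bmean = a[m].sum() / tot if tot > 0 else 0.5
            keys = {(grp["chrom"].iloc[0], int(p)) for p in pos[m]}
            if abs(bmean - 0.5) <= ambig_margin:
                drop_keys |= keys
                n_dropped += 1
            elif bmean < 0.5:
                flip_keys |= keys
    out = snp_table.copy()
    key = list(zip(out["chrom"], out["pos"]))
    flip_mask = np.array([k in flip_keys for k in key])
    drop_mask = np.array([k in drop_keys for k in key])
    a = out["a_count"].to_numpy().copy()
    b = out["b_count"].to_numpy().copy()
    out["a_count"] = np.where(flip_mask, b, a)
    out["b_count"] = np.where(flip_mask, a, b)
    out = out[~drop_mask].reset_index(drop=True)
    if n_dropped:
        log.info("dropped %d ambiguous phase block(s)", n_dropped)
    return out, n_dropped


# ---------------------------------------------------------------------------
# haplotype-BAF purity
# ---------------------------------------------------------------------------

def purity_from_haplotype_baf(corrected_snps: pd.DataFrame, anchor: AnchorRegion,
                              sample_id: str, *, min_snps: int = 20,
                              eps: float = 1e-9) -> float:
    """Per-anchor purity from the pooled haplotype-A BAF of one sample."""
    snps = corrected_snps[(corrected_snps["sample"] == sample_id)
                          & (corrected_snps["chrom"] == anchor.chrom)
                          & (corrected_snps["pos"] >= anchor.start)
                          & (corrected_snps["pos"] < anchor.end)]
    if len(snps) < min_snps:
        raise EstimationError(f"anchor has {len(snps)} SNPs (< {min_snps})")
    b = pooled_baf(snps)
    denom = b * (anchor.n_a + anchor.n_b - 2) - (anchor.n_a - 1)
    if abs(denom) < eps:
        raise EstimationError("anchor BAF equation is degenerate (denominator ~ 0)")
    return float(np.clip((1.0 - 2.0 * b) / denom, 0.0, 1.0))


def estimate_purity_hapbaf(corrected_snps: pd.DataFrame,
                           anchors: list[AnchorRegion], sample_id: str, *,
                           min_anchors: int = 3,
                           min_snps: int = 20) -> tuple[float | None, dict[int, float]]:
    """Median of per-anchor purities; invalid (None) below ``min_anchors``."""
    per_anchor: dict[int, float] = {}
    for i, anchor in enumerate(anchors):
        try:
            per_anchor[i] = purity_from_haplotype_baf(
                corrected_snps, anchor, sample_id, min_snps=min_snps)
        except EstimationError as e:
            log.info("anchor %d unusable for %s: %s", i, sample_id, e)
    if len(per_anchor) < min_anchors:
        return None, per_anchor
    return float(np.median(list(per_anchor.values()))), per_anchor


# ---------------------------------------------------------------------------
# grid purity/ploidy fit
# ---------------------------------------------------------------------------

def grid_fit_purity_ploidy(seg: SegmentProfile,
                           rho_grid: np.ndarray | None = None,
                           psi_grid: np.ndarray | None = None, *,
                           flat_sd: float = 1e-3
                           ) -> tuple[float, float, float, bool]:
    """Penalized grid search for purity and ploidy.

    Minimizes  E(rho, psi) = sum_s w_s |CN_s - round(CN_s)|
                             * (1 + |psi - 2|)^0.5 / rho^0.5
    with w_s the segment length fraction; ploidy and lower-cellularity
    penalty weights are both 0.5 (the exponents).  Ties are broken toward
    higher purity, then ploidy nearer 2.  A flat profile (length-weighted
    ratio SD below ``flat_sd``) returns (1, 2) with the degeneracy flag set.
    Returns (rho, psi, score, degenerate).
    """
    if len(seg.segments) < 5:
        warnings.warn("grid fit on fewer than 5 segments is poorly constrained")
    rho_grid = rho_grid if rho_grid is not None else np.round(np.arange(0.05, 1.0001, 0.01), 4)
    psi_grid = psi_grid if psi_grid is not None else np.round(np.arange(1.5, 5.0001, 0.05), 4)
    ratios = seg.segments["ratio"].to_numpy()
    w = (seg.segments["end"] - seg.segments["start"]).to_numpy().astype(float)
    w = w / w.sum()
    mean = float(np.sum(w * ratios))
    sd = float(np.sqrt(np.sum(w * (ratios - mean) ** 2)))
    if sd < flat_sd:
        return 1.0, 2.0, 0.0, True
    c_n = np.where(seg.segments["chrom"] == "chrX", 1.0, 2.0)

    rho = rho_grid[:, None, None]
    psi = psi_grid[None, :, None]
    d = rho * psi + 2.0 * (1.0 - rho)
    cn = (ratios[None, None, :] * d - c_n[None, None, :] * (1.0 - rho)) / rho
    resid = np.sum(w[None, None, :] * np.abs(cn - np.round(cn)), axis=2)
    energy = resid * np.sqrt(1.0 + np.abs(psi_grid[None, :] - 2.0)) / np.sqrt(rho_grid[:, None])

    best = energy.min()
    cand = np.argwhere(energy <= best + 1e-12)
    # higher rho first, then psi nearer 2
    key = sorted(cand, key=lambda ij: (-rho_grid[ij[0]], abs(psi_grid[ij[1]] - 2.0)))
    i, j = key[0]
    return float(rho_grid[i]), float(psi_grid[j]), float(energy[i, j]), False


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_purity(rho_hapbaf: float | None, rho_grid: float | None,
                     concordance_window: float = 0.1) -> tuple[float, bool]:
    """Combine the two estimates: mean when concordant (|diff| <= window),
    the haplotype-BAF value with a discordance flag otherwise, or whichever
    one is valid.  Returns (rho, discordant)."""
    if rho_hapbaf is None and rho_grid is None:
        raise EstimationError("no valid purity estimate")
    if rho_hapbaf is None:
        return float(rho_grid), False
    if rho_grid is None:
        return float(rho_hapbaf), False
    if abs(rho_hapbaf - rho_grid) <= concordance_window:
        return float((rho_hapbaf + rho_grid) / 2.0), False
    return float(rho_hapbaf), True
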