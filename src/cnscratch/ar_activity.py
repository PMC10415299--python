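"""Ternary AR transcriptional-activity score from expression counts.

Counts are filtered (>= 10 reads in >= 90% of samples), converted to
log2 counts-per-million and quantile normalized; per-gene z-scores across
samples are then ternarized against an androgen-response signature:

    score(up-gene)   =  1 if z >= 1,  -1 if z <= -1,  0 otherwise
    score(down-gene) = the negation of the up rule

and summed per sample over the signature genes present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .profiles import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARSignature:
    """Gene ids with regulation direction ('up' or 'down') under AR."""

    directions: dict[str, str]

    def __post_init__(self) -> None:
        bad = [d for d in self.directions.values() if d not in ("up", "down")]
        if bad:
            raise ValueError("directions must be 'up' or 'down'")
        if not self.directions:
            raise ValueError("signature is empty")

    @property
    def genes(self) -> list[str]:
        return list(self.directions)

    @classmethod
    def from_tsv(cls, path) -> "ARSignature":
        df = pd.read_csv(path, sep="\t", comment="#")
        if df["gene"].duplicated().any():
            raise ValueError("duplicate genes in signature")
        return cls(dict(zip(df["gene"], df["direction"])))

    @classmethod
    def default(cls) -> "ARSignature":
        """The bundled synthetic stand-in androgen-response signature
        (27 genes, 20 up / 7 down); replaceable via ``from_tsv``."""
        ref = resources.files("cnscratch").joinpath("data/ar_signature_synthetic.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def filter_and_normalize(counts: pd.DataFrame, min_count: int = 10,
                         min_fraction: float = 0.9) -> pd.DataFrame:
    """Keep genes with >= min_count reads in >= min_fraction of samples, then
    log2-CPM transform and quantile-normalize columns to the mean empirical
    distribution (all columns share one sorted value multiset afterwards)."""
    if counts.shape[1] < 2:
        raise DataError("need at least two samples")
    frac = (counts >= min_count).mean(axis=1)
    kept = counts.loc[frac >= min_fraction - 1e-12]
    if kept.empty:
        raise DataError("no genes survive the expression filter")
    cpm = kept / kept.sum(axis=0) * 1e6
    logx = np.log2(cpm + 0.5)
    ranks = np.apply_along_axis(rankdata, 0, logx.to_numpy())
    target = np.sort(logx.to_numpy(), axis=0).mean(axis=1)
    grid = np.arange(1, len(target) + 1)
    qn = np.empty_like(logx.to_numpy())
    for j in range(qn.shape[1]):
        qn[:, j] = np.interp(ranks[:, j], grid, target)
    return pd.DataFrame(qn, index=kept.index, columns=kept.columns)


def zscore_matrix(norm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (ddof=1); zero-variance genes get 0."""
    mu = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    z = norm.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def ternary_score(z: float, direction: str) -> int:
    """Ternarize a z-score; the down-gene rule is the negation of the up rule."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    up = 1 if z >= 1 else (-1 if z <= -1 else 0)
    if direction == "up":
        return up
    if direction == "down":
        return -up
    raise ValueError("direction must be 'up' or 'down'")


def ar_score(zm: pd.DataFrame, sig: ARSignature) -> pd.Series:
    """Per-sample sum of ternary scores over the signature genes present in
    the z-score matrix; missing genes are logged and skipped."""
    present = [g for g in sig.genes if g in zm.index]
    missing = [g for g in sig.genes if g not in zm.index]
    if missing:
        log.info("signature genes absent from matrix and skipped: %s", missing)
    if not present:
        raise DataError("no signature genes present in the z-score matrix")
    log.info("aggregating AR score over %d signature genes", len(present))
    scores = np.zeros(zm.shape[1], dtype=int)
    for g in present:
        direction = sig.directions[g]
        scores += np.array([ternary_score(z, direction) for z in zm.loc[g]])
    return pd.Series(scores, index=zm.columns, name="ar_score")


def compare_expression_by_group(values, labels, alternative: str = "two-sided",
                                exact_max_n: int = 12) -> float:
    """Mann-Whitney U p-value between the two groups in ``labels`` (exact
    null distribution for small tie-free groups, normal approximation
    otherwise)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise DataError("labels must define exactly two groups")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    ties = len(np.unique(values)) < len(values)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not ties) \
        else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)
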