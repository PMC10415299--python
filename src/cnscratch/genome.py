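"""Miniature genome model on a fixed-width bin grid.

The package works on a desk-scale male genome: a handful of autosomes plus
chromosome X, tiled by fixed-width bins (default 500 kb, 0-based half-open
coordinates).  Chromosome X carries a single copy in the (male) germline and
holds the designated AR gene bin, its centromeric enhancer bin and the Xq arm
used by the gain-classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

DEFAULT_BIN_WIDTH = 500_000


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width genomic bins tiling each chromosome without gaps.

    Coordinates are 0-based half-open; bin ``i`` of a chromosome spans
    ``[i*bin_width, (i+1)*bin_width)``.  ``ar_bin``, ``enhancer_bin`` and
    ``xq_start_bin`` are chrX-local bin indices.
    """

    chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chrX")
    chrom_bins: tuple[int, ...] = (200, 200, 200, 200, 120)
    bin_width: int = DEFAULT_BIN_WIDTH
    ar_bin: int = 66
    enhancer_bin: int = 65
    xq_start_bin: int = 50

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_bins):
            raise ValueError("chrom_names and chrom_bins must have equal length")
        if any(n <= 0 for n in self.chrom_bins):
            raise ValueError("every chromosome needs at least one bin")
        if "chrX" in self.chrom_names:
            nx = self.chrom_bins[self.chrom_names.index("chrX")]
            for name, b in (("ar_bin", self.ar_bin),
                            ("enhancer_bin", self.enhancer_bin),
                            ("xq_start_bin", self.xq_start_bin)):
                if not 0 <= b < nx:
                    raise ValueError(f"{name}={b} outside chrX ({nx} bins)")

    @cached_property
    def n_bins(self) -> int:
        return int(sum(self.chrom_bins))

    @cached_property
    def offsets(self) -> dict[str, int]:
        """Global bin offset of each chromosome."""
        off, total = {}, 0
        for name, n in zip(self.chrom_names, self.chrom_bins):
            off[name] = total
            total += n
        return off

    def n_chrom_bins(self, chrom: str) -> int:
        return self.chrom_bins[self.chrom_names.index(chrom)]

    def global_bins(self, chrom: str, start_bin: int = 0, end_bin: int | None = None) -> np.ndarray:
        """Global bin indices for a chrom-local half-open bin interval."""
        if end_bin is None:
            end_bin = self.n_chrom_bins(chrom)
        off = self.offsets[chrom]
        return np.arange(off + start_bin, off + end_bin)

    @cached_property
    def chrom_of_bin(self) -> np.ndarray:
        """Chromosome name per global bin."""
        return np.repeat(np.asarray(self.chrom_names, dtype=object), self.chrom_bins)

    @cached_property
    def autosome_mask(self) -> np.ndarray:
        return np.asarray([c != "chrX" for c in self.chrom_of_bin], dtype=bool)

    @cached_property
    def chrx_mask(self) -> np.ndarray:
        return ~self.autosome_mask

    @cached_property
    def xq_mask(self) -> np.ndarray:
        """Global-bin mask for the Xq arm (chrX bins at or past the centromere)."""
        mask = np.zeros(self.n_bins, dtype=bool)
        if "chrX" in self.chrom_names:
            mask[self.global_bins("chrX", self.xq_start_bin)] = True
        return mask

    @cached_property
    def normal_copies(self) -> np.ndarray:
        """Germline copy number per bin: 2 on autosomes, 1 on (male) chrX."""
        return np.where(self.autosome_mask, 2, 1).astype(float)

    def bin_start_bp(self, chrom: str, local_bin: int) -> int:
        return local_bin * self.bin_width

    @property
    def ar_interval(self) -> tuple[str, int, int]:
        """The bp interval of the AR gene bin on chrX."""
        return ("chrX", self.ar_bin * self.bin_width, (self.ar_bin + 1) * self.bin_width)

    def ar_locus_window(self, size_bp: int = 30_000_000) -> tuple[str, int, int]:
        """A window of ``size_bp`` centered on the AR bin, clipped to chrX."""
        mid = (self.ar_bin * self.bin_width) + self.bin_width // 2
        nx = self.n_chrom_bins("chrX") * self.bin_width
        lo = max(0, mid - size_bp // 2)
        hi = min(nx, mid + size_bp // 2)
        return ("chrX", lo, hi)


def default_grid() -> BinGrid:
    return BinGrid()
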