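import warnings

import numpy as np
import pytest

from cnscratch import (BinGrid, simulate_clone_tree, simulate_binned_counts,
                       BinnedProfile, normalize_counts, segment_absolute)

warnings.filterwarnings("ignore", message="only .* anchor region")
warnings.filterwarnings("ignore", message=".* clipped to CN 0 .*")


@pytest.fixture(scope="session")
def small_grid():
    """A tiny autosome-only grid for hand-checkable examples."""
    return BinGrid(chrom_names=("chr1",), chrom_bins=(5,))


@pytest.fixture(scope="session")
def default_tree():
    return simulate_clone_tree(3, 4, seed=11)


@pytest.fixture(scope="session")
def default_counts(default_tree):
    return simulate_binned_counts(default_tree, seed=12)


@pytest.fixture(scope="session")
def called_profiles(default_tree, default_counts):
    """Absolute-CN segment profiles at true purity/ploidy."""
    out = []
    for sid, c in default_counts.items():
        prof = normalize_counts(BinnedProfile(sid, default_tree.grid, c))
        out.append(segment_absolute(prof, default_tree.purity_of[sid],
                                    default_tree.median_autosomal_ploidy(sid)))
    return out


def ratio_profile(grid, ratios, sample_id="S"):
    return BinnedProfile(sample_id, grid, np.zeros(grid.n_bins),
                         ratio=np.asarray(ratios, dtype=float))
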