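import numpy as np
import pytest

from pepscreen.array_layout import GridSpec, build_layout
from pepscreen.library_design import LibraryConfig, PeptideEntry, assemble_library
from pepscreen.scan_simulator import assign_latent_adhesion, random_proteins


def brute_force_median(values):
    """Independent sort-based median: mean of the two central order statistics
    for even counts."""
    s = sorted(float(v) for v in values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


@pytest.fixture(scope="session")
def small_proteins():
    return random_proteins(lengths=(60, 45), seed=11, id_prefix="P")


@pytest.fixture(scope="session")
def small_library(small_proteins):
    cfg = LibraryConfig(n_random=60, n_blank=12, seed=5, replicates_scan=3,
                        replicates_substitution=2, replicates_random=2)
    library, report = assemble_library(cfg, small_proteins, parents=("NRWHE",))
    return library


@pytest.fixture(scope="session")
def small_layout(small_library):
    total = sum(e.replicates for e in small_library)
    side = int(np.ceil(np.sqrt(total / 0.9)))
    grid = GridSpec(grid_rows=side, grid_cols=side, seed=7)
    return build_layout(small_library, grid)


@pytest.fixture(scope="session")
def small_adhesion(small_library):
    return assign_latent_adhesion(small_library, seed=13)
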