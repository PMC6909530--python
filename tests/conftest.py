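import numpy as np
import pytest

import delcall as dc


@pytest.fixture(scope="session")
def homo_scene():
    """30 kb scene with one homozygous 600 bp deletion at 30x."""
    return dc.simulate_scene(
        30_000, [dc.DeletionSpec("chr1", 14_000, 14_600)],
        dc.LibraryModel(coverage=30), seed=42)


@pytest.fixture(scope="session")
def homo_stats(homo_scene):
    return dc.estimate_insert_stats(homo_scene.reads)


@pytest.fixture(scope="session")
def wild_scene():
    """Deletion-free 30 kb scene at 30x."""
    return dc.simulate_scene(30_000, [], dc.LibraryModel(coverage=30), seed=7)
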