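import numpy as np
import pytest

from dtrcall import Packaging, build_genome, package_molecules, shotgun_reads


@pytest.fixture(scope="session")
def small_genome():
    """20 kb circular assembly with a 2 kb declared terminal repeat."""
    return build_genome(20_000, 2_000, gc_fraction=0.66, seed=11)


@pytest.fixture(scope="session")
def small_simulation(small_genome):
    """Molecules + 100x error-free reads from the small genome."""
    molecules = package_molecules(
        small_genome, 30, Packaging.NONPERMUTED_REPEAT, seed=12
    )
    reads = shotgun_reads(
        molecules, fold_coverage=100, seed=13, unit_length=small_genome.unit_length
    )
    return molecules, reads


def brute_force_depth(molecules, reads, unit_length):
    """Oracle: per-base depth by direct counting from simulator ground truth."""
    depth = np.zeros(unit_length, dtype=int)
    starts = {m.name: m.origin_coords[0] for m in molecules}
    for read in reads:
        t = read.truth
        pos = (starts[t.molecule] + t.offset + np.arange(len(read.sequence))) % unit_length
        np.add.at(depth, pos, 1)
    return depth
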