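import pytest

import mycocheck as mc


@pytest.fixture(scope="session")
def small_markerset() -> mc.MarkerSet:
    """10 protein families (2 expected in 2 copies) + 3 DNA elements."""
    return mc.make_marker_set(
        n_families=10, n_multicopy=2, n_hde=3, mean_length=150, rng_seed=101
    )


@pytest.fixture(scope="session")
def small_genome(small_markerset):
    """A ~400 kb genome embedding every marker of ``small_markerset``."""
    return mc.make_genome(
        small_markerset, rng_seed=102, target_length=400_000, n_contigs=3
    )


@pytest.fixture(scope="session")
def small_report(small_markerset, small_genome):
    assembly, _ = small_genome
    return mc.full_report(assembly, small_markerset)
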