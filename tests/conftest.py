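import pytest

from taxaccum import SyntheticConfig, build_taxonomy, simulate_counts


@pytest.fixture(scope="session")
def small_tree():
    """2 phyla x 2 families x 3 genera = 12 genus leaves."""
    cfg = SyntheticConfig(n_phyla=2, families_per_phylum=2, genera_per_family=3)
    return build_taxonomy(cfg)


@pytest.fixture(scope="session")
def small_table(small_tree):
    cfg = SyntheticConfig(
        n_samples_per_group=10,
        n_phyla=2,
        families_per_phylum=2,
        genera_per_family=3,
        zero_fraction=0.3,
        seed=7,
    )
    table, labels = simulate_counts(small_tree, cfg)
    return table, labels
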