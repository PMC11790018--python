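import pytest

from methdep.synthetic import LibrarySpec, TruthConfig, generate_cohort

SMALL_LIBRARY = LibrarySpec(
    n_target_genes=30, n_essential_genes=6, n_nontargeting_guides=40
)


def small_config(**overrides) -> TruthConfig:
    """A scaled-down cohort configuration for fast unit tests."""
    base = dict(
        n_pediatric=20,
        n_adult=8,
        n_genes_expression=60,
        n_background_cpgs=60,
        n_mutation_genes=10,
        n_cnv_genes=6,
        library_spec=SMALL_LIBRARY,
        seed=101,
    )
    base.update(overrides)
    return TruthConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small synthetic cohort (28 lines, 160-guide library)."""
    return generate_cohort(small_config())
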