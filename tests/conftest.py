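import pytest

from circevo import synth


@pytest.fixture(scope="session")
def truth5():
    """Default five-species study: genomes, repeats, and read libraries."""
    specs = synth.default_species_specs()
    truth = synth.make_genomes(specs, seed=7)
    tables = synth.plant_repeats(truth, seed=8)
    libraries = synth.simulate_reads(truth, seed=9, depth=12_000)
    return truth, tables, libraries


def make_small_specs(n_genes=20, genome_length=200_000):
    te = synth.default_te_library()
    return [
        synth.SpeciesSpec("mouse", "rodent", genome_length=genome_length,
                          n_genes=n_genes, te_library=list(te)),
        synth.SpeciesSpec("rat", "rodent", genome_length=genome_length,
                          n_genes=n_genes, te_library=list(te)),
    ]


def small_plan(total=20):
    return synth.CircPlan(
        n_all=4, n_non_marsupial=0, n_rodent=3, n_primate=0,
        n_specific_per_species=2, n_partial_l1=1, n_partial_l2=1,
        n_total_target=total,
    )


@pytest.fixture(scope="session")
def small_truth():
    """Two-rodent toy study for fast unit tests."""
    truth = synth.make_genomes(make_small_specs(), seed=11, plan=small_plan())
    tables = synth.plant_repeats(truth, seed=12)
    libraries = synth.simulate_reads(truth, seed=13, depth=4000)
    return truth, tables, libraries
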