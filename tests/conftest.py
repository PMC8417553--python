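import numpy as np
import pytest

from dumbopt import CodonUsageTable, example_table


@pytest.fixture(scope="session")
def human_table():
    return example_table("human")


@pytest.fixture(scope="session")
def ecoli_table():
    return example_table("ecoli")


@pytest.fixture(scope="session")
def uniform_table():
    """All codons equally used within every synonymous family."""
    return CodonUsageTable.from_fractions("uniform", {})


def make_table(organism_id, fractions):
    """Table with the given per-family fractions; unspecified families uniform."""
    return CodonUsageTable.from_fractions(organism_id, fractions)


@pytest.fixture(scope="session")
def random_gene_factory(human_table):
    """Callable (seed, length) -> coding DNA sampled from the human-like table."""
    from dumbopt import GeneGenSpec, generate_gene

    def factory(seed, length=120, table=None, include_stop=True):
        return generate_gene(
            GeneGenSpec(
                table=table or human_table,
                seed=seed,
                length=length,
                include_stop=include_stop,
            )
        )

    return factory
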