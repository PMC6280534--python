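import numpy as np
import pandas as pd
import pytest

from dmrscan.methylome import MethylomeTable
from dmrscan.simulate import (
    DegPlan,
    SimulationSpec,
    SirnaPlan,
    generate_study,
    simulate_methylome,
    simulate_sirna_and_deg,
)


def make_table(rows, sample="s", condition="A", replicate=1):
    """MethylomeTable from (chrom, pos, strand, context, c, ct) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "c_count", "ct_count"]
    )
    return MethylomeTable(sample, condition, replicate, df)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(seed=1, genome_length=200_000, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_study(small_spec)


@pytest.fixture(scope="session")
def small_methylomes(small_study):
    ta = [simulate_methylome(small_study, "immature", r) for r in (1, 2)]
    tb = [simulate_methylome(small_study, "ripe", r) for r in (1, 2)]
    return ta, tb


@pytest.fixture(scope="session")
def small_pipeline(small_study, small_methylomes):
    from dmrscan.dmr import call_dmr_pipeline

    ta, tb = small_methylomes
    return call_dmr_pipeline(ta, tb, chrom_sizes=small_study.chrom_sizes)


@pytest.fixture(scope="session")
def small_sirna_deg(small_study):
    return simulate_sirna_and_deg(small_study)
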