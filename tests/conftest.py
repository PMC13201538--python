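import numpy as np
import pytest

from thermotrout.popgen import GenotypeTable
from thermotrout.respirometry import OxygenTrace


@pytest.fixture
def linear_trace():
    """Noiseless 180-min trace: DO = 10 - 0.5 * t_hours."""
    minutes = np.arange(181, dtype=float)
    return OxygenTrace(
        chamber_id="ch1",
        fish_id="F1",
        timestamps=minutes,
        do_mgL=10.0 - 0.5 * minutes / 60.0,
        temp_C=np.full(181, 12.0),
    )


def make_table(genotypes_by_pop, loci=None):
    """Build a GenotypeTable from {pop: [[(a,b), ...] per individual]}."""
    individuals, labels, rows = [], [], []
    for pop, inds in genotypes_by_pop.items():
        for i, g in enumerate(inds):
            individuals.append(f"{pop}_{i + 1}")
            labels.append(pop)
            rows.append(g)
    n_loci = len(rows[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeTable(
        individuals, loci, np.array(rows, dtype=int), np.array(labels, dtype=object)
    )


@pytest.fixture
def diverged_table():
    """Two populations fixed for different alleles at two loci."""
    return make_table(
        {
            "A": [[(1, 1), (1, 1)]] * 6,
            "B": [[(2, 2), (2, 2)]] * 6,
        }
    )
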