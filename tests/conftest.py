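import numpy as np
import pytest

from breedscan.genodata import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    PopulationScheme,
)
from breedscan.simdata import PopulationSpec, SimConfig, simulate


def make_matrix(calls, accession_ids=None, snp_ids=None, alleles=None):
    """Build a GenotypeMatrix from a nested list of call states."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_snp = calls.shape
    return GenotypeMatrix(
        accession_ids=accession_ids or [f"acc{i}" for i in range(n_acc)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(n_snp)],
        calls=calls,
        alleles=alleles or [("A", "G")] * n_snp,
    )


def make_map(n_snps, snp_ids=None, group="1H", spacing=1.0):
    snp_ids = snp_ids or [f"snp{j}" for j in range(n_snps)]
    return GeneticMap(
        snp_ids=snp_ids,
        linkage_groups=[group] * n_snps,
        positions_cm=np.arange(n_snps) * spacing,
    )


@pytest.fixture
def tiny_matrix():
    # 4 accessions x 3 SNPs covering all call states
    return make_matrix(
        [
            [HOM_REF, HOM_ALT, HOM_REF],
            [HOM_REF, HOM_REF, HOM_ALT],
            [HOM_ALT, HET, HOM_REF],
            [MISSING, HOM_REF, HOM_ALT],
        ]
    )


@pytest.fixture
def two_pop_scheme():
    return PopulationScheme(
        assignments={"acc0": "P1", "acc1": "P1", "acc2": "P2", "acc3": "P2"},
        spike_type={"P1": 2, "P2": 6},
        growth_habit={"P1": "spring", "P2": "spring"},
    )


def small_sim_config(seed=0, **overrides):
    base = dict(
        populations=[
            PopulationSpec("A", 2, "spring", 20, 0.15),
            PopulationSpec("B", 6, "spring", 20, 0.15),
            PopulationSpec("C", 2, "winter", 15, 0.15),
            PopulationSpec("D", 6, "winter", 15, 0.15),
        ],
        snps_per_group={"1H": 120, "2H": 120},
        map_length_cm={"1H": 100.0, "2H": 100.0},
        c_habit=0.05,
        c_spike=0.05,
        selfing_generations=4,
        missing_rate=0.02,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest 4-population simulated dataset shared across tests."""
    return simulate(small_sim_config(seed=11))
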