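import numpy as np
import pytest

from soilnet.io_tables import CountTable, SampleDesign, SampleInfo
from soilnet.synthetic_community import (
    AssociationBlock,
    SimulationConfig,
    TaxonSpec,
    cell_codes,
)


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        ["t1", "t2", "t3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[5, 0, 2, 7], [1, 3, 4, 1], [2, 2, 2, 2]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_flat_config(n_taxa: int = 10, blocks=(), **kwargs) -> SimulationConfig:
    """Flat composition across all cells, optional association blocks."""
    taxa = [
        TaxonSpec(f"t{i:02d}", "bacteria", f"d__Bacteria;p__P;c__;o__;f__F;g__t{i:02d}")
        for i in range(n_taxa)
    ]
    shares = {cell: {t.name: 1.0 / n_taxa for t in taxa} for cell in cell_codes()}
    return SimulationConfig(taxa=taxa, cell_shares=shares,
                            blocks=list(blocks), **kwargs)


def make_factorial_design(ismb=("L", "H"), fert=("N", "C"), hab=("SB", "SR"),
                          replicates=2, covariates=None) -> SampleDesign:
    infos = []
    for i_level in ismb:
        for f_level in fert:
            for h_level in hab:
                for rep in range(1, replicates + 1):
                    name = f"{f_level}{i_level}_{h_level}_{rep}"
                    covs = covariates(name) if covariates else {}
                    infos.append(SampleInfo(name, i_level, f_level, h_level, rep, covs))
    return SampleDesign(infos)


@pytest.fixture
def pair_block_config() -> SimulationConfig:
    return make_flat_config(8, blocks=[AssociationBlock(("t00", "t01"), 1.5, 1)])
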