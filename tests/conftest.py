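import numpy as np
import pandas as pd
import pytest

from panelkit.containers import GenotypeMatrix, HaplotypePanel, make_variant_table
from panelkit.simulate import BlockSpec, SimConfig, simulate_block_haplotypes


@pytest.fixture(scope="session")
def planted_panel():
    """3 planted blocks x 200 SNPs, 500 individuals, mutation 0.02."""
    cfg = SimConfig(
        n_individuals=500,
        blocks=tuple(BlockSpec(200, 8, 0.02) for _ in range(3)),
        seed=11,
    )
    return simulate_block_haplotypes(cfg)


@pytest.fixture(scope="session")
def small_panel():
    cfg = SimConfig(
        n_individuals=120, blocks=(BlockSpec(40, 6, 0.02), BlockSpec(40, 6, 0.02)), seed=3
    )
    return simulate_block_haplotypes(cfg)


def genotypes_from_array(arr, **kwargs) -> GenotypeMatrix:
    arr = np.asarray(arr, dtype=float)
    return GenotypeMatrix(
        arr, make_variant_table(arr.shape[1], **kwargs), [f"s{i}" for i in range(arr.shape[0])]
    )


def panel_from_haplotypes(hap, **kwargs) -> HaplotypePanel:
    hap = np.asarray(hap, dtype=np.uint8)
    return HaplotypePanel(
        hap, make_variant_table(hap.shape[1], **kwargs), [f"s{i}" for i in range(hap.shape[0] // 2)]
    )
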