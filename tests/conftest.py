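import numpy as np
import pandas as pd
import pytest

from lohma import ChromInfo, SimConfig, SnpMap


@pytest.fixture
def two_chrom_config() -> SimConfig:
    """Small two-chromosome genome for fast simulations."""
    return SimConfig(
        chrom_lengths={"chrI": 200_000, "chrII": 300_000},
        centromeres={"chrI": 100_000, "chrII": 150_000},
        seed=11,
    )


@pytest.fixture
def tiny_map() -> SnpMap:
    """Ten evenly spaced SNPs on one 100 kb chromosome."""
    pos = np.arange(1, 11) * 10_000 - 5_000  # 5000, 15000, ..., 95000
    return SnpMap(
        pd.DataFrame(
            {
                "chrom": "chrI",
                "pos": pos,
                "s_allele": ["A"] * 10,
                "y_allele": ["G"] * 10,
            }
        )
    )


@pytest.fixture
def tiny_chrom_info() -> ChromInfo:
    return ChromInfo({"chrI": 100_000}, {"chrI": 50_000})


def make_snp_map(positions_by_chrom: dict[str, list[int]]) -> SnpMap:
    if not positions_by_chrom:
        return SnpMap(
            pd.DataFrame(columns=["chrom", "pos", "s_allele", "y_allele"])
        )
    frames = []
    for chrom, positions in positions_by_chrom.items():
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions,
                    "s_allele": "A",
                    "y_allele": "G",
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))
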