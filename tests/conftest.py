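import numpy as np
import pandas as pd
import pytest

from bsaqtl.simulate import (
    GeneticMap,
    ReadModel,
    TraitModel,
    simulate_bsa_experiment,
)


@pytest.fixture
def two_chrom_map() -> GeneticMap:
    """Two 40 Mb chromosomes, 200 evenly spaced markers each (rice-like 4 cM/Mb)."""
    return GeneticMap.uniform(n_chromosomes=2, length_bp=40_000_000, n_markers=200)


@pytest.fixture
def default_trait(two_chrom_map) -> TraitModel:
    """Fully penetrant recessive susceptibility locus mid-chromosome-1."""
    pos = int(two_chrom_map.markers.query("chrom == 'chr1'")["pos"].iloc[100])
    return TraitModel(causal_chrom="chr1", causal_pos=pos)


@pytest.fixture
def bsa_experiment(two_chrom_map, default_trait):
    """One seeded bulked-segregant experiment (n=300, bulks of 20, depth 20)."""
    return simulate_bsa_experiment(
        two_chrom_map, default_trait, ReadModel(mean_depth=20.0), n=300, k=20, seed=7
    )


def make_track(
    pos, index_br, index_bs, depth_br=30, depth_bs=30, chrom="chr1"
) -> pd.DataFrame:
    """Hand-built SNP-index track for unit tests."""
    pos = np.asarray(pos)
    ibr = np.asarray(index_br, dtype=float)
    ibs = np.asarray(index_bs, dtype=float)
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "depth_br": np.broadcast_to(depth_br, n).copy(),
            "index_br": ibr,
            "depth_bs": np.broadcast_to(depth_bs, n).copy(),
            "index_bs": ibs,
            "delta": ibr - ibs,
        }
    )
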