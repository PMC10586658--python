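import numpy as np
import pandas as pd
import pytest

from regcircuit.config import SimConfig
from regcircuit.intervals import GenomicInterval
from regcircuit.io import PeakRecord


@pytest.fixture
def toy_genes():
    """Six genes on two chromosomes with known TSSs."""
    return pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
            "start": [1_000, 40_000, 200_000, 5_000, 90_000, 400_000],
            "end": [2_000, 41_000, 201_000, 6_000, 91_000, 401_000],
            "strand": ["+", "+", "-", "+", "-", "+"],
            "tss": [1_000, 40_000, 200_999, 5_000, 90_999, 400_000],
        }
    )


@pytest.fixture
def toy_catalogue():
    return pd.DataFrame(
        {
            "cre": ["c1", "c2", "c3", "c4", "c5"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "summit": [1_500, 45_000, 150_000, 6_000, 500_000],
            "source_states": ["A,B"] * 5,
        }
    )


@pytest.fixture
def small_sim_cfg():
    """Reduced-size simulation config for fast tests."""
    return SimConfig(
        n_chroms=2,
        chrom_length_bp=5_000_000,
        n_genes=150,
        n_cres=300,
        n_samples_per_state=3,
        n_tfs=8,
        n_shared_tfs=2,
        n_a_specific_tfs=1,
        n_b_specific_tfs=1,
        tf_target_fanout=8,
        shared_tf_fanout=10,
        master_tf_fanout=12,
        n_disease_genes=15,
        n_cres_per_disease_gene=2,
        rng_seed=7,
    )


def make_peak(chrom, start, end, name="p", score=1.0, summit_offset=None):
    summit = (start + end) // 2 if summit_offset is None else start + summit_offset
    return PeakRecord(GenomicInterval(chrom, start, end), name, score, summit)
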