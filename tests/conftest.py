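import numpy as np
import pandas as pd
import pytest

from reosig import Signature, SimulationConfig, simulate_study


@pytest.fixture
def tiny_expr() -> pd.DataFrame:
    """3 genes x 4 samples, no ties, distinct orderings per sample."""
    return pd.DataFrame(
        [[5.0, 1.0, 2.0, 9.0],
         [1.0, 3.0, 7.0, 2.0],
         [3.0, 2.0, 4.0, 1.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture(scope="session")
def planted_study():
    """Pair-only synthetic study: 15 planted pairs, no differential genes."""
    cfg = SimulationConfig(
        n_genes=200, n_samples_per_group=60, n_planted_reversal_pairs=15,
        reversal_stability=0.98, n_planted_degs=0, seed=1,
    )
    return simulate_study(cfg)


@pytest.fixture
def signature21() -> Signature:
    """A 21-pair signature with the canonical more-than-10 vote rule."""
    pairs = [(f"A{i:02d}", f"B{i:02d}") for i in range(21)]
    return Signature(pairs=pairs, threshold=10)


def split_groups(pheno: pd.DataFrame) -> tuple[list[str], list[str]]:
    low = list(pheno.loc[pheno["group"] == "LGG_like", "sample_id"])
    high = list(pheno.loc[pheno["group"] == "GBM_like", "sample_id"])
    return low, high
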