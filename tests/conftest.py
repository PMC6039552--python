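"""Shared fixtures: small synthetic genomes, methylomes and annotations."""

import numpy as np
import pandas as pd
import pytest

from bsmeth import genome_io, synthetic


@pytest.fixture(scope="session")
def genome_small() -> genome_io.Genome:
    """30 kb two-replicon genome (chromosome + plasmid analogue)."""
    return synthetic.simulate_genome(
        30_000, seed=11, lengths=[25_000, 5_000], names=["chromosome", "plasmid_1"]
    )


@pytest.fixture(scope="session")
def features_small(genome_small) -> genome_io.FeatureTable:
    return synthetic.simulate_features(genome_small, seed=11)


@pytest.fixture(scope="session")
def methylome_small(genome_small) -> synthetic.TrueMethylome:
    return synthetic.assign_methylome(genome_small, seed=11)


def make_calls_frame(sites: pd.DataFrame, coverage, k, is_mc, ml=None) -> pd.DataFrame:
    """Assemble a minimal calls DataFrame from site rows and per-site arrays."""
    calls = sites.copy().reset_index(drop=True)
    calls["coverage"] = np.asarray(coverage)
    calls["count_methylated"] = np.asarray(k)
    calls["count_unmethylated"] = calls["coverage"] - calls["count_methylated"]
    calls["ml_uncorrected"] = calls["count_methylated"] / calls["coverage"]
    calls["ml_corrected"] = calls["ml_uncorrected"] if ml is None else np.asarray(ml)
    calls["is_mc"] = np.asarray(is_mc, dtype=bool)
    return calls
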