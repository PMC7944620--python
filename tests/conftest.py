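"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

import triadtrack as tt


@pytest.fixture(scope="session")
def toy_triads() -> tt.TriadTable:
    """Three triads on one chromosome group, fixed coordinates."""
    coords = pd.DataFrame(
        {
            "chrom": ["chr1A", "chr1A", "chr1A",
                      "chr1B", "chr1B", "chr1B",
                      "chr1D", "chr1D", "chr1D"],
            "start": [0, 1000, 5000, 0, 1000, 5000, 0, 1000, 5000],
            "end": [1000, 4000, 7000, 1000, 4000, 7000, 1000, 4000, 7000],
        },
        index=pd.Index([f"g{i}{s}" for s in "ABD" for i in range(3)],
                       name="gene_id"),
    )
    coords["length"] = coords["end"] - coords["start"]
    table = pd.DataFrame(
        {"gene_A": ["g0A", "g1A", "g2A"],
         "gene_B": ["g0B", "g1B", "g2B"],
         "gene_D": ["g0D", "g1D", "g2D"]},
        index=pd.Index(["t0", "t1", "t2"], name="triad_id"),
    )
    return tt.TriadTable(table, coords)


@pytest.fixture(scope="session")
def noiseless_domestication() -> tuple:
    """A noiseless planted domestication series plus its pipeline outputs."""
    cfg = tt.domestication_config(n_triads=800, seed=42, noiseless=True)
    ds = tt.simulate_series(cfg)
    tpm = tt.tpm_matrix(ds.counts, ds.triads.gene_lengths())
    calls = tt.classify_dataset(tt.aggregate_replicates(tpm), ds.triads)
    return ds, tpm, calls


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
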