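import numpy as np
import pytest

import breedscan as bs


@pytest.fixture(scope="session")
def small_config():
    return bs.SimConfig(n_hybrids=60, n_snps=1500, seed=7)


@pytest.fixture(scope="session")
def panel(small_config):
    G, meta, truth = bs.simulate_panel(small_config)
    return G, meta, truth


@pytest.fixture(scope="session")
def qc_panel(panel):
    G, meta, truth = panel
    G2, report = bs.qc_and_impute(G)
    return G2, meta, truth, report


@pytest.fixture(scope="session")
def environments(small_config):
    return bs.simulate_environments(small_config)


@pytest.fixture(scope="session")
def trial(small_config, qc_panel, environments):
    G2, meta, truth, _ = qc_panel
    table, ttruth = bs.simulate_trial(small_config, G2, meta, environments, truth)
    return table, ttruth


def make_genotypes(counts, chrom=None, pos=None, ref=None, alt=None):
    """Small GenotypeMatrix from a raw count array."""
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    return bs.GenotypeMatrix(
        counts=counts,
        hybrid_ids=np.array([f"h{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(m) * 1000, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * m, dtype=object),
    )
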