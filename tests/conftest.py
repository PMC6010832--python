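import logging

import numpy as np
import pandas as pd
import pytest

from lekgraph.io import GenotypeTable, LocusPanel

logging.getLogger("lekgraph").setLevel(logging.ERROR)


def make_table(calls, lek_ids=None, lats=None, lons=None, loci=None, sample_ids=None):
    """Build a GenotypeTable from a nested list of (a1, a2) pairs per sample."""
    calls = np.asarray(calls, dtype=np.int64)
    n, n_loci = calls.shape[:2]
    loci = tuple(loci or [f"L{j + 1:02d}" for j in range(n_loci)])
    meta = pd.DataFrame({
        "sample_id": sample_ids or [f"S{i:03d}" for i in range(n)],
        "lek_id": lek_ids or ["lekA"] * n,
        "lat": lats if lats is not None else [40.0] * n,
        "lon": lons if lons is not None else [-110.0] * n,
        "source": ["synthetic"] * n,
    })
    return GenotypeTable(meta, loci, calls)


def random_table(rng, n_samples=10, n_loci=4, n_alleles=5, missing_rate=0.1,
                 n_leks=3):
    """Random valid genotype table for round-trip / invariance tests."""
    alleles = 100 + 4 * np.arange(n_alleles)
    calls = rng.choice(alleles, size=(n_samples, n_loci, 2))
    miss = rng.random((n_samples, n_loci)) < missing_rate
    calls[miss] = 0
    lek_ids = [f"lek{rng.integers(n_leks)}" for _ in range(n_samples)]
    lats = rng.uniform(35, 45, n_samples).round(4)
    lons = rng.uniform(-115, -105, n_samples).round(4)
    return make_table(calls, lek_ids=lek_ids, lats=list(lats), lons=list(lons))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def panel4():
    return LocusPanel.from_names(["L01", "L02", "L03", "L04"], motif_length=4)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A tiny simulated input bundle shared across tests (session-scoped)."""
    from lekgraph.simulate import make_fixture

    outdir = tmp_path_factory.mktemp("tiny_fixture")
    paths = make_fixture("tiny", seed=11, outdir=outdir)
    return paths
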