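import numpy as np
import pandas as pd
import pytest

from mutspectra import polarize, simdata


@pytest.fixture(scope="session")
def small_config():
    """A 50 kb, 10+10 diploid cohort with injected adjacent pairs."""
    return simdata.SimulationConfig(
        chrom_lengths={"chr1": 30_000, "chr2": 20_000},
        populations={"A": 10, "B": 10},
        variants_per_population=250,
        sdm_pairs_per_population={"A": 10, "B": 10},
        mnp_pairs_per_population={"A": 5, "B": 5},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate(small_config)


@pytest.fixture(scope="session")
def small_variants(small_dataset):
    """Polarized variants of the small cohort (all sites survive filters)."""
    rejections = {}
    variants = list(
        polarize.polarize_sites(
            iter(small_dataset.sites), small_dataset.ancestral, rejections=rejections
        )
    )
    assert sum(rejections.values()) + len(variants) == len(small_dataset.sites)
    return variants


def make_site(ref="A", alt="G", genotypes=None, phased=None, chrom="chr1", pos=100):
    """Hand-built biallelic site; genotypes default to a clean spread."""
    if genotypes is None:
        genotypes = [(0, 0), (0, 1), (1, 1), (0, 1), (0, 1)]
    return polarize.SiteRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=(alt,) if isinstance(alt, str) else tuple(alt),
        genotypes=genotypes,
        phased=phased or [True] * len(genotypes),
    )


@pytest.fixture
def toy_catalog():
    """A deterministic 96-channel synthetic signature catalogue."""
    from mutspectra.snv import channel_labels

    labels = channel_labels(3)
    rng = np.random.default_rng(7)
    data = {
        f"SIG{i + 1}": rng.dirichlet(np.ones(len(labels))) for i in range(5)
    }
    return pd.DataFrame(data, index=labels)
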