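import pytest

from kinarray.kinase_mapping import collapse_to_families
from kinarray.synthetic_data import SyntheticTruth, generate_catalog, generate_map


@pytest.fixture(scope="session")
def catalog():
    return generate_catalog(196, 3, seed=7)


@pytest.fixture(scope="session")
def kmap(catalog):
    return generate_map(catalog, n_kinases=60, seed=7)


@pytest.fixture(scope="session")
def family_peptides(kmap):
    return collapse_to_families(kmap)


@pytest.fixture(scope="session")
def spiked_family(kmap, family_peptides):
    """A family with >= 5 mapped peptides, with all member kinases listed."""
    fam = next(f for f in sorted(family_peptides) if len(family_peptides[f]) >= 5)
    return fam, kmap.members_of(fam)


def make_truth(members, effect=1.5, noise_sd=0.0, seed=0, **kw):
    return SyntheticTruth(
        spiked_kinases=tuple((m, effect) for m in members), noise_sd=noise_sd, seed=seed, **kw
    )
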