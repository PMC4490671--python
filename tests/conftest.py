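import numpy as np
import pytest

from virocurate import CommunitySpec, generate_community

#: maps generator class labels to the triage label they must recover to
TRIAGE_LABEL = {"viral": "viral", "cellular": "cellular_review",
                "plasmid": "plasmid_review", "mitochondrial": "mito_review"}


@pytest.fixture(scope="session")
def spec():
    return CommunitySpec(n_viral=8, n_cellular=4, n_plasmidlike=3,
                         n_mitolike=3, fraction_circular=0.5,
                         n_attp=3, n_crispr=2, n_redundant=3, seed=11)


@pytest.fixture(scope="session")
def community(spec):
    return generate_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_2509)
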