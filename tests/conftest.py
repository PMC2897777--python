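import numpy as np
import pytest

from isoclone.fixtures import FixtureSpec, random_cds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def clean_target():
    """A 300-codon CDS free of all four recognition sites."""
    return random_cds(FixtureSpec(seed=11, n_codons=300, id="clean"))


@pytest.fixture(scope="session")
def small_target_set():
    """Twenty mixed-domain site-free targets for I/O round-trips."""
    domains = ("eukarya", "bacteria", "archaea")
    return [
        random_cds(
            FixtureSpec(seed=100 + k, n_codons=60 + 7 * k,
                        domain_of_life=domains[k % 3], id=f"t{k:02d}")
        )
        for k in range(20)
    ]


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
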