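import pytest

from mitotrio import synth
from mitotrio.pipeline import run_trio


@pytest.fixture(scope="session")
def base_genome():
    return synth.make_base(seed=1)


@pytest.fixture(scope="session")
def trio(base_genome):
    """Default-spectrum trio: (genomes dict, ground-truth ledger)."""
    return synth.make_trio(base_genome, seed=7)


@pytest.fixture(scope="session")
def analysis(trio):
    """Full pipeline result on the session trio."""
    genomes, _ledger = trio
    return run_trio(
        genomes[synth.TARGET].seq,
        genomes[synth.CONSPECIFIC].seq,
        genomes[synth.REFERENCE],
    )
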