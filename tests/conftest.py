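import pytest

from levsim.pkmodel import IndividualParameters, PopulationParameters, typical_clearance


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    return PopulationParameters()


@pytest.fixture
def typical_subject(pop):
    """Typical-value subject at a given CrCl (no inter-individual variability)."""

    def make(crcl: float) -> IndividualParameters:
        return IndividualParameters(
            cl=typical_clearance(crcl, pop), v1=pop.v1_pop, q=pop.q_pop, v2=pop.v2_pop
        )

    return make
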