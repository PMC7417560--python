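import pytest

from circscreen import DesignParams, build_junction_context, design_primary
from circscreen.fixtures import CircLayout, FixtureSpec, synth_locus


@pytest.fixture(scope="session")
def locus():
    """Default synthetic locus: 200-nt single-exon plus-strand circle."""
    return synth_locus(FixtureSpec(rng_seed=1))


@pytest.fixture(scope="session")
def minus_locus():
    return synth_locus(
        FixtureSpec(rng_seed=2, circ_layout=CircLayout(strand="-"))
    )


@pytest.fixture(scope="session")
def junction_ctx(locus):
    return build_junction_context(locus.circs[0], locus.genome, DesignParams())


@pytest.fixture(scope="session")
def primary_design(junction_ctx):
    return design_primary(junction_ctx, DesignParams())
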