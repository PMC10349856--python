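import pytest

from raflsbool import (
    fixture_rafls,
    fixture_rafls_unmodified,
    inputs_of,
    parse_bnet,
)


@pytest.fixture(scope="session")
def rafls():
    return fixture_rafls()


@pytest.fixture(scope="session")
def rafls_unmodified():
    return fixture_rafls_unmodified()


@pytest.fixture(scope="session")
def all_inputs_on(rafls):
    return {v: 1 for v in inputs_of(rafls)}


@pytest.fixture()
def p53_mdm2():
    """The two-node negative feedback loop driving the oscillations."""
    return parse_bnet("targets, factors\nTP53, !MDM2\nMDM2, TP53\n")


def subspace_key(spaces):
    """Order-insensitive canonical form for sets of subspaces."""
    return {tuple(sorted(s.items())) for s in spaces}
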