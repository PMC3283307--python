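import pytest

from synteams.validation_fixtures import load_example


@pytest.fixture(scope="session")
def example(request):
    return load_example


@pytest.fixture(scope="session", params=[1, 2, 3, 4, 5, 6])
def each_example(request):
    return load_example(request.param)


def famsets(clusters):
    """Family-set collection of a cluster/synteny/zone iterable."""
    return {c.families for c in clusters}


def witness_positions(synteny):
    return {(g.chromosome, g.position) for g in synteny.witness}
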