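import pytest

from nicodh import build_group_templates, generate_reference_anchors

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def anchors():
    return generate_reference_anchors(FIXTURE_SEED)


@pytest.fixture(scope="session")
def anchor_by_clade(anchors):
    return {a.clade: a for a in anchors}


@pytest.fixture(scope="session")
def templates():
    return build_group_templates(FIXTURE_SEED)
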