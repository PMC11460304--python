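import pytest

from abbrsense.corpus import AbbrevInstance, SenseInventory, build_sense_inventory
from abbrsense.pairs import WhitespaceTokenizer


@pytest.fixture
def worked_instance() -> AbbrevInstance:
    """The canonical worked example: 'BK' meaning 'below knee'."""
    return AbbrevInstance(
        index="1",
        target="BK",
        left="...He is status post a",
        right="amputation on the right side and...",
        label="below knee",
        negs=("BK(virus)",),
    )


@pytest.fixture
def worked_inventory(worked_instance) -> SenseInventory:
    return build_sense_inventory([worked_instance])


@pytest.fixture
def tokenizer() -> WhitespaceTokenizer:
    return WhitespaceTokenizer(model_max_length=512)
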