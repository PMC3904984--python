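import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_inventory():
    from lipoarch import io

    return io.load_paper_inventory()


@pytest.fixture(scope="session")
def paper_calls(paper_inventory):
    from lipoarch import pathway

    return pathway.call_inventories(paper_inventory)
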