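import pytest

from genelog.logstore import LogStore, TopicSpec


@pytest.fixture
def store(tmp_path):
    return LogStore(tmp_path / "store")


@pytest.fixture
def topic4(store):
    """Plain 4-partition topic."""
    return store.create_topic(TopicSpec(name="t", n_partitions=4))


@pytest.fixture
def compacted_topic(store):
    return store.create_topic(
        TopicSpec(name="c", n_partitions=1, compacted=True))
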