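import pytest

from onconer import Document, load_default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture
def worked_size_sentence():
    # training-set sentence exercising the full size pipeline
    return "左肺上叶示一不规则软组织密度灶,大小约1.3CM × 1.7CM,边缘分叶,可见强化。"


@pytest.fixture
def two_primary_doc():
    # two primary sites in one report; the rule set extracts only the first
    return Document(
        "two-primary",
        "右乳炎性乳癌术后;右肺中叶磨玻璃结节伴轻度糖代谢增高,考虑为原发性MT可能。",
    )
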