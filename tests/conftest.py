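import pytest
from hypothesis import settings

import lexiscreen as lx

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Small deterministic lexicon with its generation-time tally."""
    spec = lx.FixtureSpec(seed=11)
    lex, summary = lx.make_toy_lexicon(spec)
    return spec, lex, summary


@pytest.fixture()
def tiny_lexicon():
    """Three hand-written entries covering phrases, emoticons and variants."""
    return lx.Lexicon(
        entries=[
            lx.KeywordEntry(
                entry_id="g1", category="guilt_self_esteem", surface="i feel worthless",
                derivatives=frozenset({"feeling worthless"}),
                variations=frozenset({"i feel wrthless"}),
                sources=frozenset({"expert_interview"}),
            ),
            lx.KeywordEntry(
                entry_id="s1", category="suicide", surface="take my life",
                variations=frozenset({"tke my life", "take my lyf"}),
                sources=frozenset({"expert_interview", "researcher_extension"}),
            ),
            lx.KeywordEntry(
                entry_id="m1", category="mood", surface=":-(",
                sources=frozenset({"focus_group"}),
            ),
        ],
        metadata={"name": "tiny"},
    )
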