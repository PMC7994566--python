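import pytest

from fluency2ef.session_data import FluencySession, Token
from fluency2ef.synthetic_cohort import GeneratorConfig, generate_cohort
from fluency2ef.toy_resource import build_toy_embeddings, build_toy_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return build_toy_taxonomy()


@pytest.fixture(scope="session")
def embeddings():
    return build_toy_embeddings()


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-sized realistic cohort shared by read-only tests."""
    return generate_cohort(
        GeneratorConfig(n_participants=60, seed=7, scenario="paper_like")
    )


def make_session(words_and_times, task_id="t1", participant_id="p1", codes=None,
                 categories=None, duration=120.0):
    """Terse constructor for handmade sessions in tests."""
    codes = codes or ["correct"] * len(words_and_times)
    if categories is None:
        categories = [None if task_id != "t3" else "sports"] * len(words_and_times)
    tokens = [
        Token(word=w, onset=a, offset=b, code=c, category=cat)
        for (w, a, b), c, cat in zip(words_and_times, codes, categories)
    ]
    return FluencySession(participant_id=participant_id, task_id=task_id,
                         tokens=tokens, duration=duration)
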