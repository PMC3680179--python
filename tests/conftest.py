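from dataclasses import replace

import pytest

from eventweave.synthetic import generate, standard_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return standard_scenarios()


@pytest.fixture(scope="session")
def identical_corpora(scenarios):
    cfg = replace(scenarios["identical-scopes"], docs_per_corpus=14)
    return generate(cfg)


@pytest.fixture(scope="session")
def disjoint_corpora(scenarios):
    cfg = replace(scenarios["disjoint-plus-shared"], docs_per_corpus=30)
    return generate(cfg)


@pytest.fixture(scope="session")
def nested_corpora(scenarios):
    cfg = replace(scenarios["nested-regulation"], docs_per_corpus=20)
    return generate(cfg)


@pytest.fixture(scope="session")
def hedge_corpora(scenarios):
    cfg = replace(scenarios["hedge-mix"], docs_per_corpus=20)
    return generate(cfg)
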