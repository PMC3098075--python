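import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tcmnorm.corpus_io import build_remedy_bags
from tcmnorm.remedy_metrics import RemedyContext
from tcmnorm.synth_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic corpus (seed 42) shared across tests."""
    return generate_corpus(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_context(default_bundle):
    """All three remedy models fitted on the default bundle."""
    return RemedyContext.fit(build_remedy_bags(default_bundle.corpus))


@pytest.fixture(scope="session")
def default_names(default_bundle):
    standards = sorted(default_bundle.corpus.standard_names)
    clinicals = sorted(default_bundle.corpus.clinical_names)
    return standards, clinicals
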