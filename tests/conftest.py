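import pandas as pd
import pytest

from elderwell.codebook import default_codebook
from elderwell.index import score_table
from elderwell.recode import collapse_levels
from elderwell.simulate import make_fixture


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def tiny8():
    return make_fixture("tiny8")


@pytest.fixture(scope="session")
def allbest4():
    return make_fixture("allbest4")


@pytest.fixture(scope="session")
def paper_like():
    return make_fixture("paper_like_300")


@pytest.fixture(scope="session")
def paper_like_scores(paper_like):
    return score_table(paper_like)


@pytest.fixture(scope="session")
def paper_like_coded(paper_like, paper_like_scores) -> pd.DataFrame:
    return collapse_levels(paper_like, paper_like_scores)
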