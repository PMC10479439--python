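import numpy as np
import pytest
from hypothesis import settings

from npmatch.lexicon import Lexicon, SynonymGroup

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def licorice_group():
    return SynonymGroup(
        group_id="g1",
        preferred_term="LIQUORICE",
        latin_binomial="GLYCYRRHIZA GLABRA",
        variants=frozenset({"LIKORICE"}),
    )


@pytest.fixture
def small_lexicon(licorice_group):
    ginger = SynonymGroup(
        group_id="g2",
        preferred_term="GINGER",
        latin_binomial="ZINGIBER OFFICINALE",
        variants=frozenset({"GINGER ROOT"}),
    )
    cinnamon = SynonymGroup(
        group_id="g3",
        preferred_term="CINNAMON",
        latin_binomial="CINNAMOMUM VERUM",
        variants=frozenset(),
    )
    return Lexicon([licorice_group, ginger, cinnamon])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
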