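import numpy as np
import pytest

from mscascade.microstate import TemplateSet
from mscascade.montage import standard_1020_19
from mscascade.synthetic import make_prototypes


@pytest.fixture(scope="session")
def montage():
    return standard_1020_19()


@pytest.fixture(scope="session")
def prototypes(montage):
    return make_prototypes(montage)


@pytest.fixture(scope="session")
def prototype_maps(prototypes):
    return np.stack([p.map for p in prototypes])


@pytest.fixture(scope="session")
def ideal_templates(prototype_maps):
    """A TemplateSet whose maps are exactly the built-in prototypes."""
    return TemplateSet("broadband", prototype_maps, ("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
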