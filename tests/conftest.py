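import numpy as np
import pytest

import anchordock as ad
from anchordock import fixtures as fx


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec()


@pytest.fixture(scope="session")
def groove(spec):
    return fx.generate_groove(spec)


@pytest.fixture(scope="session")
def complex_default(spec):
    return fx.generate_complex(spec)


LIBRARY_SEQUENCES = ["ILKEPVHGV", "LLFGYPVYV", "ALWGFFPVL",
                     "SLYNTVATL", "GILGFVFTL"]


@pytest.fixture(scope="session")
def library_complexes(spec):
    return [fx.generate_complex(spec, s, 2.0 - 0.1 * i)
            for i, s in enumerate(LIBRARY_SEQUENCES)]


@pytest.fixture(scope="session")
def template_library(library_complexes):
    return ad.build_template_library(library_complexes)


@pytest.fixture(scope="session")
def rotamer_library():
    return ad.RotamerLibrary.default()


@pytest.fixture(scope="session")
def params():
    return ad.ForceFieldParams.default()
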